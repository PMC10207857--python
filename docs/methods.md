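# Methods

This note documents the models, defaults, and design choices behind
`plauscheck`, and what its synthetic-data tests do and do not establish
about real registry data.

## Problem setting

A tumor record is a tuple of 16 categorical tokens. A record is
*implausible* when its value combination contradicts medical knowledge even
though each individual value is valid. Screening is unsupervised: both
scorers are trained and evaluated on the same full table. This is sound for
anomaly detection — neither method sees labels, so there is no
label-leakage analogue of overfitting; scoring a held-out table with the
trained models would be expected to behave similarly.

## FindFPOF

- **Pattern semantics.** A pattern assigns at most one token per variable;
  frequency is the fraction of records matched. Frequencies are computed
  over the full table *including* the scored record — no leave-one-out.
- **Thresholds.** `max_length = 5`, `min_frequency = 0.10` by default. The
  frequency threshold is inclusive: a pattern at exactly 10% is frequent.
  Internally the threshold is the smallest support count `c` with
  `c/n ≥ min_frequency`, computed with a 1e-9 guard against binary
  floating-point artifacts (e.g. `0.1 × 30` evaluating just above 3).
- **`min_frequency = 0`.** The effective minimum support is one record:
  patterns never observed in the table are excluded. Unobserved patterns
  would contribute nothing to any score's numerator while making the
  denominator astronomically large; for any positive threshold the choice
  is vacuous.
- **Zero-length patterns** are excluded; they match everything and would
  only shift all scores by a constant.
- **Mining.** Level-wise Apriori: a pattern is extended only if frequent,
  candidates are generated in canonical order (variables in schema order,
  tokens in domain order), so the enumeration is reproducible. Row
  membership is kept as packed bitsets (`np.packbits` /
  `np.bitwise_count`), which keeps a 20,000-record mining run with
  thousands of frequent patterns in well under a second. FPOF numerators
  are accumulated during the same pass, so the table is mined exactly once.
- **Degenerate inputs.** An empty table has undefined frequencies; an empty
  frequent-pattern set has undefined FPOF. Both raise instead of returning
  a silent 0/0.

## Autoencoder

- **Architecture.** `D → 16 → 8 → 16 → D` where `D` is the total one-hot
  width. ReLU hidden activations; dropout 0.2 after each hidden layer
  during training only; logistic output so binary cross-entropy on {0,1}
  targets is well defined (the loss fixes the output activation even
  though recipes often leave it implicit). Construction refuses any
  configuration whose widest hidden layer is not strictly below `D`: an
  overcomplete "autoencoder" can learn the identity and its reconstruction
  error stops being an anomaly signal.
- **Training.** Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8 — auxiliary
  hyperparameters at their conventional defaults), mini-batches of 32 with
  a fresh seeded shuffle each epoch (last batch may be smaller), 20 epochs,
  no validation split, no early stopping, no input normalization beyond
  one-hot. Weights are fan-in-scaled Gaussian (`√(2/fan_in)` for ReLU
  layers, reduced for the output layer) from the same seeded generator.
  The loss trace records the per-epoch mean.
- **Score.** Mean per-column binary cross-entropy between the row and its
  reconstruction, dropout disabled, probabilities clipped to
  `[1e-7, 1−1e-7]` inside the logs. Mean (rather than sum) keeps scores
  comparable across schemas of different width.
- **Determinism.** The implementation is plain numpy; a fixed
  (seed, config, input) triple reproduces parameters and scores bit-for-bit
  on a given platform. `score_table_ae` presents rows to the trainer in
  ascending row-id order, so scores are keyed by record identity and are
  invariant to the incidental row order of the table.

## Synthetic cohorts

The generator emulates the statistical structure screening relies on, not
clinical coding itself (tokens are synthetic strings like `ICD_24`,
`M1_0`).

- **Study conditions (defaults).** 20,000 records; stratum mix breast 54%,
  colorectal 34%, prostate 12%; implausibility rates 2% / 18% / 8% per
  stratum; 16 variables with domain sizes from 3 (sex, staging prefixes)
  to 127 (morphology).
- **Dependency rules** are decidable predicates over a single record:
  prostate-class ICD ⇒ male sex; topography and ICD must indicate the same
  localization; in-situ T stage ⇒ node-negative N and M0; metastasis site
  ⇔ TNM-M class (M1 needs a site, M0 forbids one, MX unconstrained). Every
  stratum admits rule-consistent records by construction.
- **Distributions.** Only ICD, topography, sex, and morphology carry the
  stratum signature; the remaining variables share one front-loaded
  distribution (a dominant token plus a geometric tail) across strata.
  This mirrors real registries — per-localization ICD and topography are
  nearly one dominant code, while grading, prefixes, and staging dominants
  are common to all localizations — and it realizes the premise both
  scorers need: normal records share frequent cross-variable combinations.
  An earlier draft that gave every stratum its own dominant tokens for all
  16 variables made stratum rarity dominate the FPOF ranking instead of
  implausibility; the current structure is the deliberate fix, chosen on
  modeling grounds.
- **Implants.** Implausibility is implanted post hoc on rule-consistent
  records: a rule-participating variable is resampled to a token that
  newly violates between 1 and `n_break` rules (default exactly 1),
  candidates tried in seeded random order. Ground truth is therefore exact
  and auditable by `check_rules`; labels are implausible iff at least one
  rule is violated.
- **What passing tests do not show.** Real implausibility has error modes
  the rule set does not model (free-text miscodings, temporal
  inconsistencies, linkage errors), real marginals are unpublished, and
  real expert labels carry reviewer variance. Synthetic results establish
  that the scorers recover *dependency-violating* anomalies under a
  realistic frequency structure, not that real-data precision will match
  any particular value.

## Evaluation harness

- **Canonical ranking.** Rank 1 = most anomalous, regardless of the
  scorer's orientation (FPOF is rank-reversed); ties break by ascending
  row id, so every downstream metric is reproducible.
- **Exact intervals.** Clopper–Pearson via the beta-quantile closed form,
  equal α/2 tails; `lower = 0` at `k = 0`, `upper = 1` at `k = n`. Tests
  verify it against an independent root-finding inversion of the binomial
  tail sums. The maximum 95% width at n = 300 is ≈ 0.116 ≤ 0.12, which is
  the design argument for 300-record review samples.
- **Sensitivity/specificity** are computed by thresholding a ranking at
  `k` on a fully labeled sample (in the standard design, the random
  baseline sample); with a label file covering only selected records,
  dataset-wide confusion metrics are unavailable and the harness computes
  them on the labeled sample only.
- **Report tables** keep fractions at full precision; integer percentages
  are a display concern.

## Problem sizes

Unit and property tests run on tables of up to a few thousand rows;
brute-force oracle comparisons use ≤ 30 rows × ≤ 6 variables where
exhaustive pattern enumeration is exact. The end-to-end anomaly-recovery
check and the acceptance script use the full default conditions (20,000
records, 300-record selections, five seeds for the recovery check); one
such run takes on the order of ten seconds.

## Known limitations

- Single-record screening only: no record linkage, no longitudinal or
  event-sequence implausibility.
- The rule set is illustrative, not a clinical rule base; no automatic
  correction of violations.
- The autoencoder recipe is fixed; no hyperparameter search, embeddings,
  or alternative deep scorers.
- Initialization randomness is exposed (seed) but not studied beyond the
  multi-seed recovery checks.
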