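# plauscheck

Unsupervised screening of **implausible categorical health records** — the
kind of quality-control problem cancer registries face: each tumor record is
a row of 16 categorical variables (ICD code, topography, morphology, TNM
staging, sex, binned ages, …), every single value may be valid, and yet the
*combination* contradicts medical knowledge (a female sex token on a
prostate-tumor record). Labeled error sets are rare and unrepresentative, so
screening must work without supervision: score every record for
anomalousness, hand the top of the ranking to domain experts, and hope the
short list concentrates far more implausible records than a random sample
would.

`plauscheck` implements two complementary scorers, a synthetic cohort
generator with exact rule-based ground truth, and the full ranking
evaluation harness.

## Methods

**FindFPOF.** A *pattern* assigns at most one value per variable; it matches
a record containing all of its values. With frequent patterns defined by a
maximal length (default 5) and a minimal dataset frequency (default 10%),
the Frequent Pattern Outlier Factor of record *r* is

```
FPOF(r) = Σ_{p ∈ FPS, p matches r} freq(p) / |FPS|
```

Normal records share many frequent value combinations and score high;
anomalies score low. Mining is level-wise Apriori over packed bitsets,
extending only frequent patterns (support anti-monotonicity).

**Autoencoder.** Records are one-hot encoded (one binary column per domain
token) and compressed through an undercomplete network
`D → 16 → 8 → 16 → D` with ReLU hidden units, dropout 0.2 after each hidden
layer, a logistic output, and binary cross-entropy loss, trained with Adam
(lr 0.001, batches of 32, 20 epochs) on the full table. The anomaly score of
a record is its mean per-column reconstruction cross-entropy; high scores
mark anomalies. The network is plain numpy, bit-reproducible from its seed.

**Evaluation.** Scores become a canonical ranking (rank 1 = most anomalous,
row-id tie-break). For the top-*n* selections of each method and a random
baseline the harness computes precision@n with exact Clopper–Pearson 95%
intervals, sensitivity/specificity sweeps obtained by thresholding the
ranking at *k* on a fully labeled random sample, ROC and
precision–sensitivity point sets, overlap accounting between samples,
per-stratum selection shares, distinct-value diversity of the found
implausible records, and cross-ranking coverage depths.

**Synthetic cohorts.** Because real registry extracts are restricted, the
generator emulates their structure: three strata (breast 54%, colorectal
34%, prostate 12%), 16 categorical variables with 3–127 values each, skewed
stratum-conditional distributions, and implausibility implanted by breaking
one of an explicit set of dependency rules (sex↔ICD, topography↔ICD, TNM
internal consistency, metastasis↔TNM-M) at per-stratum rates of 2% / 18% /
8%. Ground truth is exact: a record is implausible iff the rule checker
reports a violation.

## Worked example

The classic three-record toy — (Male, Prostate), (Female, Prostate),
(Male, Breast) — with frequent patterns of length 1:

```python
>>> import pandas as pd
>>> from plauscheck import *
>>> schema = [VariableSchema("sex", ("Male", "Female")),
...           VariableSchema("localization", ("Prostate", "Breast"))]
>>> table = RecordTable(schema, pd.DataFrame(
...     {"sex": ["Male", "Female", "Male"],
...      "localization": ["Prostate", "Prostate", "Breast"]}, dtype=str))
>>> fps = mine_frequent_patterns(table, FPOFParams(max_length=1, min_frequency=1e-9))
>>> len(fps)
4
>>> [round(fpof_score(table.row(i), fps), 4) for i in range(3)]
[0.3333, 0.25, 0.25]
```

Four frequent patterns ({Male}, {Female}, {Prostate}, {Breast} with
frequencies 2/3, 1/3, 2/3, 1/3); the common record scores 1/3 and the two
rare records 1/4 each, so both rank as most anomalous — exactly what a
screening tool should surface.

An end-to-end run from the shell:

```
$ plauscheck run --n-records 20000 --seed 1 --n-select 300 --outdir out/
findfpof: precision 0.210 (63/300), 95% CI [0.165, 0.261]
autoencoder: precision 0.363 (109/300), 95% CI [0.309, 0.421]
random: precision 0.107 (32/300), 95% CI [0.074, 0.147]
```

Both scorers concentrate implausible records about 2–3.5× above the random
baseline, and the written report (`out/report.json`) shows they over-select
the colorectal stratum, whose implausibility rate is highest — the expected
behavior of a well-functioning screening method. `plauscheck generate`,
`score`, and `evaluate` expose the individual stages for file-based
workflows.

## Layout

| module | contents |
| --- | --- |
| `plauscheck.records` | schema-aware tables, CSV/schema I/O, equal-count binning, missing-fill, dedup |
| `plauscheck.synthetic` | rule set, cohort generator, violation implants, label files |
| `plauscheck.findfpof` | pattern matching/frequency, Apriori mining, FPOF scoring |
| `plauscheck.autoencoder` | one-hot layout, numpy MLP autoencoder, reconstruction error |
| `plauscheck.evaluation` | rankings, selections, precision/CI, ROC, overlap, strata, coverage |
| `plauscheck.cli` | `ExperimentConfig`, `run_experiment`, the `plauscheck` command |

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
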