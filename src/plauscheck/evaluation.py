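"""Ranking evaluation harness for anomaly-based plausibility screening.

Scores from any method become a canonical anomaly ranking (rank 1 = most
anomalous, deterministic row-id tie-break).  Selection samples (top-n or a
uniform random baseline) are evaluated against plausibility ground truth:
precision@n with exact Clopper–Pearson binomial confidence intervals,
sensitivity/specificity sweeps obtained by thresholding a ranking at k, ROC
and precision–sensitivity point sets, overlap accounting between samples,
per-stratum selection/implausibility tables, distinct-value diversity
tables, and cross-ranking coverage depths (how deep one method's ranking
must be searched to recover the implausible records another method found).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .findfpof import AnomalyScores
from .records import RecordTable


class LabelingError(ValueError):
    """A queried row id has no plausibility label."""


class MetricUndefinedError(ValueError):
    """A confusion metric is undefined (empty positive or negative class)."""


# ---------------------------------------------------------------------------
# Rankings and selections
# ---------------------------------------------------------------------------


@dataclass
class AnomalyRanking:
    """Total order from most to least anomalous.

    ``order`` lists row ids most-anomalous-first; ``ranks`` maps row id to
    rank (1 = most anomalous).
    """

    order: np.ndarray
    scores: AnomalyScores

    @property
    def n(self) -> int:
        return len(self.order)

    @property
    def ranks(self) -> pd.Series:
        return pd.Series(np.arange(1, self.n + 1), index=self.order)

    def restrict(self, row_ids: Sequence) -> "AnomalyRanking":
        """The induced ranking on a subset of rows (order preserved)."""
        keep = set(row_ids)
        sub_order = np.array([r for r in self.order if r in keep])
        sub_scores = AnomalyScores(
            self.scores.scores.loc[sub_order],
            self.scores.orientation,
            self.scores.method,
        )
        return AnomalyRanking(sub_order, sub_scores)


def rank_records(scores: AnomalyScores) -> AnomalyRanking:
    """Sort by anomalousness under the declared orientation.

    Low-is-anomalous scores sort ascending, high-is-anomalous descending;
    ties break by ascending row id, so rankings are reproducible.
    """
    s = scores.scores
    if len(s) == 0:
        raise ValueError("cannot rank empty scores")
    vals = s.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("scores must be finite")
    key = vals if scores.orientation == "low" else -vals
    idx = np.lexsort((np.asarray(s.index), key))
    return AnomalyRanking(s.index.to_numpy()[idx], scores)


@dataclass
class SelectionSample:
    """A named set of selected row ids."""

    method: str
    row_ids: np.ndarray

    def __post_init__(self) -> None:
        self.row_ids = np.asarray(self.row_ids)
        if len(set(self.row_ids.tolist())) != len(self.row_ids):
            raise ValueError(f"sample {self.method!r} contains duplicate row ids")

    @property
    def n(self) -> int:
        return len(self.row_ids)


def select_top(ranking: AnomalyRanking, n: int) -> SelectionSample:
    """The n most anomalous records of a ranking."""
    if not 1 <= n <= ranking.n:
        raise ValueError(f"n={n} outside 1..{ranking.n}")
    return SelectionSample(ranking.scores.method, ranking.order[:n].copy())


def select_random(table: RecordTable, n: int, seed: int) -> SelectionSample:
    """Uniform sample of n rows without replacement, reproducible from seed."""
    if n > table.n_rows:
        raise ValueError(f"n={n} exceeds table size {table.n_rows}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(table.row_ids, size=n, replace=False)
    return SelectionSample("random", chosen)


# ---------------------------------------------------------------------------
# Truth labels and confusion metrics
# ---------------------------------------------------------------------------


@dataclass
class TruthLabels:
    """Plausibility ground truth; ``implausible`` is the positive class."""

    implausible: pd.Series  # bool, indexed by row_id

    @classmethod
    def from_plausible(cls, plausible: Sequence[bool], row_ids: Sequence) -> "TruthLabels":
        return cls(pd.Series(~np.asarray(plausible, dtype=bool), index=row_ids))

    def lookup(self, row_ids: Sequence) -> np.ndarray:
        missing = [r for r in row_ids if r not in self.implausible.index]
        if missing:
            raise LabelingError(f"no label for row ids {missing[:5]}")
        return self.implausible.loc[list(row_ids)].to_numpy(dtype=bool)

    @property
    def n_positive(self) -> int:
        return int(self.implausible.sum())


def precision_at(sample: SelectionSample, truth: TruthLabels) -> float:
    """Fraction of truly implausible records in a selection sample."""
    flags = truth.lookup(sample.row_ids)
    return float(flags.sum()) / sample.n


def precision_curve(
    ranking: AnomalyRanking, truth: TruthLabels, max_n: int
) -> list[tuple[int, float]]:
    """precision@n for n = 1..max_n along the canonical order."""
    if not 1 <= max_n <= ranking.n:
        raise ValueError(f"max_n={max_n} outside 1..{ranking.n}")
    flags = truth.lookup(ranking.order[:max_n])
    cum = np.cumsum(flags)
    return [(n, cum[n - 1] / n) for n in range(1, max_n + 1)]


def binary_labels_at_k(ranking: AnomalyRanking, k: int) -> pd.Series:
    """Top-k predicted anomalous, the rest predicted normal."""
    if not 0 <= k <= ranking.n:
        raise ValueError(f"k={k} outside 0..{ranking.n}")
    pred = np.zeros(ranking.n, dtype=bool)
    pred[:k] = True
    return pd.Series(pred, index=ranking.order)


def sensitivity_specificity(
    predicted: pd.Series, truth: TruthLabels
) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) with implausible as the positive class."""
    actual = truth.lookup(predicted.index)
    pred = predicted.to_numpy(dtype=bool)
    P = int(actual.sum())
    N = len(actual) - P
    if P == 0:
        raise MetricUndefinedError("sensitivity undefined: no implausible records")
    if N == 0:
        raise MetricUndefinedError("specificity undefined: no plausible records")
    tp = int((pred & actual).sum())
    tn = int((~pred & ~actual).sum())
    return tp / P, tn / N


def ranking_curves(
    ranking: AnomalyRanking, truth: TruthLabels
) -> tuple[np.ndarray, np.ndarray]:
    """ROC and precision–sensitivity point sets over the full k sweep.

    Returns ``(roc, ps)`` where roc rows are (k, 1−specificity, sensitivity)
    for k = 0..n and ps rows are (k, sensitivity, precision) for k = 1..n.
    """
    actual = truth.lookup(ranking.order)
    P = int(actual.sum())
    N = len(actual) - P
    if P == 0 or N == 0:
        raise MetricUndefinedError("both classes must be present")
    tp = np.concatenate(([0], np.cumsum(actual)))
    ks = np.arange(ranking.n + 1)
    fp = ks - tp
    sens = tp / P
    fpr = fp / N
    roc = np.column_stack((ks, fpr, sens))
    prec = tp[1:] / ks[1:]
    ps = np.column_stack((ks[1:], sens[1:], prec))
    return roc, ps


def roc_auc(roc: np.ndarray) -> float:
    """Trapezoid-rule area under an ROC point set from :func:`ranking_curves`."""
    return float(np.trapezoid(roc[:, 2], roc[:, 1]))


# ---------------------------------------------------------------------------
# Exact binomial confidence interval
# ---------------------------------------------------------------------------


def exact_binomial_ci(
    k: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Two-sided exact (Clopper–Pearson) binomial interval for a proportion.

    Obtained by inverting the binomial tail probabilities at α/2 per side;
    the bounds are the standard beta-quantile closed form.  ``lower = 0``
    when k = 0 and ``upper = 1`` when k = n.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"invalid k={k}, n={n}")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0,1)")
    alpha = 1.0 - confidence
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def max_ci_width(n: int, confidence: float = 0.95) -> float:
    """Maximum Clopper–Pearson interval width over all k for fixed n.

    Used to size a labeling sample before the number of implausible records
    is known.
    """
    widths = [
        u - l for k in range(n + 1) for l, u in [exact_binomial_ci(k, n, confidence)]
    ]
    return max(widths)


# ---------------------------------------------------------------------------
# Overlap, strata, diversity, coverage
# ---------------------------------------------------------------------------


@dataclass
class OverlapReport:
    """Membership accounting across selection samples."""

    multiplicity: dict[int, int]        # m -> #row_ids in exactly m samples
    pairwise: dict[tuple[str, str], int]
    union_size: int

    @property
    def total_selected(self) -> int:
        return sum(m * c for m, c in self.multiplicity.items())


def overlap_counts(samples: Sequence[SelectionSample]) -> OverlapReport:
    """Partition selected row ids by how many samples contain them."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    counts: dict = {}
    for s in samples:
        for r in s.row_ids.tolist():
            counts[r] = counts.get(r, 0) + 1
    multiplicity: dict[int, int] = {m: 0 for m in range(1, len(samples) + 1)}
    for m in counts.values():
        multiplicity[m] += 1
    pairwise = {}
    for a, b in combinations(samples, 2):
        pairwise[(a.method, b.method)] = len(
            set(a.row_ids.tolist()) & set(b.row_ids.tolist())
        )
    return OverlapReport(multiplicity, pairwise, len(counts))


def stratum_table(
    samples: Sequence[SelectionSample],
    truth: TruthLabels,
    strata: pd.Series,
) -> pd.DataFrame:
    """Per-sample × per-stratum selection and implausibility counts.

    For each sample and stratum (plus "all"): the selected count n, its share
    of the sample, the implausible count, and the within-stratum precision.
    Fractions are kept at full precision; round for display.
    """
    rows = []
    stratum_values = sorted(set(strata))
    for sample in samples:
        ids = list(sample.row_ids)
        missing = [r for r in ids if r not in strata.index]
        if missing:
            raise LabelingError(f"no stratum for row ids {missing[:5]}")
        s_strat = strata.loc[ids]
        s_impl = truth.lookup(ids)
        for name in ["all", *stratum_values]:
            mask = np.ones(len(ids), dtype=bool) if name == "all" else (
                s_strat.to_numpy() == name
            )
            n_sel = int(mask.sum())
            n_impl = int(s_impl[mask].sum())
            rows.append(
                {
                    "sample": sample.method,
                    "stratum": name,
                    "n": n_sel,
                    "share": n_sel / sample.n,
                    "n_implausible": n_impl,
                    "precision": (n_impl / n_sel) if n_sel else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def distinct_values_table(subset: RecordTable) -> pd.Series:
    """Number of distinct observed tokens per variable in a record subset."""
    return pd.Series(
        {v: int(subset.data[v].nunique()) for v in subset.variables}, name="n_distinct"
    )


def cross_rank_coverage(target_ids: Sequence, other_ranking: AnomalyRanking) -> int:
    """Minimal selection depth of a ranking that covers all target rows.

    Equals the worst (largest) canonical rank among the targets: how many
    top-ranked records one would need to review under ``other_ranking`` to
    find every record in ``target_ids``.
    """
    targets = list(target_ids)
    if not targets:
        raise ValueError("target set is empty")
    ranks = other_ranking.ranks
    missing = [t for t in targets if t not in ranks.index]
    if missing:
        raise ValueError(f"targets not in ranking: {missing[:5]}")
    return int(ranks.loc[targets].max())
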