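"""Frequent-pattern mining and the Frequent Pattern Outlier Factor (FPOF).

A pattern assigns at most one value token per variable; its length is the
number of assignments, and it matches a record that carries all of them.
Frequent patterns are those with length ≤ ``max_length`` and dataset
frequency ≥ ``min_frequency`` (inclusive at the boundary).  The FPOF of a
record is the mean, over all frequent patterns, of the frequencies of those
that match it:

    FPOF(r) = Σ_{p frequent, p matches r} freq(p) / |frequent patterns|

Normal records share many frequent value combinations and score high;
anomalies score low.  Mining is level-wise Apriori over packed bitsets,
extending a pattern only when it is frequent (support anti-monotonicity),
with a canonical enumeration order (variables in schema order, tokens in
domain order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import RecordTable


class UndefinedFrequencyError(ValueError):
    """Pattern frequency is undefined on an empty table."""


class UndefinedScoreError(ValueError):
    """FPOF is undefined for an empty frequent-pattern set."""


@dataclass(frozen=True)
class FPOFParams:
    """Mining thresholds: maximal pattern length and minimal frequency.

    The defaults (length ≤ 5, frequency ≥ 10%) are the standard operating
    point for FPOF on registry-scale categorical data.
    """

    max_length: int = 5
    min_frequency: float = 0.10

    def __post_init__(self) -> None:
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")
        if not 0.0 <= self.min_frequency:
            raise ValueError("min_frequency must be >= 0")


@dataclass(frozen=True)
class Pattern:
    """A value combination: at most one token per variable.

    ``assignments`` is a tuple of (variable, token) pairs in schema order.
    """

    assignments: tuple[tuple[str, str], ...]

    @property
    def length(self) -> int:
        return len(self.assignments)

    def matches(self, record: Mapping[str, str]) -> bool:
        return all(record[var] == token for var, token in self.assignments)

    def __str__(self) -> str:
        return ";".join(f"{v}={t}" for v, t in self.assignments)


def pattern_matches(pattern: Pattern, record: Mapping[str, str]) -> bool:
    """True iff the record carries every token the pattern assigns."""
    return pattern.matches(record)


def pattern_frequency(pattern: Pattern, table: RecordTable) -> float:
    """Fraction of records in the table matched by the pattern."""
    if table.n_rows == 0:
        raise UndefinedFrequencyError("frequency undefined on an empty table")
    hits = sum(
        1 for _, rec in table.iter_rows() if pattern.matches(rec)
    )
    return hits / table.n_rows


@dataclass
class FrequentPatternSet:
    """All frequent patterns of a table with their exact frequencies."""

    patterns: list[Pattern]
    counts: np.ndarray
    n_records: int
    params: FPOFParams

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_records

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[tuple[Pattern, float]]:
        return iter(zip(self.patterns, self.frequencies))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pattern": [str(p) for p in self.patterns],
                "length": [p.length for p in self.patterns],
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


@dataclass
class AnomalyScores:
    """Per-record anomaly scores with a declared orientation.

    ``orientation`` is ``"low"`` when low scores mark anomalies (FPOF) and
    ``"high"`` when high scores do (reconstruction error).
    """

    scores: pd.Series
    orientation: str
    method: str

    def __post_init__(self) -> None:
        if self.orientation not in ("low", "high"):
            raise ValueError("orientation must be 'low' or 'high'")

    def write_csv(self, path) -> None:
        frame = pd.DataFrame(
            {"row_id": self.scores.index, "score": self.scores.to_numpy()}
        )
        frame.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Mining
# ---------------------------------------------------------------------------


def _min_count(min_frequency: float, n: int) -> int:
    """Smallest support count whose frequency is >= min_frequency.

    Inclusive at the boundary (a pattern at exactly the threshold is
    frequent); never below 1, so unobserved patterns are excluded.
    """
    c = math.ceil(min_frequency * n - 1e-9)
    return max(1, c)


def _mine(
    table: RecordTable,
    params: FPOFParams,
    accumulate: np.ndarray | None = None,
) -> FrequentPatternSet:
    """Level-wise Apriori over packed bitsets.

    If ``accumulate`` is given (float vector of length n_rows), each frequent
    pattern's frequency is added to the rows it matches as patterns are
    confirmed, so FPOF numerators come out of a single mining pass.
    """
    n = table.n_rows
    if n == 0:
        raise UndefinedFrequencyError("cannot mine an empty table")
    codes = table.codes()
    n_vars = codes.shape[1]
    minc = _min_count(params.min_frequency, n)

    names = table.variables
    domains = [v.domain for v in table.schema]

    def emit(mask_packed: np.ndarray, count: int, freq_acc_weight: float) -> None:
        if accumulate is not None:
            bits = np.unpackbits(mask_packed)[:n].astype(bool)
            accumulate[bits] += freq_acc_weight

    patterns: list[Pattern] = []
    counts: list[int] = []

    # level 1: singleton patterns in canonical (variable, token) order
    level: list[tuple[tuple[tuple[int, int], ...], np.ndarray]] = []
    singles: dict[int, list[tuple[int, np.ndarray]]] = {}
    for j in range(n_vars):
        singles[j] = []
        col = codes[:, j]
        for t in range(len(domains[j])):
            mask = col == t
            count = int(mask.sum())
            if count >= minc:
                packed = np.packbits(mask)
                singles[j].append((t, packed))
                key = ((j, t),)
                patterns.append(Pattern(((names[j], domains[j][t]),)))
                counts.append(count)
                emit(packed, count, count / n)
                level.append((key, packed))

    # levels 2..max_length: extend by frequent singletons of later variables
    length = 1
    while level and length < params.max_length:
        next_level: list[tuple[tuple[tuple[int, int], ...], np.ndarray]] = []
        for key, packed in level:
            last_var = key[-1][0]
            for j in range(last_var + 1, n_vars):
                for t, item_packed in singles[j]:
                    cand = packed & item_packed
                    count = int(np.bitwise_count(cand).sum())
                    if count >= minc:
                        new_key = key + ((j, t),)
                        patterns.append(
                            Pattern(
                                tuple((names[v], domains[v][c]) for v, c in new_key)
                            )
                        )
                        counts.append(count)
                        emit(cand, count, count / n)
                        next_level.append((new_key, cand))
        level = next_level
        length += 1

    return FrequentPatternSet(
        patterns, np.asarray(counts, dtype=np.int64), n, params
    )


def mine_frequent_patterns(table: RecordTable, params: FPOFParams | None = None) -> FrequentPatternSet:
    """All patterns with length ≤ max_length and frequency ≥ min_frequency.

    Enumeration order is canonical: pattern length ascending, then variables
    in schema order and tokens in domain order.  Each pattern carries its
    exact support count.
    """
    if params is None:
        params = FPOFParams()
    return _mine(table, params)


def fpof_score(record: Mapping[str, str], fps: FrequentPatternSet) -> float:
    """FPOF of a single record against a mined frequent-pattern set."""
    if len(fps) == 0:
        raise UndefinedScoreError("FPOF undefined for an empty frequent-pattern set")
    total = sum(f for p, f in fps if p.matches(record))
    return total / len(fps)


def score_table_fpof(
    table: RecordTable, params: FPOFParams | None = None
) -> tuple[AnomalyScores, FrequentPatternSet]:
    """Mine once on the full table and score every record.

    Returns low-is-anomalous scores keyed by row id, plus the mined
    frequent-pattern set.  Frequencies include the scored record itself (the
    table is both the mining corpus and the scored population).
    """
    if params is None:
        params = FPOFParams()
    acc = np.zeros(table.n_rows, dtype=float)
    fps = _mine(table, params, accumulate=acc)
    if len(fps) == 0:
        raise UndefinedScoreError("no frequent patterns at these thresholds")
    scores = pd.Series(acc / len(fps), index=table.data.index)
    return AnomalyScores(scores, orientation="low", method="findfpof"), fps
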