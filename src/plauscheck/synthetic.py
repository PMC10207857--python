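"""Synthetic labeled registry cohorts with rule-based implausibility.

Real tumor-registry records cannot be redistributed, so this module generates
cohorts with the statistical structure that plausibility screening relies on:
records are stratified by tumor localization (breast, colorectal, prostate),
variables within a stratum follow skewed conditional distributions (so normal
records share frequent value combinations), and a small configurable fraction
of records is made implausible by breaking an explicit cross-variable
dependency rule — the archetype being a female sex token on a prostate-tumor
record.

Ground truth is exact and auditable: a record is labeled implausible if and
only if :func:`check_rules` reports at least one violated rule.

Value tokens are synthetic strings (``ICD_07``, ``M1_2``, …); no attempt is
made to emit clinically valid ICD or TNM codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import MISSING_TOKEN, RecordTable, VariableSchema

STRATA = ("breast", "colorectal", "prostate")

#: Default stratum mix of the cohort (fractions of records).
DEFAULT_STRATUM_PROPORTIONS = {"breast": 0.54, "colorectal": 0.34, "prostate": 0.12}

#: Default per-stratum implausibility rates.
DEFAULT_IMPLAUSIBILITY_RATES = {"breast": 0.02, "colorectal": 0.18, "prostate": 0.08}


class GenerationError(ValueError):
    """The generator configuration or rule set does not admit a cohort."""


class ImplantationError(GenerationError):
    """No single-variable substitution can produce the requested violation."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

# Variables whose domains are wired into the dependency rules (fixed size).
_RULE_BOUND_SIZES = {
    "tnm_t": 47,
    "tnm_n": 35,
    "icd10_code": 30,
    "icd_o_topography": 23,
    "metastasis": 12,
    "tnm_m": 11,
    "sex": 3,
}

# Rule-free variables: domain sizes may be overridden via schema_spec.
_FREE_SIZES = {
    "icd_o_morphology": 127,
    "grading": 11,
    "diagnosis_assurance": 7,
    "lateral_localization": 6,
    "cprefix_n": 5,
    "diagnosis_age": 5,
    "age_at_death": 5,
    "cprefix_t": 3,
    "cprefix_m": 3,
}

_SCHEMA_ORDER = (
    "icd_o_morphology",
    "tnm_t",
    "tnm_n",
    "icd10_code",
    "icd_o_topography",
    "tnm_m",
    "metastasis",
    "grading",
    "diagnosis_assurance",
    "lateral_localization",
    "cprefix_n",
    "diagnosis_age",
    "age_at_death",
    "sex",
    "cprefix_t",
    "cprefix_m",
)

_AGE_BINS = ("[18,50)", "[50,60)", "[60,68)", "[68,76)", "[76,99]")
_DEATH_BINS = ("[40,60)", "[60,70)", "[70,80)", "[80,90)", "[90,105]")

# ICD-10 stand-in codes are partitioned by stratum (disjoint subsets).
_ICD_SETS = {
    "breast": tuple(f"ICD_{i:02d}" for i in range(0, 13)),
    "colorectal": tuple(f"ICD_{i:02d}" for i in range(13, 24)),
    "prostate": tuple(f"ICD_{i:02d}" for i in range(24, 30)),
}
# Topography stand-ins, partitioned the same way.
_TOPO_SETS = {
    "breast": tuple(f"TOPO_{i:02d}" for i in range(0, 9)),
    "colorectal": tuple(f"TOPO_{i:02d}" for i in range(9, 18)),
    "prostate": tuple(f"TOPO_{i:02d}" for i in range(18, 23)),
}

_TIS_TOKENS = tuple(f"Tis_{i}" for i in range(5))        # in-situ T stage
_T_TOKENS = tuple(f"T_{i:02d}" for i in range(42))
_N0_TOKENS = tuple(f"N0_{i}" for i in range(10))         # node-negative
_N_TOKENS = tuple(f"N_{i:02d}" for i in range(25))
_M0_TOKENS = tuple(f"M0_{i}" for i in range(5))          # no remote metastases
_M1_TOKENS = tuple(f"M1_{i}" for i in range(5))          # remote metastases
_MET_SITES = (
    "MET_PUL", "MET_OSS", "MET_HEP", "MET_BRA", "MET_LYM", "MET_MAR",
    "MET_PLE", "MET_PER", "MET_ADR", "MET_SKI", "MET_OTH",
)


def _stratum_of_icd(token: str) -> str | None:
    for s, toks in _ICD_SETS.items():
        if token in toks:
            return s
    return None


def _stratum_of_topo(token: str) -> str | None:
    for s, toks in _TOPO_SETS.items():
        if token in toks:
            return s
    return None


@dataclass(frozen=True)
class Rule:
    """A decidable plausibility predicate over a single record.

    ``predicate`` returns True when the record is consistent with the rule.
    ``variables`` lists the variables the rule reads (candidates for
    violation implants).
    """

    name: str
    description: str
    variables: tuple[str, ...]
    predicate: Callable[[Mapping[str, str]], bool]

    def holds(self, record: Mapping[str, str]) -> bool:
        return bool(self.predicate(record))


@dataclass(frozen=True)
class DependencyRuleSet:
    rules: tuple[Rule, ...]

    def check(self, record: Mapping[str, str]) -> list[Rule]:
        """Return exactly the rules violated by the record (empty = plausible)."""
        return [r for r in self.rules if not r.holds(record)]

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)


def check_rules(record: Mapping[str, str], rules: DependencyRuleSet) -> list[Rule]:
    """List the rules whose predicate is false on the record."""
    return rules.check(record)


def _build_rules() -> DependencyRuleSet:
    def sex_vs_icd(rec: Mapping[str, str]) -> bool:
        # prostate tumors occur in males only
        if rec["icd10_code"] in _ICD_SETS["prostate"]:
            return rec["sex"] == "SEX_M"
        return True

    def topo_vs_icd(rec: Mapping[str, str]) -> bool:
        s_icd = _stratum_of_icd(rec["icd10_code"])
        s_topo = _stratum_of_topo(rec["icd_o_topography"])
        if s_icd is None or s_topo is None:
            return True  # sentinel token: not checkable
        return s_icd == s_topo

    def tnm_internal(rec: Mapping[str, str]) -> bool:
        # an in-situ tumor cannot have nodal or remote spread
        if rec["tnm_t"] in _TIS_TOKENS:
            return rec["tnm_n"] in _N0_TOKENS and rec["tnm_m"] in _M0_TOKENS
        return True

    def metastasis_vs_m(rec: Mapping[str, str]) -> bool:
        m = rec["tnm_m"]
        if m in _M1_TOKENS:
            return rec["metastasis"] != "MET_NONE"
        if m in _M0_TOKENS:
            return rec["metastasis"] == "MET_NONE"
        return True  # MX: unknown, unconstrained

    return DependencyRuleSet(
        (
            Rule(
                "sex_vs_icd",
                "prostate-class ICD code requires male sex",
                ("sex", "icd10_code"),
                sex_vs_icd,
            ),
            Rule(
                "topography_vs_icd",
                "topography must belong to the same localization as the ICD code",
                ("icd_o_topography", "icd10_code"),
                topo_vs_icd,
            ),
            Rule(
                "tnm_internal",
                "in-situ T stage requires node-negative N and M0",
                ("tnm_t", "tnm_n", "tnm_m"),
                tnm_internal,
            ),
            Rule(
                "metastasis_vs_m",
                "metastasis site must be consistent with the TNM-M class",
                ("metastasis", "tnm_m"),
                metastasis_vs_m,
            ),
        )
    )


def default_schema_and_rules(
    schema_spec: Mapping[str, int] | None = None,
) -> tuple[list[VariableSchema], DependencyRuleSet]:
    """The built-in 16-variable schema (domain sizes 3–127) and rule set.

    ``schema_spec`` may override the domain size of rule-free variables;
    rule-bound variables (sex, ICD, topography, TNM, metastasis) are fixed
    because the dependency rules are written against their domains.
    """
    sizes = dict(_FREE_SIZES)
    if schema_spec:
        for name, size in schema_spec.items():
            if name in _RULE_BOUND_SIZES:
                if size != _RULE_BOUND_SIZES[name]:
                    raise GenerationError(
                        f"variable {name!r} is rule-bound; its domain size is fixed "
                        f"at {_RULE_BOUND_SIZES[name]}"
                    )
            elif name in sizes:
                if size < 2:
                    raise GenerationError(f"variable {name!r}: need >= 2 tokens")
                sizes[name] = int(size)
            else:
                raise GenerationError(f"unknown variable {name!r} in schema_spec")

    domains: dict[str, tuple[str, ...]] = {
        "icd_o_morphology": tuple(f"MORPH_{i:03d}" for i in range(sizes["icd_o_morphology"])),
        "tnm_t": _TIS_TOKENS + _T_TOKENS,
        "tnm_n": _N0_TOKENS + _N_TOKENS,
        "icd10_code": _ICD_SETS["breast"] + _ICD_SETS["colorectal"] + _ICD_SETS["prostate"],
        "icd_o_topography": _TOPO_SETS["breast"] + _TOPO_SETS["colorectal"] + _TOPO_SETS["prostate"],
        "tnm_m": _M0_TOKENS + _M1_TOKENS + ("MX",),
        "metastasis": ("MET_NONE",) + _MET_SITES,
        "grading": tuple(f"G_{i:02d}" for i in range(sizes["grading"])),
        "diagnosis_assurance": tuple(f"DA_{i}" for i in range(sizes["diagnosis_assurance"])),
        "lateral_localization": tuple(f"LAT_{i}" for i in range(sizes["lateral_localization"])),
        "cprefix_n": tuple(f"CPN_{i}" for i in range(sizes["cprefix_n"])),
        "diagnosis_age": _AGE_BINS if sizes["diagnosis_age"] == 5
        else tuple(f"AGE_{i}" for i in range(sizes["diagnosis_age"])),
        "age_at_death": _DEATH_BINS if sizes["age_at_death"] == 5
        else tuple(f"AAD_{i}" for i in range(sizes["age_at_death"])),
        "sex": ("SEX_F", "SEX_M", "SEX_D"),
        "cprefix_t": tuple(f"CPT_{i}" for i in range(sizes["cprefix_t"])),
        "cprefix_m": tuple(f"CPM_{i}" for i in range(sizes["cprefix_m"])),
    }
    schema = [VariableSchema(name, domains[name]) for name in _SCHEMA_ORDER]
    return schema, _build_rules()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the registry mix the screening study assumes: 54% /
    34% / 12% breast / colorectal / prostate records, with per-stratum
    implausibility rates of 2% / 18% / 8%.
    """

    n_records: int = 20_000
    stratum_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRATUM_PROPORTIONS)
    )
    implausibility_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMPLAUSIBILITY_RATES)
    )
    schema_spec: dict[str, int] | None = None
    seed: int = 0
    n_break: int = 1

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise GenerationError("n_records must be >= 1")
        if set(self.stratum_proportions) != set(STRATA):
            raise GenerationError(f"stratum_proportions must cover {STRATA}")
        total = sum(self.stratum_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"stratum_proportions sum to {total}, expected 1")
        for s, r in self.implausibility_rates.items():
            if not 0.0 <= r <= 1.0:
                raise GenerationError(f"implausibility rate for {s!r} outside [0,1]")
        if self.n_break < 1:
            raise GenerationError("n_break must be >= 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_records": self.n_records,
                "stratum_proportions": self.stratum_proportions,
                "implausibility_rates": self.implausibility_rates,
                "schema_spec": self.schema_spec,
                "seed": self.seed,
                "n_break": self.n_break,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        payload = json.loads(text)
        return cls(**payload)


@dataclass
class LabeledCohort:
    """A synthetic record table plus exact ground truth.

    ``plausible`` and ``stratum`` are aligned with ``table.row_ids``.
    """

    table: RecordTable
    plausible: np.ndarray
    stratum: np.ndarray

    @property
    def implausible_ids(self) -> np.ndarray:
        return self.table.row_ids[~self.plausible]

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row_id": self.table.row_ids,
                "label": np.where(self.plausible, "plausible", "implausible"),
                "stratum": self.stratum,
            }
        )

    def write(self, data_path, labels_path) -> None:
        from .records import write_records

        write_records(self.table, data_path)
        self.labels_frame().to_csv(labels_path, index=False)


def read_labels(path) -> pd.DataFrame:
    """Read a label file (row_id, label ∈ {plausible, implausible}[, stratum])."""
    df = pd.read_csv(path, dtype={"row_id": int, "label": str})
    bad = set(df["label"]) - {"plausible", "implausible"}
    if bad:
        raise ValueError(f"unknown labels in {path}: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Sampling machinery
# ---------------------------------------------------------------------------


def _front_loaded(k: int, top: float, r: float) -> np.ndarray:
    """Skewed categorical weights: mass ``top`` on the first token, the rest
    decaying geometrically with ratio ``r`` — the shape of real registry
    variables, where one code dominates and a long tail of codes is rare."""
    if k == 1:
        return np.array([1.0])
    rest = r ** np.arange(k - 1)
    rest = rest / rest.sum() * (1.0 - top)
    return np.concatenate(([top], rest))


class _CohortSampler:
    """Stratum-conditional sampler producing rule-consistent records.

    Localization-specific variables (ICD code, topography, sex, morphology)
    carry the stratum signature; the remaining variables share one skewed
    distribution across strata, mirroring registry data where dominant
    values of grading, staging prefixes, metastasis status etc. are common
    to all tumor localizations.  The concentration makes cross-variable
    value combinations of normal records frequent, which is the premise both
    anomaly scorers rely on.
    """

    def __init__(self, schema: Sequence[VariableSchema], rules: DependencyRuleSet):
        self.schema = list(schema)
        self.rules = rules
        self.domains = {v.name: v.domain for v in schema}
        # ICD / topography: one dominant code per stratum (e.g. prostate
        # tumors are almost always a single ICD code in real registries)
        self._icd_weights = {
            s: _front_loaded(len(toks), 0.92, 0.5) for s, toks in _ICD_SETS.items()
        }
        self._topo_weights = {
            s: _front_loaded(len(toks), 0.92, 0.5) for s, toks in _TOPO_SETS.items()
        }
        self._sex_weights = {
            "breast": np.array([0.965, 0.030, 0.005]),      # F, M, D
            "colorectal": np.array([0.455, 0.535, 0.010]),
            "prostate": np.array([0.0, 1.0, 0.0]),
        }
        # shared weights for rule-free variables; morphology additionally
        # gets a per-stratum rotation (cell types are localization-specific)
        self._free_weights: dict[str, np.ndarray] = {}
        for name in _FREE_SIZES:
            k = len(self.domains[name])
            if k >= 50:
                self._free_weights[name] = _front_loaded(k, 0.30, 0.93)
            elif k >= 10:
                self._free_weights[name] = _front_loaded(k, 0.55, 0.60)
            else:
                self._free_weights[name] = _front_loaded(k, 0.65, 0.50)
        self._morph_weights = {
            s: np.roll(self._free_weights["icd_o_morphology"], si * 8)
            for si, s in enumerate(STRATA)
        }
        self._t_weights = _front_loaded(len(_T_TOKENS), 0.50, 0.80)
        self._tis_weights = _front_loaded(len(_TIS_TOKENS), 0.80, 0.50)
        self._n_weights = _front_loaded(len(self.domains["tnm_n"]), 0.60, 0.70)
        self._n0_weights = _front_loaded(len(_N0_TOKENS), 0.80, 0.50)
        self._m0_weights = _front_loaded(len(_M0_TOKENS), 0.85, 0.50)
        self._m1_weights = _front_loaded(len(_M1_TOKENS), 0.60, 0.60)
        self._site_weights = _front_loaded(len(_MET_SITES), 0.45, 0.70)

    def _pick(self, rng: np.random.Generator, tokens: Sequence[str],
              weights: np.ndarray) -> str:
        return tokens[rng.choice(len(tokens), p=weights)]

    def sample_plausible(self, stratum: str, rng: np.random.Generator) -> dict[str, str]:
        rec: dict[str, str] = {}
        rec["icd10_code"] = self._pick(rng, _ICD_SETS[stratum], self._icd_weights[stratum])
        rec["icd_o_topography"] = self._pick(
            rng, _TOPO_SETS[stratum], self._topo_weights[stratum]
        )
        rec["sex"] = self.domains["sex"][rng.choice(3, p=self._sex_weights[stratum])]
        # T stage: ~10% in situ (then node-negative and M0 by rule), the
        # rest invasive with skewed stage distributions
        if rng.random() < 0.10:
            rec["tnm_t"] = self._pick(rng, _TIS_TOKENS, self._tis_weights)
            rec["tnm_n"] = self._pick(rng, _N0_TOKENS, self._n0_weights)
            rec["tnm_m"] = self._pick(rng, _M0_TOKENS, self._m0_weights)
        else:
            rec["tnm_t"] = self._pick(rng, _T_TOKENS, self._t_weights)
            rec["tnm_n"] = self._pick(rng, self.domains["tnm_n"], self._n_weights)
            u = rng.random()
            if u < 0.82:
                rec["tnm_m"] = self._pick(rng, _M0_TOKENS, self._m0_weights)
            elif u < 0.92:
                rec["tnm_m"] = self._pick(rng, _M1_TOKENS, self._m1_weights)
            else:
                rec["tnm_m"] = "MX"
        if rec["tnm_m"] in _M1_TOKENS:
            rec["metastasis"] = self._pick(rng, _MET_SITES, self._site_weights)
        elif rec["tnm_m"] == "MX":
            rec["metastasis"] = (
                "MET_NONE" if rng.random() < 0.7
                else self._pick(rng, _MET_SITES, self._site_weights)
            )
        else:
            rec["metastasis"] = "MET_NONE"
        for name in _FREE_SIZES:
            weights = (
                self._morph_weights[stratum]
                if name == "icd_o_morphology"
                else self._free_weights[name]
            )
            rec[name] = self._pick(rng, self.domains[name], weights)
        return {name: rec[name] for name in _SCHEMA_ORDER}


def implant_implausibility(
    record: Mapping[str, str],
    rules: DependencyRuleSet,
    n_break: int,
    rng: np.random.Generator,
    schema: Sequence[VariableSchema] | None = None,
) -> dict[str, str]:
    """Make a rule-consistent record implausible by one token substitution.

    A rule-participating variable is resampled to a token that newly violates
    between 1 and ``n_break`` rules; candidate (variable, token) pairs are
    tried in seeded random order and the first admissible substitution wins.
    Raises :class:`ImplantationError` when no substitution qualifies.
    """
    if rules.check(record):
        raise GenerationError("implant target must satisfy all rules")
    if schema is None:
        schema, _ = default_schema_and_rules()
    domains = {v.name: v.domain for v in schema}

    candidate_vars = sorted({v for r in rules for v in r.variables})
    order = rng.permutation(len(candidate_vars))
    for vi in order:
        var = candidate_vars[vi]
        tokens = [t for t in domains[var] if t != record[var]]
        for ti in rng.permutation(len(tokens)):
            mutated = dict(record)
            mutated[var] = tokens[ti]
            violated = rules.check(mutated)
            if 1 <= len(violated) <= n_break:
                return mutated
    raise ImplantationError("no single-token substitution yields the requested violation")


def generate_cohort(config: GeneratorConfig) -> LabeledCohort:
    """Draw a labeled synthetic cohort; fully reproducible from the seed.

    Each record samples a stratum, then rule-consistent variables from the
    stratum-conditional distributions; with the stratum's implausibility
    rate, a dependency violation is implanted afterwards.
    """
    schema, rules = default_schema_and_rules(config.schema_spec)
    sampler = _CohortSampler(schema, rules)
    rng = np.random.default_rng(config.seed)

    props = np.array([config.stratum_proportions[s] for s in STRATA])
    strata_idx = rng.choice(len(STRATA), size=config.n_records, p=props)

    rows: list[dict[str, str]] = []
    plausible = np.ones(config.n_records, dtype=bool)
    stratum_labels = np.empty(config.n_records, dtype=object)
    for i in range(config.n_records):
        s = STRATA[strata_idx[i]]
        stratum_labels[i] = s
        rec = sampler.sample_plausible(s, rng)
        if rng.random() < config.implausibility_rates[s]:
            rec = implant_implausibility(rec, rules, config.n_break, rng, schema)
            plausible[i] = False
        rows.append(rec)

    data = pd.DataFrame(rows, columns=list(_SCHEMA_ORDER), dtype=str)
    data.index = pd.RangeIndex(config.n_records)
    table = RecordTable(schema, data)
    return LabeledCohort(table, plausible, stratum_labels)
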