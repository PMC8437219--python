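"""Parameter tables for the colorectal cancer screening cohort model.

A :class:`ParamSet` bundles everything the simulator consumes for one
population:

* starting prevalences of colorectal lesions by sex and age band,
* annual transition probabilities along the adenoma--carcinoma sequence,
* screening-test performance (sensitivity per lesion state, specificity),
* mortality inputs: all-cause death probabilities, CRC-specific death
  probabilities by mode of detection and years since diagnosis, and
  remaining life expectancy from life tables.

Parameters live on disk as plain tab-separated tables plus a YAML manifest,
so a parameter set is diffable and editable by hand.  Tables that carry 95%
confidence bounds (prevalences and transition rates) can be resolved under
three variants -- ``point``, ``ci-lower``, ``ci-upper`` -- used by the
sensitivity analyses.  Age bands are half-open ``[lo, hi)``; ages at or above
the last band's upper edge fall back to the last band (explicit extrapolation
for the oldest ages, where source data are sparse).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

AGE_MIN = 45
AGE_MAX = 100
SEXES = ("male", "female")

NO_LESION = "no_lesion"
NONADV_ADENOMA = "nonadvanced_adenoma"
ADV_ADENOMA = "advanced_adenoma"
PRECLIN_CRC = "preclinical_crc"
CLIN_CRC = "clinical_crc"

LESION_STATES = (NONADV_ADENOMA, ADV_ADENOMA, PRECLIN_CRC)
TRANSITIONS = (
    (NO_LESION, NONADV_ADENOMA),
    (NONADV_ADENOMA, ADV_ADENOMA),
    (ADV_ADENOMA, PRECLIN_CRC),
    (PRECLIN_CRC, CLIN_CRC),
)

MODALITIES = ("fit", "colonoscopy")
#: Modes of detection of clinical CRC; they select the CRC-specific
#: mortality schedule.
MODE_SCREEN = "screen"
MODE_SYMPTOM = "symptom"
DETECTION_MODES = (MODE_SCREEN, MODE_SYMPTOM)

VARIANTS = ("point", "ci-lower", "ci-upper")

_TABLE_FILES = {
    "prevalence": "prevalence.tsv",
    "transitions": "transitions.tsv",
    "test_performance": "test_performance.tsv",
    "all_cause_mortality": "all_cause_mortality.tsv",
    "crc_mortality": "crc_mortality.tsv",
    "life_expectancy": "life_expectancy.tsv",
}


class ParamError(ValueError):
    """Raised when a parameter set fails validation."""


def _check_prob(value: float, key: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParamError(f"probability outside [0, 1]: {key} = {value!r}")


def _resolved_column(df: pd.DataFrame, variant: str) -> pd.Series:
    """Point or CI-bound value column; rows without CI bounds keep the point."""
    if variant == "point":
        return df["value"]
    col = {"ci-lower": "ci_lower", "ci-upper": "ci_upper"}[variant]
    if col not in df.columns:
        return df["value"]
    return df[col].fillna(df["value"])


def _band_row(rows: pd.DataFrame, age: float, key: str) -> pd.Series:
    """Row of the half-open band [lo, hi) containing ``age``.

    Ages at or beyond the last band's upper edge extrapolate the last band.
    """
    rows = rows.sort_values("age_lo")
    hit = rows[(rows["age_lo"] <= age) & (age < rows["age_hi"])]
    if len(hit):
        return hit.iloc[0]
    if len(rows) and age >= rows["age_hi"].max():
        return rows.iloc[-1]
    raise ParamError(f"no age band covers age {age} for {key}")


@dataclass(eq=False)
class ParamSet:
    """All natural-history, test-performance and mortality inputs.

    The component tables keep their CI columns untouched; ``variant``
    selects which column feeds the simulator, so writing a ParamSet back to
    disk reproduces every stored number bit-exactly regardless of variant.
    """

    prevalence: pd.DataFrame
    transitions: pd.DataFrame
    test_performance: pd.DataFrame
    all_cause_mortality: pd.DataFrame
    crc_mortality: pd.DataFrame
    life_expectancy: pd.DataFrame
    ysd_cap: int = 14
    source: str = "unspecified"
    variant: str = "point"

    # -- variant handling -------------------------------------------------

    def with_variant(self, variant: str) -> "ParamSet":
        if variant not in VARIANTS:
            raise ParamError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        ps = replace(self, variant=variant)
        ps.validate()
        return ps

    # -- lookups ----------------------------------------------------------

    def resolve_rate(self, sex: str, age: float, from_state: str, to_state: str) -> float:
        """Annual transition probability for the band containing ``age``."""
        if not (AGE_MIN <= age <= AGE_MAX):
            raise ParamError(f"age {age} outside supported range [{AGE_MIN}, {AGE_MAX}]")
        df = self.transitions
        rows = df[
            (df["sex"] == sex)
            & (df["from_state"] == from_state)
            & (df["to_state"] == to_state)
        ]
        if rows.empty:
            raise ParamError(f"no transition rows for ({sex}, {from_state} -> {to_state})")
        row = _band_row(rows, age, f"transition ({sex}, {from_state} -> {to_state})")
        return float(_resolved_column(rows, self.variant).loc[row.name])

    def starting_prevalence(self, sex: str, age: float) -> dict[str, float]:
        """Lesion-state starting prevalences at ``age`` (band lookup)."""
        if not (AGE_MIN <= age <= AGE_MAX):
            raise ParamError(f"age {age} outside supported range [{AGE_MIN}, {AGE_MAX}]")
        out: dict[str, float] = {}
        df = self.prevalence
        for state in LESION_STATES:
            rows = df[(df["sex"] == sex) & (df["state"] == state)]
            if rows.empty:
                raise ParamError(f"no prevalence rows for ({sex}, {state})")
            row = _band_row(rows, age, f"prevalence ({sex}, {state})")
            out[state] = float(_resolved_column(rows, self.variant).loc[row.name])
        return out

    def sensitivity(self, modality: str, state: str) -> float:
        df = self.test_performance
        rows = df[
            (df["modality"] == modality)
            & (df["measure"] == "sensitivity")
            & (df["state"] == state)
        ]
        if rows.empty:
            raise ParamError(f"no sensitivity for ({modality}, {state})")
        return float(rows["value"].iloc[0])

    def specificity(self, modality: str) -> float:
        df = self.test_performance
        rows = df[(df["modality"] == modality) & (df["measure"] == "specificity")]
        if rows.empty:
            raise ParamError(f"no specificity for {modality}")
        return float(rows["value"].iloc[0])

    def all_cause(self, sex: str, age: int) -> float:
        if not (AGE_MIN <= age <= AGE_MAX):
            raise ParamError(f"age {age} outside supported range [{AGE_MIN}, {AGE_MAX}]")
        return float(self._cache["q"][sex][int(age) - AGE_MIN])

    def remaining_life_expectancy(self, sex: str, age: int) -> float:
        if not (AGE_MIN <= age <= AGE_MAX):
            raise ParamError(f"no life-expectancy entry for age {age}")
        return float(self._cache["le"][sex][int(age) - AGE_MIN])

    # -- dense engine arrays ----------------------------------------------

    @cached_property
    def _cache(self) -> dict:
        """Per-year-of-age arrays over AGE_MIN..AGE_MAX used by the engine."""
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
        rates = {
            (sex, fs, ts): np.array(
                [self.resolve_rate(sex, a, fs, ts) for a in ages], dtype=float
            )
            for sex in SEXES
            for fs, ts in TRANSITIONS
        }
        q, le = {}, {}
        for sex in SEXES:
            sub = self.all_cause_mortality[self.all_cause_mortality["sex"] == sex]
            qs = sub.set_index("age")["value"]
            sub = self.life_expectancy[self.life_expectancy["sex"] == sex]
            les = sub.set_index("age")["value"]
            missing = [a for a in ages if a not in qs.index or a not in les.index]
            if missing:
                raise ParamError(f"mortality/life-expectancy missing ages {missing} for {sex}")
            q[sex] = qs.reindex(ages).to_numpy(dtype=float)
            le[sex] = les.reindex(ages).to_numpy(dtype=float)
        # CRC-specific mortality by years since diagnosis; index ysd_cap + 1
        # is the post-cap long-term-survivor pool with zero excess mortality.
        crc = {}
        for mode in DETECTION_MODES:
            sub = self.crc_mortality[self.crc_mortality["mode"] == mode]
            by_ysd = sub.set_index("years_since_dx")["value"]
            vec = np.zeros(self.ysd_cap + 2, dtype=float)
            for ysd in range(self.ysd_cap + 1):
                if ysd not in by_ysd.index:
                    raise ParamError(f"CRC mortality missing ({mode}, years_since_dx={ysd})")
                vec[ysd] = float(by_ysd.loc[ysd])
            crc[mode] = vec
        return {"rates": rates, "q": q, "le": le, "crc": crc}

    def rate_array(self, sex: str, from_state: str, to_state: str) -> np.ndarray:
        return self._cache["rates"][(sex, from_state, to_state)]

    def crc_mortality_vector(self, mode: str) -> np.ndarray:
        return self._cache["crc"][mode]

    # -- validation -------------------------------------------------------

    def validate(self) -> "ParamSet":
        """Check every invariant; raise :class:`ParamError` naming the key."""
        for table, cols in (
            (self.prevalence, ("value", "ci_lower", "ci_upper")),
            (self.transitions, ("value", "ci_lower", "ci_upper")),
        ):
            for col in cols:
                if col not in table.columns:
                    continue
                for idx, v in table[col].items():
                    if pd.isna(v):
                        continue
                    _check_prob(float(v), f"{self._row_key(table, idx)}:{col}")
            if "ci_lower" in table.columns:
                bad = table[
                    (table["ci_lower"].notna() & (table["ci_lower"] > table["value"]))
                    | (table["ci_upper"].notna() & (table["ci_upper"] < table["value"]))
                ]
                if len(bad):
                    raise ParamError(
                        f"CI bounds do not bracket point estimate at {self._row_key(table, bad.index[0])}"
                    )
        for idx, v in self.test_performance["value"].items():
            _check_prob(float(v), f"test_performance row {idx}")
        for name, table in (
            ("all_cause_mortality", self.all_cause_mortality),
            ("crc_mortality", self.crc_mortality),
        ):
            for idx, v in table["value"].items():
                _check_prob(float(v), f"{name} row {idx}")

        # prevalences per (sex, band) sum to <= 1; remainder is lesion-free
        res = _resolved_column(self.prevalence, self.variant)
        sums = self.prevalence.assign(_v=res).groupby(["sex", "age_lo"])["_v"].sum()
        bad = sums[sums > 1.0 + 1e-12]
        if len(bad):
            raise ParamError(f"starting prevalences exceed 1 at {bad.index[0]}")

        # coverage + one-year outflow (progression + other-cause death) <= 1
        self.__dict__.pop("_cache", None)  # rebuild under current variant
        cache = self._cache
        for sex in SEXES:
            q = cache["q"][sex]
            for fs, ts in TRANSITIONS:
                r = cache["rates"][(sex, fs, ts)]
                over = np.nonzero(r + q > 1.0 + 1e-12)[0]
                if len(over):
                    age = AGE_MIN + int(over[0])
                    raise ParamError(
                        f"outflow > 1 for ({sex}, age {age}, {fs}): rate {r[over[0]]} + all-cause {q[over[0]]}"
                    )
            le = cache["le"][sex]
            if not np.all(np.diff(le) < 0):
                raise ParamError(f"remaining life expectancy not strictly decreasing in age for {sex}")

        crc = cache["crc"]
        if np.any(crc[MODE_SCREEN] > crc[MODE_SYMPTOM] + 1e-12):
            warnings.warn(
                "screen-detected CRC mortality exceeds symptom-detected at some "
                "years-since-diagnosis",
                stacklevel=2,
            )
        for state in LESION_STATES:
            if self.sensitivity("colonoscopy", state) < self.sensitivity("fit", state) - 1e-12:
                warnings.warn(
                    f"colonoscopy sensitivity below FIT sensitivity for {state}",
                    stacklevel=2,
                )
        return self

    @staticmethod
    def _row_key(table: pd.DataFrame, idx) -> str:
        row = table.loc[idx]
        keys = [c for c in ("sex", "age_lo", "state", "from_state", "to_state") if c in table.columns]
        return ", ".join(f"{k}={row[k]}" for k in keys)


# -- disk I/O --------------------------------------------------------------


def load_param_set(path: str | Path, variant: str = "point") -> ParamSet:
    """Load a parameter directory (manifest + TSV tables) and validate it.

    ``variant`` selects point estimates or a 95%-CI limit for every
    CI-carrying parameter; parameters without CI columns keep point values.
    """
    path = Path(path)
    if variant not in VARIANTS:
        raise ParamError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    tables = {
        name: pd.read_csv(
            path / manifest["tables"][name], sep="\t", float_precision="round_trip"
        )
        for name in _TABLE_FILES
    }
    ps = ParamSet(
        prevalence=tables["prevalence"],
        transitions=tables["transitions"],
        test_performance=tables["test_performance"].fillna({"state": ""}),
        all_cause_mortality=tables["all_cause_mortality"],
        crc_mortality=tables["crc_mortality"],
        life_expectancy=tables["life_expectancy"],
        ysd_cap=int(manifest.get("ysd_cap", 14)),
        source=str(manifest.get("source", path.name)),
        variant=variant,
    )
    ps.validate()
    return ps


def write_param_set(params: ParamSet, path: str | Path) -> Path:
    """Write a parameter directory that :func:`load_param_set` round-trips."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tables = {
        "prevalence": params.prevalence,
        "transitions": params.transitions,
        "test_performance": params.test_performance,
        "all_cause_mortality": params.all_cause_mortality,
        "crc_mortality": params.crc_mortality,
        "life_expectancy": params.life_expectancy,
    }
    for name, df in tables.items():
        df.to_csv(path / _TABLE_FILES[name], sep="\t", index=False)
    manifest = {
        "tables": dict(_TABLE_FILES),
        "source": params.source,
        "ysd_cap": int(params.ysd_cap),
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path
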