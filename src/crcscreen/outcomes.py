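"""Outcome aggregation: cumulative cases, deaths, YPLL, reductions, ratios.

All counts are reported per 100,000 people alive at model start, over the
scenario horizon (50 years by default).  Years of potential life lost
(YPLL) weight each CRC death by the remaining life expectancy at the
(integer) age of death, so deaths at younger ages carry more weight.

Reductions are percentages relative to the matched no-screening baseline;
sporadic/selective comparisons are ratios of *prevented* counts
(baseline minus scenario), which is equivalent to ratios of reductions
because the two scenarios of a matched pair share their baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .parameters import ParamError, ParamSet

#: Reporting population: counts are per this many people at model start.
POPULATION = 100_000

OUTCOME_KEYS = ("cases", "deaths", "ypll")


def ypll(
    crc_deaths_by_age: Mapping[int, float], params: ParamSet, sex: str
) -> float:
    """Years of potential life lost for the given CRC-death flow table.

    ``crc_deaths_by_age`` maps integer age at death to the death count
    (any scale); each death contributes the remaining life expectancy at
    that age.
    """
    total = 0.0
    for age, deaths in crc_deaths_by_age.items():
        le = params.remaining_life_expectancy(sex, age)  # raises if missing
        total += deaths * le
    return total


@dataclass
class OutcomeSummary:
    """Cumulative outcomes of one scenario (per 100,000 starting population)."""

    label: str
    sex: str
    start_age: int
    horizon: int
    cases: float
    deaths: float
    ypll: float
    cum_cases: np.ndarray
    cum_mortality: np.ndarray
    cum_ypll: np.ndarray
    fits_performed: float = 0.0
    colonoscopies_performed: float = 0.0
    reductions: dict[str, float] | None = None

    @property
    def config_key(self) -> tuple:
        return (self.sex, self.start_age, self.horizon)

    def outcome(self, key: str) -> float:
        return {"cases": self.cases, "deaths": self.deaths, "ypll": self.ypll}[key]


def summarize_trajectory(
    traj, params: ParamSet, sex: str, label: str = "", event_results=()
) -> OutcomeSummary:
    """Aggregate an engine trajectory into an :class:`OutcomeSummary`."""
    ages = [flows.age for _, flows in traj]
    start_age = ages[0] if ages else 0
    new_cases = np.array(
        [flows.new_clinical_symptom + flows.new_clinical_screen for _, flows in traj]
    )
    crc_deaths = np.array([flows.crc_deaths for _, flows in traj])
    le = np.array([params.remaining_life_expectancy(sex, a) for a in ages])
    cum_cases = np.cumsum(new_cases) * POPULATION
    cum_mort = np.cumsum(crc_deaths) * POPULATION
    cum_ypll = np.cumsum(crc_deaths * le) * POPULATION
    return OutcomeSummary(
        label=label,
        sex=sex,
        start_age=int(start_age),
        horizon=len(traj),
        cases=float(cum_cases[-1]) if len(traj) else 0.0,
        deaths=float(cum_mort[-1]) if len(traj) else 0.0,
        ypll=float(cum_ypll[-1]) if len(traj) else 0.0,
        cum_cases=cum_cases,
        cum_mortality=cum_mort,
        cum_ypll=cum_ypll,
        fits_performed=sum(r.fits_performed for r in event_results) * POPULATION,
        colonoscopies_performed=sum(r.colonoscopies_performed for r in event_results)
        * POPULATION,
    )


def mix_summaries(
    weighted: Sequence[tuple[float, OutcomeSummary]], label: str = ""
) -> OutcomeSummary:
    """Convex mixture of sub-cohort summaries (weights must sum to 1)."""
    if not weighted:
        raise ParamError("nothing to mix")
    if abs(sum(w for w, _ in weighted) - 1.0) > 1e-9:
        raise ParamError("sub-cohort weights must sum to 1")
    first = weighted[0][1]
    for _, s in weighted:
        if s.config_key != first.config_key:
            raise ParamError("sub-cohort summaries have mismatched configurations")
    return OutcomeSummary(
        label=label or first.label,
        sex=first.sex,
        start_age=first.start_age,
        horizon=first.horizon,
        cases=sum(w * s.cases for w, s in weighted),
        deaths=sum(w * s.deaths for w, s in weighted),
        ypll=sum(w * s.ypll for w, s in weighted),
        cum_cases=sum(w * s.cum_cases for w, s in weighted),
        cum_mortality=sum(w * s.cum_mortality for w, s in weighted),
        cum_ypll=sum(w * s.cum_ypll for w, s in weighted),
        fits_performed=sum(w * s.fits_performed for w, s in weighted),
        colonoscopies_performed=sum(w * s.colonoscopies_performed for w, s in weighted),
    )


def reduction_vs_baseline(
    scenario: OutcomeSummary, baseline: OutcomeSummary
) -> dict[str, float]:
    """Percentage reductions vs the matched no-screening baseline."""
    if scenario.config_key != baseline.config_key:
        raise ParamError(
            f"scenario {scenario.config_key} and baseline {baseline.config_key} differ"
        )
    out = {}
    for key in OUTCOME_KEYS:
        b = baseline.outcome(key)
        s = scenario.outcome(key)
        out[key] = 0.0 if b == 0.0 else 100.0 * (b - s) / b
    return out


@dataclass
class ComparisonResult:
    """Matched selective-vs-sporadic comparison at one adherence level."""

    adherence_level: float
    selective: OutcomeSummary
    sporadic: OutcomeSummary
    baseline: OutcomeSummary
    #: prevented-count ratios sporadic/selective per outcome; NaN when the
    #: selective scenario prevents nothing (flagged undefined)
    ratios: dict[str, float] = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return all(math.isfinite(v) for v in self.ratios.values())


def compare_patterns(
    baseline: OutcomeSummary,
    selective: OutcomeSummary,
    sporadic: OutcomeSummary,
    adherence: float = float("nan"),
) -> ComparisonResult:
    """Ratios of prevented counts, sporadic over selective.

    Computed on unrounded prevented counts (baseline minus scenario), never
    on rounded percentages.
    """
    for s in (selective, sporadic):
        if s.config_key != baseline.config_key:
            raise ParamError("comparison scenarios must share sex, start age and horizon")
    ratios = {}
    for key in OUTCOME_KEYS:
        b = baseline.outcome(key)
        prev_sel = b - selective.outcome(key)
        prev_spo = b - sporadic.outcome(key)
        # prevented counts indistinguishable from zero at floating precision
        # leave the ratio undefined
        tol = 1e-9 * max(1.0, abs(b))
        ratios[key] = prev_spo / prev_sel if prev_sel > tol else float("nan")
    return ComparisonResult(
        adherence_level=adherence,
        selective=selective,
        sporadic=sporadic,
        baseline=baseline,
        ratios=ratios,
    )
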