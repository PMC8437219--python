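"""Scenario orchestration: single runs, table reproduction, sensitivity suite.

A :class:`ScenarioConfig` names everything one simulation needs — sex,
start age (50, or 45 for the earlier-start sensitivity analysis), horizon
(50 years, i.e. up to age 100), strategy, adherence pattern, and parameter
variant.  :func:`run_scenario` executes it in deterministic cohort mode
together with its matched no-screening baseline.

:func:`reproduce_tables` sweeps the full scenario grid of the published
comparison: annual FIT at ten matched adherence levels (100% down to 10%)
and three-age screening colonoscopy with its single- and two-age sporadic
variants, for both sexes, and reports reductions and sporadic/selective
ratios in the layout of the published tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .adherence import (
    AdherencePattern,
    ScreeningStrategy,
    adherence_level,
    build_cohort_plan,
)
from .natural_history import run_unscreened
from .outcomes import (
    ComparisonResult,
    OutcomeSummary,
    compare_patterns,
    mix_summaries,
    reduction_vs_baseline,
    summarize_trajectory,
)
from .parameters import AGE_MAX, ParamError, ParamSet, SEXES, VARIANTS
from .screening import run_screened


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (screening arm plus implicit baseline)."""

    sex: str
    strategy: ScreeningStrategy | None
    pattern: AdherencePattern | None
    start_age: int = 50
    horizon: int = 50
    variant: str = "point"
    label: str = ""

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ParamError(f"unknown sex {self.sex!r}; expected one of {SEXES}")
        if self.start_age + self.horizon > AGE_MAX:
            raise ParamError(
                f"start age {self.start_age} + horizon {self.horizon} exceeds {AGE_MAX}"
            )
        if self.variant not in VARIANTS:
            raise ParamError(f"unknown variant {self.variant!r}")
        if (self.strategy is None) != (self.pattern is None):
            raise ParamError("strategy and pattern must be given together")


def _baseline(params: ParamSet, config: ScenarioConfig) -> OutcomeSummary:
    traj = run_unscreened(params, config.sex, config.start_age, config.horizon)
    return summarize_trajectory(traj, params, config.sex, label="no screening")


def run_scenario(config: ScenarioConfig, params: ParamSet) -> OutcomeSummary:
    """Run one scenario; the result carries reductions vs its baseline."""
    if config.variant != params.variant:
        params = params.with_variant(config.variant)
    baseline = _baseline(params, config)
    if config.strategy is None:
        summary = baseline
        summary.label = config.label or "no screening"
    else:
        plan = build_cohort_plan(config.pattern, config.strategy)
        pieces = []
        for weight, events in plan:
            if events:
                traj, results = run_screened(
                    params, config.sex, config.start_age, config.horizon, events
                )
                pieces.append(
                    (weight, summarize_trajectory(traj, params, config.sex,
                                                  event_results=results))
                )
            else:
                pieces.append((weight, _baseline(params, config)))
        summary = mix_summaries(pieces, label=config.label or config.pattern.describe())
    summary.reductions = reduction_vs_baseline(summary, baseline)
    return summary


def run_matched_pair(
    params: ParamSet,
    sex: str,
    strategy: ScreeningStrategy,
    selective: AdherencePattern,
    sporadic: AdherencePattern,
    start_age: int = 50,
    horizon: int = 50,
    variant: str = "point",
) -> ComparisonResult:
    """Selective-vs-sporadic comparison sharing one baseline."""
    if params.variant != variant:
        params = params.with_variant(variant)
    cfg = ScenarioConfig(sex, strategy, selective, start_age, horizon, variant)
    baseline = _baseline(params, cfg)
    sel = run_scenario(cfg, params)
    spo = run_scenario(replace(cfg, pattern=sporadic), params)
    level = adherence_level(selective, strategy)
    return compare_patterns(baseline, sel, spo, adherence=level)


# -- published-table layout -------------------------------------------------

#: Matched FIT pairs: selective fraction 1/k vs sporadic every k years,
#: k = 1..10 (levels 100%, 50%, 33%, ..., 10%).
FIT_INTERVALS = tuple(range(1, 11))

def _colo_pairs(ages: tuple[int, int, int]):
    """Matched colonoscopy pairs at a three-age strategy: the full schedule,
    every two-age subset (level 2/3), and every single age (level 1/3)."""
    a, b, c = ages
    return (
        (1.0, ((a, b, c),)),
        (2.0 / 3.0, ((a, b), (a, c), (b, c))),
        (1.0 / 3.0, ((a,), (b,), (c,))),
    )


def _row(
    level: float,
    sel_label: str,
    spo_label: str,
    comp: ComparisonResult,
) -> dict:
    sel_red = comp.selective.reductions
    spo_red = comp.sporadic.reductions
    return {
        "adherence_level": level,
        "selective_scheme": sel_label,
        "selective_incidence_reduction": sel_red["cases"],
        "selective_mortality_reduction": sel_red["deaths"],
        "selective_ypll_reduction": sel_red["ypll"],
        "sporadic_scheme": spo_label,
        "sporadic_incidence_reduction": spo_red["cases"],
        "sporadic_mortality_reduction": spo_red["deaths"],
        "sporadic_ypll_reduction": spo_red["ypll"],
        "ratio_incidence": comp.ratios["cases"],
        "ratio_mortality": comp.ratios["deaths"],
        "ratio_ypll": comp.ratios["ypll"],
    }


def reproduce_tables(
    params: ParamSet, start_age: int = 50, horizon: int = 50, variant: str = "point"
) -> dict[str, pd.DataFrame]:
    """Full scenario sweep in the layout of the published comparison tables.

    Returns ``{"fit": ..., "colonoscopy": ...}`` with one row per matched
    selective/sporadic pair and sex.  Reductions are percentages (unrounded;
    round for display), ratios are prevented-count ratios.
    """
    fit_strategy = ScreeningStrategy.annual_fit(start_age, start_age + 25)
    colo_ages = (start_age, start_age + 10, start_age + 20)
    colo_strategy = ScreeningStrategy.colonoscopy_at(colo_ages)

    fit_rows = []
    for sex in SEXES:
        for k in FIT_INTERVALS:
            sel = AdherencePattern.selective(1.0 / k)
            spo = AdherencePattern.sporadic_every(k, fit_strategy)
            comp = run_matched_pair(
                params, sex, fit_strategy, sel, spo, start_age, horizon, variant
            )
            row = _row(
                1.0 / k,
                f"{100.0 / k:.0f}% annually",
                "100% annually" if k == 1 else f"100% every {k} year",
                comp,
            )
            row["sex"] = sex
            fit_rows.append(row)

    colo_rows = []
    for sex in SEXES:
        for frac, subsets in _colo_pairs(colo_ages):
            sel = AdherencePattern.selective(frac)
            for subset in subsets:
                spo = AdherencePattern.sporadic(subset)
                comp = run_matched_pair(
                    params, sex, colo_strategy, sel, spo, start_age, horizon, variant
                )
                ages_txt = ", ".join(str(a) for a in colo_ages)
                row = _row(
                    frac,
                    f"{100 * frac:.0f}% at ages {ages_txt} years",
                    f"100% at ages {', '.join(str(a) for a in subset)} years",
                    comp,
                )
                row["sex"] = sex
                colo_rows.append(row)

    cols = ["sex"] + [c for c in fit_rows[0] if c != "sex"]
    return {
        "fit": pd.DataFrame(fit_rows)[cols],
        "colonoscopy": pd.DataFrame(colo_rows)[cols],
    }


def run_sensitivity_suite(
    params: ParamSet, start_age: int = 50, horizon: int = 50
) -> dict[str, dict[str, pd.DataFrame]]:
    """Sensitivity analyses: CI-limit parameter variants and start age 45.

    Reruns the full table sweep under each variant; returns a mapping from
    variant name (``point``, ``ci-lower``, ``ci-upper``, ``start-45``) to
    the corresponding table pair.
    """
    out = {}
    for variant in VARIANTS:
        out[variant] = reproduce_tables(
            params.with_variant(variant), start_age, horizon, variant
        )
    out["start-45"] = reproduce_tables(params, 45, min(horizon, AGE_MAX - 45), "point")
    return out
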