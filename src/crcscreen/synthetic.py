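"""Synthetic parameter sets with the structure the analysis assumes.

The German screening-colonoscopy-registry parameters behind the published
model are distributed separately, so this module generates parameter sets
that reproduce their *structure* — lesion prevalences rising with age,
sex-specific transition rates along the adenoma--carcinoma sequence, test
sensitivity increasing from non-advanced adenoma to preclinical cancer, and
a survival advantage for screen-detected over symptom-detected cancer —
without claiming their numerical values.  Every stage of the package can
therefore be exercised and tested with no external download.

Two entry points:

* :func:`generate_param_set` draws a full :class:`~crcscreen.parameters.ParamSet`
  from a seeded :class:`SynthSpec`;
* :func:`degenerate_sets` returns analytically transparent parameter sets
  ("null", "deterministic-chain", "perfect-test", "useless-test") used as
  oracles in tests.

Default ranges are chosen so an unscreened cohort starting at age 50
accumulates a lifetime CRC risk of roughly 3--7% — the order of magnitude of
average-risk Western populations — and so screening moves outcomes by large,
stable margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import (
    ADV_ADENOMA,
    AGE_MAX,
    AGE_MIN,
    LESION_STATES,
    MODE_SCREEN,
    MODE_SYMPTOM,
    NONADV_ADENOMA,
    NO_LESION,
    PRECLIN_CRC,
    SEXES,
    TRANSITIONS,
    ParamError,
    ParamSet,
)

Range = tuple[float, float]

#: Age bands used for prevalences and transition rates: five-year bands from
#: 45 to 80, then one open-ended band covering 80+ (last-band extrapolation).
BANDS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 5) for lo in range(AGE_MIN, 80, 5)
) + ((80, AGE_MAX + 1),)


@dataclass(frozen=True)
class SynthSpec:
    """Specification of one synthetic parameter draw.

    Prevalence and transition ranges are given at the anchor ages 50 and 75;
    band values are interpolated log-linearly between (and extrapolated
    beyond) the anchors, which makes every generated curve monotone in age.
    Women's rates are men's scaled by ``female_factor``.
    """

    seed: int = 0
    # starting prevalence ranges (fractions of the cohort) at ages 50 / 75
    prevalence_50: dict[str, Range] = field(
        default_factory=lambda: {
            NONADV_ADENOMA: (0.14, 0.20),
            ADV_ADENOMA: (0.040, 0.065),
            PRECLIN_CRC: (0.0015, 0.0030),
        }
    )
    prevalence_75: dict[str, Range] = field(
        default_factory=lambda: {
            NONADV_ADENOMA: (0.26, 0.34),
            ADV_ADENOMA: (0.085, 0.125),
            PRECLIN_CRC: (0.0055, 0.0095),
        }
    )
    # annual transition-probability ranges per edge at ages 50 / 75
    transition_50: dict[tuple[str, str], Range] = field(
        default_factory=lambda: {
            (NO_LESION, NONADV_ADENOMA): (0.0060, 0.0090),
            (NONADV_ADENOMA, ADV_ADENOMA): (0.010, 0.015),
            (ADV_ADENOMA, PRECLIN_CRC): (0.017, 0.024),
            (PRECLIN_CRC, "clinical_crc"): (0.22, 0.28),
        }
    )
    transition_75: dict[tuple[str, str], Range] = field(
        default_factory=lambda: {
            (NO_LESION, NONADV_ADENOMA): (0.012, 0.018),
            (NONADV_ADENOMA, ADV_ADENOMA): (0.019, 0.028),
            (ADV_ADENOMA, PRECLIN_CRC): (0.030, 0.042),
            (PRECLIN_CRC, "clinical_crc"): (0.22, 0.28),
        }
    )
    female_factor: float = 0.82
    ci_lower_factor: float = 0.8
    ci_upper_factor: float = 1.2
    # test performance (fractions)
    fit_sensitivity: dict[str, float] = field(
        default_factory=lambda: {
            NONADV_ADENOMA: 0.07,
            ADV_ADENOMA: 0.25,
            PRECLIN_CRC: 0.75,
        }
    )
    fit_specificity: float = 0.96
    colo_sensitivity: dict[str, float] = field(
        default_factory=lambda: {
            NONADV_ADENOMA: 0.75,
            ADV_ADENOMA: 0.95,
            PRECLIN_CRC: 0.95,
        }
    )
    colo_specificity: float = 1.0
    # all-cause mortality: Gompertz q(age) = q0 * exp(slope * (age - 45))
    gompertz_q0: dict[str, float] = field(
        default_factory=lambda: {"male": 0.0045, "female": 0.0028}
    )
    gompertz_slope: float = 0.088
    # CRC-specific annual death probability by years since diagnosis:
    # base * exp(-decay * ysd); screen-detected scaled by the relative hazard
    crc_mortality_symptom_year0: float = 0.12
    crc_mortality_decay: float = 0.22
    screen_detected_relative_hazard: float = 0.45
    ysd_cap: int = 14

    def validate(self) -> "SynthSpec":
        for name, d in (
            ("prevalence_50", self.prevalence_50),
            ("prevalence_75", self.prevalence_75),
            ("transition_50", self.transition_50),
            ("transition_75", self.transition_75),
        ):
            for key, (lo, hi) in d.items():
                if not (0.0 <= lo <= hi <= 1.0):
                    raise ParamError(f"invalid range {name}[{key}] = ({lo}, {hi})")
        for state in LESION_STATES:
            if self.prevalence_75[state][1] < self.prevalence_50[state][0]:
                raise ParamError(
                    f"prevalence range at 75 lies below range at 50 for {state}; "
                    "lesion prevalence must rise with age"
                )
        return self


DEFAULT_SPEC = SynthSpec()


def _log_interp(v50: float, v75: float, age: float) -> float:
    """Log-linear interpolation anchored at ages 50 and 75; exact zeros stay
    zero (degenerate null curves)."""
    if v50 <= 0.0 and v75 <= 0.0:
        return 0.0
    v50 = max(v50, 1e-12)
    v75 = max(v75, 1e-12)
    return float(v50 * (v75 / v50) ** ((age - 50.0) / 25.0))


def _band_mid(lo: int, hi: int) -> float:
    return 0.5 * (lo + hi)


def generate_param_set(spec: SynthSpec = DEFAULT_SPEC) -> ParamSet:
    """Draw a full parameter set; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    def draw(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    # anchor draws (men); women scaled by female_factor
    prev_anchor = {
        state: tuple(
            sorted((draw(*spec.prevalence_50[state]), draw(*spec.prevalence_75[state])))
        )
        for state in LESION_STATES
    }
    rate_anchor = {
        edge: tuple(
            sorted((draw(*spec.transition_50[edge]), draw(*spec.transition_75[edge])))
        )
        for edge in TRANSITIONS
    }

    prev_rows, trans_rows = [], []
    for sex in SEXES:
        factor = 1.0 if sex == "male" else spec.female_factor
        for lo, hi in BANDS:
            mid = _band_mid(lo, hi)
            for state in LESION_STATES:
                v50, v75 = prev_anchor[state]
                v = min(factor * _log_interp(v50, v75, mid), 0.95)
                prev_rows.append(
                    {
                        "sex": sex,
                        "age_lo": lo,
                        "age_hi": hi,
                        "state": state,
                        "value": v,
                        "ci_lower": spec.ci_lower_factor * v,
                        "ci_upper": min(spec.ci_upper_factor * v, 1.0),
                    }
                )
            for edge in TRANSITIONS:
                v50, v75 = rate_anchor[edge]
                v = min(factor * _log_interp(v50, v75, mid), 0.95)
                trans_rows.append(
                    {
                        "sex": sex,
                        "age_lo": lo,
                        "age_hi": hi,
                        "from_state": edge[0],
                        "to_state": edge[1],
                        "value": v,
                        "ci_lower": spec.ci_lower_factor * v,
                        "ci_upper": min(spec.ci_upper_factor * v, 1.0),
                    }
                )

    test_rows = []
    for state in LESION_STATES:
        test_rows.append(
            {"modality": "fit", "measure": "sensitivity", "state": state,
             "value": spec.fit_sensitivity[state]}
        )
        test_rows.append(
            {"modality": "colonoscopy", "measure": "sensitivity", "state": state,
             "value": spec.colo_sensitivity[state]}
        )
    test_rows.append({"modality": "fit", "measure": "specificity", "state": "",
                      "value": spec.fit_specificity})
    test_rows.append({"modality": "colonoscopy", "measure": "specificity", "state": "",
                      "value": spec.colo_specificity})

    mort_rows, le_rows = [], []
    for sex in SEXES:
        q0 = spec.gompertz_q0[sex]
        # extend the curve beyond the model horizon for the life-table tail
        ages_ext = np.arange(AGE_MIN, 121)
        q_ext = np.minimum(q0 * np.exp(spec.gompertz_slope * (ages_ext - AGE_MIN)), 0.65)
        q_ext[-1] = 1.0
        surv = np.cumprod(1.0 - q_ext)
        for i, age in enumerate(range(AGE_MIN, AGE_MAX + 1)):
            mort_rows.append({"sex": sex, "age": age, "value": float(q_ext[i])})
            # curtate expectation + half-year convention
            tail = surv[i:] / surv[i - 1] if i > 0 else surv[i:]
            le = float(np.sum(tail)) + 0.5
            le_rows.append({"sex": sex, "age": age, "value": le})

    crc_rows = []
    for ysd in range(spec.ysd_cap + 1):
        base = spec.crc_mortality_symptom_year0 * np.exp(-spec.crc_mortality_decay * ysd)
        crc_rows.append({"mode": MODE_SYMPTOM, "years_since_dx": ysd, "value": float(base)})
        crc_rows.append(
            {"mode": MODE_SCREEN, "years_since_dx": ysd,
             "value": float(spec.screen_detected_relative_hazard * base)}
        )

    ps = ParamSet(
        prevalence=pd.DataFrame(prev_rows),
        transitions=pd.DataFrame(trans_rows),
        test_performance=pd.DataFrame(test_rows),
        all_cause_mortality=pd.DataFrame(mort_rows),
        crc_mortality=pd.DataFrame(crc_rows),
        life_expectancy=pd.DataFrame(le_rows),
        ysd_cap=spec.ysd_cap,
        source=f"synthetic(seed={spec.seed})",
        variant="point",
    )
    try:
        ps.validate()
    except ParamError as err:
        raise ParamError(f"infeasible synthetic spec: {err}") from err
    return ps


def _override_values(df: pd.DataFrame, value: float) -> pd.DataFrame:
    out = df.copy()
    out["value"] = value
    for col in ("ci_lower", "ci_upper"):
        if col in out.columns:
            out[col] = value
    return out


def degenerate_sets(base_seed: int = 0) -> dict[str, ParamSet]:
    """Analytically transparent parameter sets for oracle tests.

    * ``"null"`` — no lesions ever (zero prevalences and transition rates);
    * ``"deterministic-chain"`` — every transition probability 1 and no
      death from any cause: a cohort marches one state per year;
    * ``"perfect-test"`` — all sensitivities and specificities 1;
    * ``"useless-test"`` — all sensitivities 0 (specificity 1), so screening
      is a no-op.
    """
    base = generate_param_set(replace(DEFAULT_SPEC, seed=base_seed))

    null = replace(
        base,
        prevalence=_override_values(base.prevalence, 0.0),
        transitions=_override_values(base.transitions, 0.0),
        source="degenerate:null",
    )

    n_le = len(base.life_expectancy)
    chain_le = base.life_expectancy.copy()
    chain_le["value"] = 120.0 - chain_le["age"].astype(float)
    chain = replace(
        base,
        prevalence=_override_values(base.prevalence, 0.0),
        transitions=_override_values(base.transitions, 1.0),
        all_cause_mortality=_override_values(base.all_cause_mortality, 0.0),
        crc_mortality=_override_values(base.crc_mortality, 0.0),
        life_expectancy=chain_le,
        source="degenerate:deterministic-chain",
    )

    def with_tests(sens: float, specificity: float, label: str) -> ParamSet:
        tp = base.test_performance.copy()
        tp.loc[tp["measure"] == "sensitivity", "value"] = sens
        tp.loc[tp["measure"] == "specificity", "value"] = specificity
        return replace(base, test_performance=tp, source=f"degenerate:{label}")

    sets = {
        "null": null,
        "deterministic-chain": chain,
        "perfect-test": with_tests(1.0, 1.0, "perfect-test"),
        "useless-test": with_tests(0.0, 1.0, "useless-test"),
    }
    for ps in sets.values():
        ps.validate()
    return sets
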