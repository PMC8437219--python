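"""Deterministic cohort propagation through the adenoma--carcinoma sequence.

The cohort is represented as a mass distribution over health states:

``NO_LESION -> NONADV_ADENOMA -> ADV_ADENOMA -> PRECLIN_CRC -> CLIN_CRC``

plus two absorbing dead states (CRC death, other-cause death).  Clinical CRC
is split into substates by mode of detection (screen- vs symptom-detected)
and integer years since diagnosis, because the CRC-specific mortality
schedule depends on both.  Years since diagnosis are tracked up to a cap
(default 14); beyond the cap the mass pools in a long-term-survivor substate
with no excess CRC mortality.

Propagation is expected-value (cohort) rather than individual-level Monte
Carlo: state masses are fractions of the initial cohort and advance by the
annual transition probabilities, which gives the exact expectation of the
equivalent microsimulation with no sampling noise.

Within-year event order (a fixed convention, applied multiplicatively):

1. screening event, if one is scheduled (handled by :mod:`crcscreen.screening`);
2. lesion progression, one step along the sequence per year — the
   preclinical-to-clinical transition books a symptom-detected diagnosis;
3. CRC-specific death, applied only to diagnosed (clinical) CRC substates
   by mode of detection and years since diagnosis;
4. other-cause death, applied to every alive state at the all-cause rate;
5. years-since-diagnosis increment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    ADV_ADENOMA,
    AGE_MAX,
    AGE_MIN,
    CLIN_CRC,
    MODE_SCREEN,
    MODE_SYMPTOM,
    NONADV_ADENOMA,
    NO_LESION,
    PRECLIN_CRC,
    ParamError,
    ParamSet,
)

MASS_TOL = 1e-12


class StateSpace:
    """Index layout of the state vector for a given years-since-dx cap."""

    def __init__(self, ysd_cap: int = 14):
        self.ysd_cap = int(ysd_cap)
        self.NO_LESION = 0
        self.NONADV = 1
        self.ADV = 2
        self.PRECLIN = 3
        self.n_ysd = self.ysd_cap + 2  # 0..cap plus post-cap survivor pool
        self._clin0 = {MODE_SCREEN: 4, MODE_SYMPTOM: 4 + self.n_ysd}
        self.DEAD_CRC = 4 + 2 * self.n_ysd
        self.DEAD_OTHER = self.DEAD_CRC + 1
        self.n = self.DEAD_OTHER + 1

    def clin(self, mode: str, ysd: int) -> int:
        """Index of the clinical-CRC substate (``ysd`` > cap = survivor pool)."""
        ysd = min(int(ysd), self.ysd_cap + 1)
        return self._clin0[mode] + ysd

    def clin_slice(self, mode: str) -> slice:
        return slice(self._clin0[mode], self._clin0[mode] + self.n_ysd)

    def alive_indices(self) -> np.ndarray:
        return np.arange(0, self.DEAD_CRC)


@dataclass
class StateDistribution:
    """Mass of a cohort across health states at one age.

    Masses are fractions of the initial cohort; multiplying by 100,000 gives
    counts for the standard reporting population.
    """

    sex: str
    age: int
    mass: np.ndarray
    space: StateSpace

    def copy(self) -> "StateDistribution":
        return StateDistribution(self.sex, self.age, self.mass.copy(), self.space)

    @property
    def total(self) -> float:
        return float(self.mass.sum())

    @property
    def alive(self) -> float:
        return float(self.mass[self.space.alive_indices()].sum())

    def check(self) -> "StateDistribution":
        if np.any(self.mass < -MASS_TOL):
            raise ValueError("negative state mass")
        if abs(self.total - 1.0) > 1e-9:
            raise ValueError(f"total mass {self.total} != 1")
        return self


@dataclass
class AnnualFlows:
    """Event masses booked while propagating one year (at start-of-year age)."""

    age: int
    new_preclinical: float = 0.0
    new_clinical_symptom: float = 0.0
    new_clinical_screen: float = 0.0
    crc_deaths: float = 0.0
    other_deaths: float = 0.0


def initial_distribution(params: ParamSet, sex: str, start_age: int) -> StateDistribution:
    """Cohort at model start: lesion prevalences, remainder lesion-free."""
    prev = params.starting_prevalence(sex, start_age)
    space = StateSpace(params.ysd_cap)
    mass = np.zeros(space.n)
    mass[space.NONADV] = prev[NONADV_ADENOMA]
    mass[space.ADV] = prev[ADV_ADENOMA]
    mass[space.PRECLIN] = prev[PRECLIN_CRC]
    mass[space.NO_LESION] = 1.0 - mass.sum()
    if mass[space.NO_LESION] < -MASS_TOL:
        raise ParamError(f"starting prevalences exceed 1 at ({sex}, {start_age})")
    return StateDistribution(sex, int(start_age), mass, space).check()


def advance_year(
    dist: StateDistribution, params: ParamSet
) -> tuple[StateDistribution, AnnualFlows]:
    """Propagate one year: progression, CRC death, other-cause death, ageing."""
    age = dist.age
    if age >= AGE_MAX:
        raise ParamError(f"cannot advance beyond age {AGE_MAX}")
    sp = dist.space
    m = dist.mass.copy()
    flows = AnnualFlows(age=age)
    ai = age - AGE_MIN
    sex = dist.sex

    # 1. lesion progression (single step per year, from start-of-year masses)
    r1 = params.rate_array(sex, NO_LESION, NONADV_ADENOMA)[ai]
    r2 = params.rate_array(sex, NONADV_ADENOMA, ADV_ADENOMA)[ai]
    r3 = params.rate_array(sex, ADV_ADENOMA, PRECLIN_CRC)[ai]
    r4 = params.rate_array(sex, PRECLIN_CRC, CLIN_CRC)[ai]
    f_no = m[sp.NO_LESION] * r1
    f_na = m[sp.NONADV] * r2
    f_aa = m[sp.ADV] * r3
    f_pc = m[sp.PRECLIN] * r4
    m[sp.NO_LESION] -= f_no
    m[sp.NONADV] += f_no - f_na
    m[sp.ADV] += f_na - f_aa
    m[sp.PRECLIN] += f_aa - f_pc
    m[sp.clin(MODE_SYMPTOM, 0)] += f_pc
    flows.new_preclinical = f_aa
    flows.new_clinical_symptom = f_pc

    # 2. CRC-specific death (diagnosed CRC only, by mode and years since dx)
    for mode in (MODE_SCREEN, MODE_SYMPTOM):
        sl = sp.clin_slice(mode)
        mort = params.crc_mortality_vector(mode)
        dead = m[sl] * mort
        m[sl] -= dead
        d = float(dead.sum())
        m[sp.DEAD_CRC] += d
        flows.crc_deaths += d

    # 3. other-cause death on every alive state
    q = params.all_cause(sex, age)
    alive = sp.alive_indices()
    dead_other = m[alive] * q
    m[alive] -= dead_other
    d = float(dead_other.sum())
    m[sp.DEAD_OTHER] += d
    flows.other_deaths = d

    # 4. years-since-diagnosis increment (cap pools into the survivor state)
    for mode in (MODE_SCREEN, MODE_SYMPTOM):
        sl = sp.clin_slice(mode)
        sub = m[sl]
        sub[-1] += sub[-2]
        sub[1:-1] = sub[0:-2]
        sub[0] = 0.0
        m[sl] = sub

    out = StateDistribution(sex, age + 1, m, sp)
    assert abs(out.total - dist.total) < MASS_TOL, "mass not conserved"
    return out, flows


def run_unscreened(
    params: ParamSet, sex: str, start_age: int, horizon: int
) -> list[tuple[StateDistribution, AnnualFlows]]:
    """Baseline trajectory with no screening: ``horizon`` annual steps.

    Element ``t`` holds the distribution *after* year ``t`` together with the
    flows booked during that year.
    """
    if start_age + horizon > AGE_MAX:
        raise ParamError(
            f"horizon {horizon} from age {start_age} exceeds maximum age {AGE_MAX}"
        )
    dist = initial_distribution(params, sex, start_age)
    traj = []
    for _ in range(horizon):
        dist, flows = advance_year(dist, params)
        traj.append((dist, flows))
    return traj


def trajectory_frame(traj: list[tuple[StateDistribution, AnnualFlows]]):
    """Long-format export of a trajectory (one row per year and quantity)."""
    import pandas as pd

    rows = []
    for dist, flows in traj:
        sp = dist.space
        rows.append(
            {
                "age": dist.age,
                "alive": dist.alive,
                "no_lesion": dist.mass[sp.NO_LESION],
                "nonadvanced_adenoma": dist.mass[sp.NONADV],
                "advanced_adenoma": dist.mass[sp.ADV],
                "preclinical_crc": dist.mass[sp.PRECLIN],
                "clinical_crc_screen": dist.mass[sp.clin_slice(MODE_SCREEN)].sum(),
                "clinical_crc_symptom": dist.mass[sp.clin_slice(MODE_SYMPTOM)].sum(),
                "dead_crc": dist.mass[sp.DEAD_CRC],
                "dead_other": dist.mass[sp.DEAD_OTHER],
                "new_preclinical": flows.new_preclinical,
                "new_clinical_symptom": flows.new_clinical_symptom,
                "new_clinical_screen": flows.new_clinical_screen,
                "crc_deaths": flows.crc_deaths,
                "other_deaths": flows.other_deaths,
            }
        )
    return pd.DataFrame(rows)
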