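"""Screening events: detection, adenoma removal, stage shift to diagnosis.

A screening event intercepts the natural history of the cohort: detected
adenomas (non-advanced or advanced) are removed endoscopically and the
subjects return to the lesion-free state; detected preclinical cancer
becomes *screen-detected* clinical cancer, which carries a milder
CRC-specific mortality schedule than symptom-detected cancer.

Two modalities are modelled.  Primary colonoscopy applies its per-state
sensitivity directly.  FIT (fecal immunochemical test) is a two-stage
filter: participants test, a state-dependent fraction is positive, and
positives receive a diagnostic colonoscopy whose own sensitivity determines
detection (so the detected fraction is the product of the two
sensitivities).  Lesion-free participants trigger false-positive diagnostic
colonoscopies at rate ``1 - specificity`` with no state change.

Subjects with already-diagnosed CRC and the dead are outside the screening-
eligible pool.  Mass is conserved exactly through every event.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    ADV_ADENOMA,
    MODE_SCREEN,
    NONADV_ADENOMA,
    PRECLIN_CRC,
    ParamError,
    ParamSet,
)
from .natural_history import AnnualFlows, StateDistribution


@dataclass(frozen=True)
class ScreeningEvent:
    """One offer: modality, age at offer, participation of the eligible mass."""

    modality: str  # "fit" | "colonoscopy"
    age: int
    participation: float = 1.0

    def __post_init__(self):
        if self.modality not in ("fit", "colonoscopy"):
            raise ParamError(f"unknown modality {self.modality!r}")
        if not (0.0 <= self.participation <= 1.0):
            raise ParamError(f"participation {self.participation} outside [0, 1]")


@dataclass
class EventResult:
    """Bookkeeping for one applied event (masses per initial cohort)."""

    age: int
    modality: str
    fits_performed: float = 0.0
    colonoscopies_performed: float = 0.0
    removed_nonadvanced: float = 0.0
    removed_advanced: float = 0.0
    detected_preclinical: float = 0.0

    @property
    def detections_and_removals(self) -> float:
        return self.removed_nonadvanced + self.removed_advanced + self.detected_preclinical


def _move(dist: StateDistribution, result: EventResult, det_na: float, det_aa: float, det_pc: float) -> None:
    sp = dist.space
    m = dist.mass
    m[sp.NONADV] -= det_na
    m[sp.ADV] -= det_aa
    m[sp.NO_LESION] += det_na + det_aa
    m[sp.PRECLIN] -= det_pc
    m[sp.clin(MODE_SCREEN, 0)] += det_pc
    result.removed_nonadvanced = det_na
    result.removed_advanced = det_aa
    result.detected_preclinical = det_pc


def apply_colonoscopy(
    dist: StateDistribution, params: ParamSet, participation: float = 1.0
) -> tuple[StateDistribution, EventResult]:
    """Primary screening colonoscopy on the participating eligible mass."""
    if not (0.0 <= participation <= 1.0):
        raise ParamError(f"participation {participation} outside [0, 1]")
    out = dist.copy()
    sp = out.space
    res = EventResult(age=dist.age, modality="colonoscopy")
    sens = {s: params.sensitivity("colonoscopy", s) for s in (NONADV_ADENOMA, ADV_ADENOMA, PRECLIN_CRC)}
    det_na = participation * sens[NONADV_ADENOMA] * out.mass[sp.NONADV]
    det_aa = participation * sens[ADV_ADENOMA] * out.mass[sp.ADV]
    det_pc = participation * sens[PRECLIN_CRC] * out.mass[sp.PRECLIN]
    _move(out, res, det_na, det_aa, det_pc)
    # everyone participating is scoped, detected or not; the eligible pool
    # is the undiagnosed alive mass at the moment of the offer
    res.colonoscopies_performed = participation * (
        dist.mass[sp.NO_LESION] + dist.mass[sp.NONADV] + dist.mass[sp.ADV] + dist.mass[sp.PRECLIN]
    )
    return out.check(), res


def apply_fit(
    dist: StateDistribution, params: ParamSet, participation: float = 1.0
) -> tuple[StateDistribution, EventResult]:
    """FIT with diagnostic colonoscopy follow-up of positives."""
    if not (0.0 <= participation <= 1.0):
        raise ParamError(f"participation {participation} outside [0, 1]")
    out = dist.copy()
    sp = out.space
    res = EventResult(age=dist.age, modality="fit")
    masses = {
        NONADV_ADENOMA: out.mass[sp.NONADV],
        ADV_ADENOMA: out.mass[sp.ADV],
        PRECLIN_CRC: out.mass[sp.PRECLIN],
    }
    res.fits_performed = participation * (out.mass[sp.NO_LESION] + sum(masses.values()))

    positives = {
        s: participation * params.sensitivity("fit", s) * masses[s] for s in masses
    }
    false_pos = participation * (1.0 - params.specificity("fit")) * out.mass[sp.NO_LESION]
    res.colonoscopies_performed = sum(positives.values()) + false_pos

    det_na = positives[NONADV_ADENOMA] * params.sensitivity("colonoscopy", NONADV_ADENOMA)
    det_aa = positives[ADV_ADENOMA] * params.sensitivity("colonoscopy", ADV_ADENOMA)
    det_pc = positives[PRECLIN_CRC] * params.sensitivity("colonoscopy", PRECLIN_CRC)
    _move(out, res, det_na, det_aa, det_pc)
    return out.check(), res


def apply_event(
    dist: StateDistribution, params: ParamSet, event: ScreeningEvent
) -> tuple[StateDistribution, EventResult]:
    if event.age != dist.age:
        raise ParamError(f"event scheduled at age {event.age} applied at age {dist.age}")
    fn = apply_fit if event.modality == "fit" else apply_colonoscopy
    return fn(dist, params, event.participation)


def run_screened(
    params: ParamSet,
    sex: str,
    start_age: int,
    horizon: int,
    events: tuple[ScreeningEvent, ...] | list[ScreeningEvent],
) -> tuple[list[tuple[StateDistribution, AnnualFlows]], list[EventResult]]:
    """Trajectory with scheduled screening events.

    Each year: the event offered at the current age (if any) is applied
    first, then the year is propagated; screen detections are booked into
    that year's flows.
    """
    from .natural_history import advance_year, initial_distribution
    from .parameters import AGE_MAX

    if start_age + horizon > AGE_MAX:
        raise ParamError(
            f"horizon {horizon} from age {start_age} exceeds maximum age {AGE_MAX}"
        )
    by_age = {}
    for ev in events:
        if ev.age in by_age:
            raise ParamError(f"multiple events at age {ev.age}")
        by_age[ev.age] = ev
    dist = initial_distribution(params, sex, start_age)
    traj, results = [], []
    for _ in range(horizon):
        screen_det = 0.0
        if dist.age in by_age:
            dist, res = apply_event(dist, params, by_age[dist.age])
            results.append(res)
            screen_det = res.detected_preclinical
        dist, flows = advance_year(dist, params)
        flows.new_clinical_screen = screen_det
        traj.append((dist, flows))
    return traj, results
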