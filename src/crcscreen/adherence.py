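"""Screening strategies and longitudinal adherence patterns.

Overall adherence over a program horizon is defined as

    (people screened / people invited) x (tests used / tests offered)

which separates *who* attends from *how often*.  Two pure patterns span the
same adherence level in opposite ways:

* **selective** — a fraction ``p`` of the population attends every offer,
  the rest never attend (second factor 1, level = ``p``);
* **sporadic** — everyone attends, but only a subset of the offered ages
  (first factor 1, level = attended / offered).

``build_cohort_plan`` turns a pattern into weighted sub-cohorts with
explicit event schedules for the deterministic engine; for the selective
pattern this makes every cumulative outcome an exact convex mixture of the
full-adherence and no-screening outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import AGE_MAX, AGE_MIN, ParamError
from .screening import ScreeningEvent

SELECTIVE = "selective"
SPORADIC = "sporadic"


@dataclass(frozen=True)
class ScreeningStrategy:
    """Test modality plus the explicit list of offered ages."""

    modality: str
    offered_ages: tuple[int, ...]

    def __post_init__(self):
        if self.modality not in ("fit", "colonoscopy"):
            raise ParamError(f"unknown modality {self.modality!r}")
        ages = self.offered_ages
        if not ages:
            raise ParamError("strategy offers no ages")
        if list(ages) != sorted(set(ages)):
            raise ParamError("offered ages must be strictly increasing")
        if ages[0] < AGE_MIN or ages[-1] > AGE_MAX:
            raise ParamError(f"offered ages must lie within [{AGE_MIN}, {AGE_MAX}]")

    @classmethod
    def annual_fit(cls, start: int = 50, stop: int = 75) -> "ScreeningStrategy":
        """Annual FIT offers from ``start`` to ``stop`` inclusive."""
        return cls("fit", tuple(range(start, stop + 1)))

    @classmethod
    def colonoscopy_at(cls, ages=(50, 60, 70)) -> "ScreeningStrategy":
        """Screening colonoscopy at the given ages (default 50/60/70)."""
        return cls("colonoscopy", tuple(ages))


@dataclass(frozen=True)
class AdherencePattern:
    """Selective (fraction ``p`` fully adherent) or sporadic (everyone, subset
    of offers) adherence."""

    variant: str
    p: float | None = None
    attended_ages: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.variant == SELECTIVE:
            if self.p is None or not (0.0 <= self.p <= 1.0):
                raise ParamError(f"selective fraction must be in [0, 1], got {self.p}")
        elif self.variant == SPORADIC:
            if not self.attended_ages:
                raise ParamError("sporadic pattern needs a non-empty attended-age set")
        else:
            raise ParamError(f"unknown adherence variant {self.variant!r}")

    @classmethod
    def selective(cls, p: float) -> "AdherencePattern":
        return cls(SELECTIVE, p=p)

    @classmethod
    def sporadic(cls, attended_ages) -> "AdherencePattern":
        return cls(SPORADIC, attended_ages=tuple(sorted(attended_ages)))

    @classmethod
    def sporadic_every(cls, k: int, strategy: ScreeningStrategy) -> "AdherencePattern":
        """Attend every ``k``-th offer, anchored at the first offered age."""
        if k < 1:
            raise ParamError(f"interval must be >= 1, got {k}")
        offered = strategy.offered_ages
        first = offered[0]
        ages = tuple(a for a in offered if (a - first) % k == 0)
        return cls.sporadic(ages)

    def describe(self) -> str:
        if self.variant == SELECTIVE:
            return f"selective p={self.p:g}"
        return f"sporadic ages={list(self.attended_ages)}"


def adherence_level(pattern: AdherencePattern, strategy: ScreeningStrategy) -> float:
    """Overall adherence of a pattern/strategy pair, in (0, 1]."""
    offered = strategy.offered_ages
    if not offered:
        raise ParamError("strategy offers no ages")
    if pattern.variant == SELECTIVE:
        return float(pattern.p)
    extra = set(pattern.attended_ages) - set(offered)
    if extra:
        raise ParamError(f"attended ages {sorted(extra)} are not offered by the strategy")
    return len(pattern.attended_ages) / len(offered)


def build_cohort_plan(
    pattern: AdherencePattern, strategy: ScreeningStrategy
) -> list[tuple[float, tuple[ScreeningEvent, ...]]]:
    """Weighted sub-cohorts with explicit schedules; weights sum to 1.

    Selective(p): weight ``p`` on the full schedule, ``1 - p`` unscreened.
    Sporadic(A):  one cohort attending exactly the ages in ``A``.
    """
    full = tuple(
        ScreeningEvent(strategy.modality, age, participation=1.0)
        for age in strategy.offered_ages
    )
    if pattern.variant == SELECTIVE:
        plan = []
        if pattern.p > 0.0:
            plan.append((float(pattern.p), full))
        if pattern.p < 1.0:
            plan.append((1.0 - float(pattern.p), ()))
        return plan
    adherence_level(pattern, strategy)  # validates subset
    events = tuple(
        ScreeningEvent(strategy.modality, age, participation=1.0)
        for age in pattern.attended_ages
    )
    return [(1.0, events)]
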