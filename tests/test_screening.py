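"""Screening events: detection arithmetic, conservation, dominance."""

import numpy as np
import pytest

from crcscreen import (
    ScreeningEvent,
    apply_colonoscopy,
    apply_fit,
    initial_distribution,
    run_screened,
    run_unscreened,
)
from crcscreen.parameters import (
    ADV_ADENOMA,
    MODE_SCREEN,
    NONADV_ADENOMA,
    PRECLIN_CRC,
    ParamError,
)
from conftest import set_prevalence, set_test_performance


def test_perfect_colonoscopy_clears_all_lesions(degenerates):
    dist = initial_distribution(degenerates["perfect-test"], "male", 50)
    out, res = apply_colonoscopy(dist, degenerates["perfect-test"], participation=1.0)
    sp = out.space
    assert out.mass[sp.NONADV] == 0.0
    assert out.mass[sp.ADV] == 0.0
    assert out.mass[sp.PRECLIN] == 0.0
    assert out.mass[sp.clin(MODE_SCREEN, 0)] == pytest.approx(
        dist.mass[sp.PRECLIN], abs=1e-15
    )
    assert out.total == pytest.approx(1.0, abs=1e-12)


def test_useless_test_changes_nothing(degenerates):
    ps = degenerates["useless-test"]
    dist = initial_distribution(ps, "female", 50)
    for apply in (apply_colonoscopy, apply_fit):
        out, res = apply(dist, ps, participation=1.0)
        np.testing.assert_array_equal(out.mass, dist.mass)
        assert res.detections_and_removals == 0.0


def test_colonoscopy_detection_arithmetic(default_params):
    """Sensitivity 0.9 on adenoma mass 0.10 at participation 0.5 moves 0.045."""
    ps = set_test_performance(
        default_params, "colonoscopy",
        sensitivity={NONADV_ADENOMA: 0.9, ADV_ADENOMA: 0.9, PRECLIN_CRC: 0.9},
    )
    ps = set_prevalence(ps, {NONADV_ADENOMA: 0.10, ADV_ADENOMA: 0.0, PRECLIN_CRC: 0.0})
    dist = initial_distribution(ps, "male", 50)
    out, res = apply_colonoscopy(dist, ps, participation=0.5)
    assert res.removed_nonadvanced == pytest.approx(0.045, abs=1e-15)
    assert out.mass[out.space.NONADV] == pytest.approx(0.055, abs=1e-15)


def test_fit_detection_uses_product_of_sensitivities(default_params):
    """FIT positives get a diagnostic colonoscopy: detected preclinical mass
    is sens_FIT x sens_colo x mass."""
    ps = set_test_performance(default_params, "fit",
                              sensitivity={PRECLIN_CRC: 0.8}, specificity=1.0)
    ps = set_test_performance(ps, "colonoscopy", sensitivity={PRECLIN_CRC: 1.0})
    ps = set_prevalence(ps, {NONADV_ADENOMA: 0.0, ADV_ADENOMA: 0.0, PRECLIN_CRC: 0.01})
    dist = initial_distribution(ps, "male", 50)
    out, res = apply_fit(dist, ps, participation=1.0)
    assert res.detected_preclinical == pytest.approx(0.008, abs=1e-15)
    assert out.mass[out.space.clin(MODE_SCREEN, 0)] == pytest.approx(0.008, abs=1e-15)


def test_fit_false_positive_colonoscopies(default_params):
    """Specificity 0.95 on lesion-free mass 0.9 books 0.045 follow-up scopes."""
    ps = set_test_performance(
        default_params, "fit",
        sensitivity={NONADV_ADENOMA: 0.0, ADV_ADENOMA: 0.0, PRECLIN_CRC: 0.0},
        specificity=0.95,
    )
    ps = set_prevalence(ps, {NONADV_ADENOMA: 0.06, ADV_ADENOMA: 0.03, PRECLIN_CRC: 0.01})
    dist = initial_distribution(ps, "male", 50)  # lesion-free mass 0.9
    out, res = apply_fit(dist, ps, participation=1.0)
    assert res.colonoscopies_performed == pytest.approx(0.045, abs=1e-15)
    np.testing.assert_array_equal(out.mass, dist.mass)


def test_fit_with_perfect_specificity_and_zero_sensitivity_is_a_noop(degenerates):
    ps = degenerates["useless-test"]  # sens 0, specificity 1
    dist = initial_distribution(ps, "male", 50)
    out, res = apply_fit(dist, ps, participation=1.0)
    assert res.colonoscopies_performed == 0.0
    np.testing.assert_array_equal(out.mass, dist.mass)


def test_fit_equals_colonoscopy_at_unit_sensitivity(degenerates):
    """With all sensitivities 1 and specificity 1 the two-stage FIT pathway
    coincides with primary colonoscopy state-for-state."""
    ps = degenerates["perfect-test"]
    dist = initial_distribution(ps, "female", 50)
    via_fit, _ = apply_fit(dist, ps, participation=1.0)
    via_colo, _ = apply_colonoscopy(dist, ps, participation=1.0)
    np.testing.assert_allclose(via_fit.mass, via_colo.mass, atol=1e-15)


def test_diagnosed_crc_is_outside_the_screening_pool(default_params):
    dist = initial_distribution(default_params, "male", 50)
    sp = dist.space
    dist.mass[sp.clin(MODE_SCREEN, 2)] += 0.1
    dist.mass[sp.NO_LESION] -= 0.1
    before = dist.mass[sp.clin(MODE_SCREEN, 2)]
    out, res = apply_colonoscopy(dist, default_params, participation=1.0)
    assert out.mass[sp.clin(MODE_SCREEN, 2)] == before
    undiagnosed = (
        dist.mass[sp.NO_LESION] + dist.mass[sp.NONADV]
        + dist.mass[sp.ADV] + dist.mass[sp.PRECLIN]
    )
    assert res.colonoscopies_performed == pytest.approx(undiagnosed, abs=1e-15)


def test_screening_dominance(default_params, degenerates):
    """Any screening prevents cases vs baseline; higher sensitivity prevents
    at least as many as lower sensitivity."""
    events = tuple(ScreeningEvent("colonoscopy", a) for a in (50, 60, 70))
    base = run_unscreened(default_params, "male", 50, 50)
    screened, _ = run_screened(default_params, "male", 50, 50, events)
    perfect, _ = run_screened(degenerates["perfect-test"], "male", 50, 50, events)

    def cases(traj):
        return sum(f.new_clinical_symptom + f.new_clinical_screen for _, f in traj)

    assert cases(screened) <= cases(base)
    assert cases(perfect) <= cases(screened)


def test_event_validation(default_params):
    with pytest.raises(ParamError, match="participation"):
        ScreeningEvent("fit", 50, participation=1.5)
    with pytest.raises(ParamError, match="modality"):
        ScreeningEvent("sigmoidoscopy", 50)
    dist = initial_distribution(default_params, "male", 50)
    with pytest.raises(ParamError, match="scheduled at age"):
        from crcscreen import apply_event

        apply_event(dist, default_params, ScreeningEvent("fit", 60))
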