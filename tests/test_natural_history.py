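"""Cohort propagation: oracles, conservation laws, closed forms."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from crcscreen import (
    DEFAULT_SPEC,
    ParamError,
    advance_year,
    generate_param_set,
    initial_distribution,
    run_unscreened,
)
from crcscreen.parameters import (
    ADV_ADENOMA,
    CLIN_CRC,
    MODE_SCREEN,
    MODE_SYMPTOM,
    NONADV_ADENOMA,
    NO_LESION,
    PRECLIN_CRC,
)
from conftest import set_constant_mortality, set_prevalence, set_transitions


def test_initial_distribution_is_prevalence_complement(default_params):
    ps = set_prevalence(
        default_params,
        {NONADV_ADENOMA: 0.20, ADV_ADENOMA: 0.05, PRECLIN_CRC: 0.002},
    )
    dist = initial_distribution(ps, "male", 50)
    sp = dist.space
    assert dist.mass[sp.NO_LESION] == pytest.approx(0.748, abs=1e-15)
    assert dist.mass[sp.NONADV] == 0.20
    assert dist.mass[sp.ADV] == 0.05
    assert dist.mass[sp.PRECLIN] == 0.002
    assert dist.mass[sp.clin_slice(MODE_SCREEN)].sum() == 0.0
    assert dist.mass[sp.clin_slice(MODE_SYMPTOM)].sum() == 0.0
    assert dist.total == pytest.approx(1.0, abs=1e-15)


def test_null_params_without_mortality_advance_is_identity(degenerates):
    ps = set_constant_mortality(degenerates["null"], q=0.0)
    dist = initial_distribution(ps, "male", 50)
    out, flows = advance_year(dist, ps)
    assert out.age == 51
    np.testing.assert_array_equal(out.mass, dist.mass)
    assert flows.crc_deaths == flows.other_deaths == 0.0


def test_pure_attrition_matches_closed_form(degenerates):
    """With no lesions and constant all-cause rate q, alive mass after n
    years is (1 - q)^n."""
    q = 0.02
    ps = set_constant_mortality(degenerates["null"], q=q)
    traj = run_unscreened(ps, "female", 50, 30)
    for n, (dist, _) in enumerate(traj, start=1):
        assert dist.alive == pytest.approx((1 - q) ** n, abs=1e-12)


def _age_independent_params(r=(0.02, 0.03, 0.04, 0.25), q=0.015, mu=0.08):
    """Constant-rate chain whose 50-year behaviour has an explicit matrix."""
    base = generate_param_set(DEFAULT_SPEC)
    ps = set_transitions(
        base,
        {
            (NO_LESION, NONADV_ADENOMA): r[0],
            (NONADV_ADENOMA, ADV_ADENOMA): r[1],
            (ADV_ADENOMA, PRECLIN_CRC): r[2],
            (PRECLIN_CRC, CLIN_CRC): r[3],
        },
    )
    # cap beyond the horizon so CRC mortality stays constant for 50 years
    ps = set_constant_mortality(ps, q=q, crc=mu, ysd_cap=60)
    return set_prevalence(
        ps, {NONADV_ADENOMA: 0.1, ADV_ADENOMA: 0.05, PRECLIN_CRC: 0.01}
    )


def test_matrix_power_oracle_equivalence():
    """The engine's n-year distribution equals the n-th power of the explicit
    one-year transition matrix for an age-independent chain.

    Oracle: 7 aggregated states (4 lesion-free/lesion, clinical CRC, two dead
    states); the one-year matrix composes progression, CRC death, and
    other-cause death in the documented order.
    """
    r1, r2, r3, r4 = 0.02, 0.03, 0.04, 0.25
    q, mu = 0.015, 0.08
    ps = _age_independent_params((r1, r2, r3, r4), q, mu)

    NO, NA, AA, PC, CC, DC, DO = range(7)
    prog = np.eye(7)
    prog[NO, NO], prog[NO, NA] = 1 - r1, r1
    prog[NA, NA], prog[NA, AA] = 1 - r2, r2
    prog[AA, AA], prog[AA, PC] = 1 - r3, r3
    prog[PC, PC], prog[PC, CC] = 1 - r4, r4
    crc = np.eye(7)
    crc[CC, CC], crc[CC, DC] = 1 - mu, mu
    other = np.eye(7)
    for s in (NO, NA, AA, PC, CC):
        other[s, s], other[s, DO] = 1 - q, q
    P = prog @ crc @ other

    x0 = np.zeros(7)
    x0[NO], x0[NA], x0[AA], x0[PC] = 0.84, 0.1, 0.05, 0.01

    traj = run_unscreened(ps, "male", 50, 50)
    for n in (1, 5, 25, 50):
        expected = x0 @ np.linalg.matrix_power(P, n)
        dist = traj[n - 1][0]
        sp = dist.space
        got = np.array(
            [
                dist.mass[sp.NO_LESION],
                dist.mass[sp.NONADV],
                dist.mass[sp.ADV],
                dist.mass[sp.PRECLIN],
                dist.mass[sp.clin_slice(MODE_SCREEN)].sum()
                + dist.mass[sp.clin_slice(MODE_SYMPTOM)].sum(),
                dist.mass[sp.DEAD_CRC],
                dist.mass[sp.DEAD_OTHER],
            ]
        )
        np.testing.assert_allclose(got, expected, atol=1e-10)


@settings(max_examples=8, derandomize=True, deadline=None)
@given(seed=st.integers(0, 50), sex=st.sampled_from(["male", "female"]))
def test_mass_conserved_and_dead_states_absorbing(seed, sex):
    ps = generate_param_set(replace(DEFAULT_SPEC, seed=seed))
    traj = run_unscreened(ps, sex, 50, 50)
    prev_dead = 0.0
    for dist, _ in traj:
        assert abs(dist.total - 1.0) <= 1e-12
        assert np.all(dist.mass >= -1e-15)
        dead = dist.mass[dist.space.DEAD_CRC] + dist.mass[dist.space.DEAD_OTHER]
        assert dead >= prev_dead - 1e-15
        prev_dead = dead


def test_cumulative_diagnoses_match_mass_entering_clinical_state(default_params):
    """With death switched off, everyone ever diagnosed is still in a
    clinical substate, so summed diagnosis flows must equal the clinical
    mass at the end of the run."""
    ps = set_constant_mortality(default_params, q=0.0, crc=0.0)
    traj = run_unscreened(ps, "male", 50, 50)
    total_dx = sum(f.new_clinical_symptom for _, f in traj)
    end = traj[-1][0]
    clin_mass = (
        end.mass[end.space.clin_slice(MODE_SCREEN)].sum()
        + end.mass[end.space.clin_slice(MODE_SYMPTOM)].sum()
    )
    assert total_dx == pytest.approx(clin_mass, abs=1e-12)
    assert total_dx > 0.0


def test_horizon_limits_are_enforced(default_params):
    with pytest.raises(ParamError, match="exceeds"):
        run_unscreened(default_params, "male", 50, 51)
    dist = initial_distribution(default_params, "male", 50)
    dist.age = 100
    with pytest.raises(ParamError, match="beyond age"):
        advance_year(dist, default_params)
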