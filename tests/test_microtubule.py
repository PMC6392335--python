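import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitosim import (
    CorticalField,
    Microtubule,
    cortex_forces,
    grow_bud,
    init_cell,
    modulate_by_load,
    step_instability,
)
from mitosim.microtubule import (
    buckling_force,
    mean_elongation_rate,
    sample_free_lengths,
    sliding_update,
    stationary_mean_length,
)


# ---------------- load modulation -------------------------------------
def test_zero_load_identities(params):
    v, c = modulate_by_load(params, 0.0)
    assert v == pytest.approx(params.v_g)
    assert c == pytest.approx(params.f_c)


def test_stall_limit(params):
    v, c = modulate_by_load(params, 1e3)
    assert v == pytest.approx(0.0, abs=1e-12)
    assert c == pytest.approx(params.f_c_stall * 60.0)  # 0.04/s = 2.4/min


def test_one_stall_force_of_load(params):
    v, _ = modulate_by_load(params, params.f_stall)
    assert v == pytest.approx(10.4 / math.e, rel=1e-12)


@settings(max_examples=60, deadline=None)
@given(st.floats(0.0, 20.0), st.floats(0.01, 5.0))
def test_load_monotonicity(f1, delta):
    from mitosim import load_params

    params = load_params(None)
    v1, c1 = modulate_by_load(params, f1)
    v2, c2 = modulate_by_load(params, f1 + delta)
    assert v2 < v1
    assert c2 > c1  # f_c_stall (2.4/min) exceeds f_c0 (1/min)


def test_negative_load_rejected(params):
    with pytest.raises(ValueError):
        modulate_by_load(params, -1.0)


# ---------------- free-space dynamic instability ------------------------
def test_stationary_mean_length_closed_form(params):
    # v_g*v_s / (v_s*f_c - v_g*f_r) with the measured rates
    assert stationary_mean_length(params) == pytest.approx(10.476, abs=0.01)


def test_unbounded_growth_regime_flagged(params):
    runaway = params.replace(f_c=0.005, f_r=0.5)  # v_s*f_c < v_g*f_r
    assert mean_elongation_rate(runaway) > 0
    with pytest.raises(ValueError, match="unbounded"):
        stationary_mean_length(runaway)


def test_free_length_distribution_matches_closed_form(params):
    # stochastic oracle: simulated stationary mean within 2 % of theory
    lengths = sample_free_lengths(params, n_samples=100_000, seed=99)
    assert np.mean(lengths) == pytest.approx(stationary_mean_length(params), rel=0.02)


def test_exponential_waiting_time_of_catastrophe(params, rng):
    # unloaded growing lifetime ~ Exp(f_c); mean = 1/f_c = 1 min
    times = []
    for _ in range(400):
        mt = Microtubule(0, np.zeros(3), np.array([0.0, 0.0, 1.0]), length=1.0)
        t = 0.0
        while mt.growing and t < 30.0:
            step_instability(mt, params, rng, dt_s=1.0)
            t += 1.0 / 60.0
        times.append(t)
    assert np.mean(times) == pytest.approx(1.0, rel=0.15)


# ---------------- cortex interaction -----------------------------------
@pytest.fixture(scope="module")
def engaged_mt(params):
    """A cMT whose plus end sits in the mother cortex, away from the bud."""
    geom, asm = init_cell(params, 5)
    geom = grow_bud(geom, geom.bud_growth_duration_s / 2)
    direction = -geom.bud_axis
    anchor = direction * (params.r_mother - 2.0)
    length = 2.0 - params.w_cor / 2
    mt = Microtubule(0, anchor, direction, length)
    mt.l_cor = 0.2
    return geom, mt


def test_push_magnitude_hand_value(params, engaged_mt):
    geom, mt = engaged_mt
    mt.l_cor = 0.2
    field = CorticalField.from_params(params)
    rep = cortex_forces(mt, geom, field, params, geom.time_s)
    assert np.linalg.norm(rep.f_push) == pytest.approx(0.2 * 5.0)  # 1.0 pN
    # push points inward, against the rod axis
    assert rep.f_push @ mt.direction < 0


def test_pull_magnitude_hand_value(params, engaged_mt):
    geom, mt = engaged_mt
    mt.l_cor = 0.3
    field = CorticalField.from_params(params)
    rep = cortex_forces(mt, geom, field, params, geom.time_s)
    assert np.linalg.norm(rep.f_pull) == pytest.approx(0.3 * 6.0 * 1.0)  # 1.8 pN
    assert rep.f_pull @ mt.direction > 0


def test_forces_vanish_outside_cortex(params):
    geom, _ = init_cell(params, 5)
    mt = Microtubule(0, np.zeros(3), np.array([1.0, 0.0, 0.0]), length=0.5)
    field = CorticalField.from_params(params)
    rep = cortex_forces(mt, geom, field, params, 0.0)
    for f in (rep.f_push, rep.f_pull, rep.f_wall, rep.f_buckling, rep.f_bim1):
        np.testing.assert_allclose(f, 0.0)


def test_buckling_force_quarter_on_doubling(params):
    assert buckling_force(params, 2.0) == pytest.approx(buckling_force(params, 1.0) / 4)


def test_sliding_threshold_branches(params):
    geom, _ = init_cell(params, 5)
    away = -geom.bud_axis
    # anchor just below the surface so the local normal barely rotates
    anchor = away * (params.r_mother - 0.05)
    normal = away
    tang = np.cross(normal, [0.0, 0.0, 1.0])
    tang /= np.linalg.norm(tang)
    # 5 degrees above the tangent plane -> sliding branch
    shallow_dir = math.cos(math.radians(5)) * tang + math.sin(math.radians(5)) * normal
    mt = Microtubule(0, anchor, shallow_dir, length=0.0)
    mt.length = _length_to_boundary(anchor, shallow_dir, params.r_mother)
    out = sliding_update(mt, geom, params.sliding_angle_deg, 0.0)
    assert out.sliding and not out.buckling

    steep_dir = normal  # radial hit, 90 degrees from the surface
    mt2 = Microtubule(0, anchor, steep_dir, length=0.0)
    mt2.length = _length_to_boundary(anchor, steep_dir, params.r_mother)
    out2 = sliding_update(mt2, geom, params.sliding_angle_deg, 0.0)
    assert out2.buckling and not out2.sliding


def _length_to_boundary(anchor, direction, radius):
    b = anchor @ direction
    c = anchor @ anchor - radius**2
    return float(-b + math.sqrt(b * b - c))
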