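import math

import numpy as np
import pytest

from mitosim import (
    CorticalField,
    Microtubule,
    apply_scenario_perturbation,
    effective_bias,
    grow_bud,
    init_cell,
    local_dynein_density,
    make_scenario,
)
from mitosim.cortex import bim1_bias_force, in_daughter_patch, ring_direction


@pytest.fixture(scope="module")
def full_bud(params):
    geom, asm = init_cell(params, 9)
    return grow_bud(geom, geom.bud_growth_duration_s)


def _mother_cortex_point(params, geom):
    return -geom.bud_axis * (params.r_mother - params.w_cor / 2)


def _daughter_point(params, geom, apex=True):
    c = geom.bud_center()
    direction = geom.bud_axis if apex else _perp(geom.bud_axis)
    return c + direction * (geom.bud_radius() - params.w_cor / 2)


def _perp(v):
    w = np.cross(v, [1.0, 0.0, 0.0])
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(v, [0.0, 1.0, 0.0])
    return w / np.linalg.norm(w)


def test_mother_base_density(params, full_bud):
    field = CorticalField.from_params(params)
    p = _mother_cortex_point(params, full_bud)
    assert local_dynein_density(field, full_bud, p, full_bud.time_s) == pytest.approx(6.0)


def test_daughter_patch_density(params, full_bud):
    field = CorticalField.from_params(params.replace(lambda_dynein_patch=2.0))
    apex = _daughter_point(params, full_bud, apex=True)
    assert in_daughter_patch(field, full_bud, apex, full_bud.time_s)
    assert local_dynein_density(field, full_bud, apex, full_bud.time_s) == pytest.approx(12.0)


def test_daughter_background_zero(params, full_bud):
    field = CorticalField.from_params(params.replace(lambda_dynein_rest=0.0))
    side = _daughter_point(params, full_bud, apex=False)
    assert not in_daughter_patch(field, full_bud, side, full_bud.time_s)
    assert local_dynein_density(field, full_bud, side, full_bud.time_s) == 0.0


def test_interior_point_rejected(params, full_bud):
    field = CorticalField.from_params(params)
    with pytest.raises(ValueError):
        local_dynein_density(field, full_bud, np.zeros(3), full_bud.time_s)


def test_uniform_reduction_invariant(params):
    # patch = rest = 1 and B = 1 reduces to the uniform base field
    field = CorticalField.from_params(params)
    assert field.patch_multiplier == field.rest_multiplier == 1.0
    assert field.bias_scale == 1.0


# ---------------- Bim1 bias force -------------------------------------
def _engaged_mother_mt(params, geom):
    # off-axis so the tangent toward the ring is well defined
    radial = -geom.bud_axis + 0.6 * _perp(geom.bud_axis)
    radial /= np.linalg.norm(radial)
    anchor = radial * (params.r_mother - 2.0)
    mt = Microtubule(0, anchor, radial, length=2.0 - params.w_cor / 2)
    mt.l_cor = 0.3
    return mt


def test_bim1_force_magnitude_and_direction(params, full_bud):
    field = CorticalField.from_params(params)
    mt = _engaged_mother_mt(params, full_bud)
    f = bim1_bias_force(mt, field, full_bud, params, full_bud.time_s)
    assert np.linalg.norm(f) == pytest.approx(0.3 * 6.0 * 1.0, rel=1e-6)  # 1.8 pN
    # tangential to the cortex ...
    normal = -mt.tip_position / np.linalg.norm(mt.tip_position)
    assert abs(f @ normal) < 1e-9
    # ... and pointing toward the ring side (positive along the bud axis here)
    assert f @ full_bud.bud_axis > 0


def test_bim1_force_zero_without_bim1(params, full_bud):
    field = CorticalField.from_params(params.replace(lambda_bim1=0.0))
    mt = _engaged_mother_mt(params, full_bud)
    np.testing.assert_allclose(bim1_bias_force(mt, field, full_bud, params, full_bud.time_s), 0.0)


def test_bim1_force_zero_in_daughter(params, full_bud):
    field = CorticalField.from_params(params)
    tip = _daughter_point(params, full_bud, apex=True)
    anchor = full_bud.bud_center()
    d = tip - anchor
    mt = Microtubule(0, anchor, d / np.linalg.norm(d), length=float(np.linalg.norm(d)))
    mt.l_cor = 0.3
    np.testing.assert_allclose(bim1_bias_force(mt, field, full_bud, params, full_bud.time_s), 0.0)


def test_ring_direction_is_unit_tangent(params, full_bud):
    p = _mother_cortex_point(params, full_bud)
    n = -p / np.linalg.norm(p)
    t = ring_direction(full_bud, p, n, full_bud.time_s)
    assert np.linalg.norm(t) == pytest.approx(1.0)
    assert abs(t @ n) < 1e-9


# ---------------- length-dependent bias --------------------------------
def test_bias_is_one_at_reference_length(params):
    assert effective_bias(2.63, params) == 1.0


def test_bias_hand_value_for_mutant_length(params):
    p = params.replace(bias_length_const=0.65)
    assert effective_bias(1.3, p) == pytest.approx(math.exp(-2.046), rel=1e-3)


def test_bias_saturates_for_long_mts(params):
    assert effective_bias(50.0, params) == 1.0


def test_bias_uniform_limit(params):
    p = params.replace(bias_length_const=1e9)
    for length in (0.1, 1.0, 2.63, 10.0):
        assert effective_bias(length, p) == pytest.approx(1.0)


# ---------------- scenario perturbations --------------------------------
def test_wild_type_is_identity(params):
    field = CorticalField.from_params(params)
    assert apply_scenario_perturbation(field, make_scenario("wild_type_cib")) == field


def test_dyn1_overexpression_triples_mother_density(params, full_bud):
    field = CorticalField.from_params(params)
    out = apply_scenario_perturbation(field, make_scenario("dyn1_oe"))
    p = _mother_cortex_point(params, full_bud)
    assert local_dynein_density(out, full_bud, p, full_bud.time_s) == pytest.approx(18.0)
    side = _daughter_point(params, full_bud, apex=False)
    assert local_dynein_density(out, full_bud, side, full_bud.time_s) == pytest.approx(6.0)


def test_bim1_delta_zeroes_bim1(params):
    field = CorticalField.from_params(params)
    out = apply_scenario_perturbation(field, make_scenario("bim1_delta"))
    assert out.lambda_bim1 == 0.0


def test_puncta_scan_multipliers(params, full_bud):
    field = CorticalField.from_params(params)
    sc = make_scenario(
        "dynein_puncta_scan",
        {"lambda_dynein_patch": 2.0, "lambda_dynein_rest": 0.5},
    )
    out = apply_scenario_perturbation(field, sc)
    apex = _daughter_point(params, full_bud, apex=True)
    side = _daughter_point(params, full_bud, apex=False)
    assert local_dynein_density(out, full_bud, apex, full_bud.time_s) == pytest.approx(12.0)
    assert local_dynein_density(out, full_bud, side, full_bud.time_s) == pytest.approx(3.0)
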