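import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitosim import Region, classify_point, grow_bud, init_cell, neck_to_nucleus_distance
from mitosim.geometry import PlacementError


@pytest.fixture(scope="module")
def cell(params):
    return init_cell(params, rng_seed=5)


def test_mtocs_sit_on_the_nuclear_envelope(params, cell):
    _, asm = cell
    assert asm.mtoc_positions.shape == (14, 3)
    d = np.linalg.norm(asm.mtoc_positions - asm.nucleus_center, axis=1)
    np.testing.assert_allclose(d, 1.0, atol=1e-9)


def test_mtocs_do_not_overlap(params, cell):
    _, asm = cell
    n = asm.n_bodies
    for i in range(n):
        for j in range(i + 1, n):
            assert (
                np.linalg.norm(asm.mtoc_positions[i] - asm.mtoc_positions[j])
                >= 2 * params.r_spb - 1e-12
            )


def test_same_seed_is_bit_identical(params):
    g1, a1 = init_cell(params, 42)
    g2, a2 = init_cell(params, 42)
    assert np.array_equal(g1.bud_axis, g2.bud_axis)
    assert np.array_equal(a1.nucleus_center, a2.nucleus_center)
    assert np.array_equal(a1.mtoc_positions, a2.mtoc_positions)


def test_single_mtoc_degenerate_case(params):
    _, asm = init_cell(params.replace(n_kt=1), 3)
    assert asm.n_bodies == 1
    assert asm.clustering_complete


def test_pathological_placement_raises(params):
    with pytest.raises(PlacementError):
        init_cell(params.replace(r_spb=0.9, n_kt=14), 1)


def test_bud_growth_law(params, cell):
    geom, _ = cell
    T = geom.bud_growth_duration_s
    assert grow_bud(geom, 0.0).budding_index() == 0.0
    half = grow_bud(geom, T / 2)
    assert half.budding_index() == pytest.approx(params.final_budding_index / 2)
    done = grow_bud(geom, T)
    later = grow_bud(geom, 2 * T)
    assert done.budding_index() == later.budding_index() == params.final_budding_index


def test_bud_radius_monotone_and_septin_circle_consistent(params, cell):
    geom, _ = cell
    T = geom.bud_growth_duration_s
    prev = -1.0
    for t in np.linspace(0, 1.5 * T, 40):
        g = grow_bud(geom, t)
        rb = g.bud_radius()
        assert rb >= prev
        prev = rb
        if rb > 0:
            # the septin circle lies on both spheres
            a = g.neck_radius()
            x_pl = g.septin_plane_distance()
            assert math.hypot(x_pl, a) == pytest.approx(params.r_mother, rel=1e-9)
            d = np.linalg.norm(g.bud_center())
            assert math.hypot(d - x_pl, a) == pytest.approx(rb, rel=1e-9)


def test_classify_center_of_mother(params, cell):
    geom, _ = cell
    pc = classify_point(geom, np.zeros(3), t_s=0.0)
    assert pc.region == Region.MOTHER_INTERIOR
    assert pc.boundary_distance == pytest.approx(3.0)


def test_classify_cortex_shell(params, cell):
    geom, _ = cell
    away = -geom.bud_axis  # opposite the bud
    p = away * (params.r_mother - params.w_cor / 2)
    assert classify_point(geom, p, 0.0).region == Region.MOTHER_CORTEX


def test_classify_daughter_cortex(params, cell):
    geom, _ = cell
    g = grow_bud(geom, geom.bud_growth_duration_s)  # full bud
    tip = g.bud_center() + g.bud_axis * (g.bud_radius() - params.w_cor / 2)
    assert classify_point(g, tip, g.time_s).region == Region.DAUGHTER_CORTEX


def test_outside_point_is_out_of_domain(params, cell):
    geom, _ = cell
    pc = classify_point(geom, np.array([10.0, 0.0, 0.0]), 0.0)
    assert pc.region == Region.OUTSIDE
    assert pc.boundary_distance < 0


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10**6))
def test_every_interior_point_gets_exactly_one_region(seed):
    from mitosim import load_params

    params = load_params(None)
    geom, _ = init_cell(params, 7)
    g = grow_bud(geom, geom.bud_growth_duration_s / 2)
    rng = np.random.default_rng(seed)
    p = rng.uniform(-4, 6, size=3)
    pc = classify_point(g, p, g.time_s)
    assert pc.region in (
        Region.MOTHER_INTERIOR,
        Region.DAUGHTER_INTERIOR,
        Region.MOTHER_CORTEX,
        Region.DAUGHTER_CORTEX,
        Region.OUTSIDE,
    )
    # depth sign must agree with the sphere-union membership
    inside = np.linalg.norm(p) < params.r_mother or np.linalg.norm(
        p - g.bud_center()
    ) < g.bud_radius()
    assert (pc.boundary_distance >= 0) == inside
    assert np.linalg.norm(pc.inward_normal) == pytest.approx(1.0)


def test_neck_distance_signs(params, cell):
    geom, asm = cell
    g = grow_bud(geom, geom.bud_growth_duration_s)
    x_pl = g.septin_plane_distance()
    on_plane = g.bud_axis * x_pl
    assert neck_to_nucleus_distance(g, on_plane) == pytest.approx(0.0)
    # nucleus at the mother centre: distance is minus the plane offset
    assert neck_to_nucleus_distance(g, np.zeros(3)) == pytest.approx(-x_pl)
    in_daughter = g.bud_axis * (x_pl + 1.3)
    assert neck_to_nucleus_distance(g, in_daughter) > 0
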