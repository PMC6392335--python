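import numpy as np
import pytest

from mitosim import (
    SpindleState,
    duplicate_spb,
    fuse_mtocs,
    init_cell,
    ipmt_force,
    kmt_kt_forces,
    kmt_length_catastrophe,
    kt_pair_forces,
)


def _two_body_assembly(params, distance):
    _, asm = init_cell(params.replace(n_kt=2), 21)
    c = asm.nucleus_center
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([np.cos(distance), np.sin(distance), 0.0])  # arc ~ chord for small d
    asm.mtoc_positions = np.stack([c + u, c + v * 1.0])
    # place at exact chord distance
    chord = np.linalg.norm(asm.mtoc_positions[0] - asm.mtoc_positions[1])
    return asm, chord


def test_fusion_conserves_volume(params):
    asm, _ = _two_body_assembly(params, 0.249)
    total_volume = np.sum(asm.mtoc_radii**3)
    events = fuse_mtocs(asm, contact_tolerance=1e-3)
    assert len(events) == 1
    assert asm.n_bodies == 1
    assert asm.mtoc_radii[0] ** 3 == pytest.approx(total_volume)
    assert asm.mtoc_radii[0] == pytest.approx(0.125 * 2 ** (1 / 3))
    # merged body re-projected onto the NE
    assert np.linalg.norm(asm.mtoc_positions[0] - asm.nucleus_center) == pytest.approx(1.0)
    # kinetochores re-associate with the merged body
    assert set(asm.kt_mtoc.tolist()) == {0}


def test_no_merge_beyond_contact(params):
    asm, _ = _two_body_assembly(params, 1.0)
    assert fuse_mtocs(asm) == []
    assert asm.n_bodies == 2


def test_single_body_is_noop(params):
    _, asm = init_cell(params.replace(n_kt=1), 3)
    assert fuse_mtocs(asm) == []
    assert asm.clustering_complete


def test_fusion_cascade_is_monotone(params):
    _, asm = init_cell(params, 8)
    # collapse all bodies onto a small cap so everything touches
    c = asm.nucleus_center
    u = asm.mtoc_positions[0] - c
    rng = np.random.default_rng(0)
    jitter = rng.normal(scale=0.05, size=(asm.n_bodies, 3))
    pos = c + (u + jitter) / np.linalg.norm(u + jitter, axis=1, keepdims=True)
    asm.mtoc_positions = pos
    events = fuse_mtocs(asm)
    remaining = [e.n_remaining for e in events]
    assert remaining == sorted(remaining, reverse=True)
    assert asm.n_bodies == 1
    assert asm.mtoc_founders[0] == 14


# ---------------- spindle forces ---------------------------------------
def _spindle(params, overlap):
    spb = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
    return SpindleState(
        spb_positions=spb,
        ipmt_overlap=overlap,
        kmt_spb=np.zeros(2, dtype=int),
        l_pen=np.zeros(2),
        l_gap=np.zeros(2),
    )


def test_ipmt_force_hand_value(params):
    f = ipmt_force(_spindle(params, overlap=2.0), params)
    np.testing.assert_allclose(f[0], [-2.0, 0, 0])  # 2 um * 1/um * 1 pN
    np.testing.assert_allclose(f[1], [2.0, 0, 0])
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)


def test_ipmt_zero_overlap_and_linearity(params):
    assert np.allclose(ipmt_force(_spindle(params, 0.0), params), 0.0)
    double = params.replace(lambda_ipmt=2.0)
    f1 = ipmt_force(_spindle(params, 1.0), params)
    f2 = ipmt_force(_spindle(params, 1.0), double)
    np.testing.assert_allclose(f2, 2 * f1)


def test_kmt_push_and_pull_hand_values(params):
    sp = _spindle(params, 0.0)
    kt = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    sp.l_pen = np.array([0.05, 0.0])
    sp.l_gap = np.array([0.0, 0.1])
    f_kt, f_spb = kmt_kt_forces(sp, kt, params)
    assert np.linalg.norm(f_kt[0]) == pytest.approx(0.05 * 5.0)   # 0.25 pN push
    assert f_kt[0] @ np.array([1.0, 0, 0]) > 0                    # away from the pole
    assert np.linalg.norm(f_kt[1]) == pytest.approx(0.1 * 10.0)   # 1.0 pN pull
    assert f_kt[1] @ np.array([0, 1.0, 0]) < 0                    # toward the pole
    # action-reaction bookkeeping
    np.testing.assert_allclose(f_kt.sum(axis=0) + f_spb.sum(axis=0), 0.0, atol=1e-12)


def test_cohesin_and_repulsion_hand_values(params):
    kt = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
    f = kt_pair_forces(kt, params)
    # sisters at 0.5 um: cohesin 0.05 pN attraction; no overlap (2*r_kt = 0.2)
    assert f[0] @ np.array([1.0, 0, 0]) == pytest.approx(0.05)
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)

    overlapping = np.array([[0.0, 0.0, 0.0], [0.18, 0.0, 0.0]])
    f2 = kt_pair_forces(overlapping, params, sister_pairs=np.empty((0, 2), dtype=int))
    assert f2[0] @ np.array([1.0, 0, 0]) == pytest.approx(-0.02)  # 0.02 pN apart


def test_coincident_unlinked_pair_is_forceless(params):
    kt = np.zeros((2, 3))
    f = kt_pair_forces(kt, params)
    np.testing.assert_allclose(f, 0.0)


@pytest.mark.parametrize("l, expected", [(0.0, 0.0), (0.8, 40.0), (1.6, 80.0)])
def test_kmt_length_catastrophe_linear(params, l, expected):
    assert kmt_length_catastrophe(l, params) == pytest.approx(expected)
    with pytest.raises(ValueError):
        kmt_length_catastrophe(-1.0, params)


def test_duplicate_spb_contract(params, rng):
    _, asm = init_cell(params, 12)
    with pytest.raises(ValueError):
        duplicate_spb(asm, params, rng)  # clustering incomplete
    fused_volume = np.sum(asm.mtoc_radii**3)
    asm.mtoc_positions = asm.mtoc_positions[:1]
    asm.mtoc_radii = np.array([fused_volume ** (1 / 3)])
    asm.mtoc_founders = np.array([14])
    asm.kt_mtoc[:] = 0
    duplicate_spb(asm, params, rng)
    assert asm.spb_positions.shape == (2, 3)
    d = np.linalg.norm(asm.spb_positions - asm.nucleus_center, axis=1)
    np.testing.assert_allclose(d, params.r_nuc, atol=1e-9)
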