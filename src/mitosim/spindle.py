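"""Intranuclear mechanics: MTOC fusion, SPB duplication, ipMTs and kMTs.

The founding MTOCs coalesce on the nuclear envelope: any two bodies whose
surfaces touch merge into one body at their volume-weighted midpoint
(re-projected onto the NE), with the merged radius conserving volume
(r^3 additive).  Clustering is complete when a single body carries every
founder; that event triggers SPB duplication, after which the two SPBs are
linked by interpolar MTs (antiparallel overlap slid apart by kinesin-5)
and to the kinetochores by kMTs.

A growing kMT tip penetrating its kinetochore pushes with ``l_pen *
K_fibril``; a shrinking tip pulls through a connector spring with ``l_gap *
K_c``.  Sister kinetochores are held by a cohesin spring, and all
kinetochores repel on overlap with a hard-core stiffness of 1 pN/um.  kMT
length is regulated by a catastrophe frequency that grows linearly with
length, f_c = h * l_kMT, which keeps the SPB-kinetochore separation
stationary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import NuclearAssembly
from .params import SimulationParams

__all__ = [
    "FusionEvent",
    "SpindleState",
    "fuse_mtocs",
    "ipmt_force",
    "kmt_kt_forces",
    "kt_pair_forces",
    "kmt_length_catastrophe",
    "duplicate_spb",
]


@dataclass
class FusionEvent:
    time_s: float
    body_a: int
    body_b: int
    merged_id: int
    n_remaining: int


@dataclass
class SpindleState:
    """Minimal spindle bookkeeping used by the force operations."""

    spb_positions: np.ndarray                  # (2, 3)
    ipmt_overlap: float = 0.0                  # um, total antiparallel overlap
    kmt_lengths: np.ndarray | None = None      # (n_kt,)
    kmt_spb: np.ndarray | None = None          # (n_kt,) 0/1 pole assignment
    kmt_growing: np.ndarray | None = None
    kmt_attached: np.ndarray | None = None
    l_pen: np.ndarray | None = None            # (n_kt,) tip penetration into KT
    l_gap: np.ndarray | None = None            # (n_kt,) tip-KT gap

    @property
    def axis(self) -> np.ndarray:
        d = self.spb_positions[1] - self.spb_positions[0]
        return d / max(np.linalg.norm(d), 1e-12)


# ----------------------------------------------------------------------
def fuse_mtocs(
    assembly: NuclearAssembly,
    contact_tolerance: float = 1e-3,
    time_s: float = 0.0,
) -> list[FusionEvent]:
    """Merge every MTOC pair in surface contact; repeat to convergence.

    Mutates ``assembly`` in place and returns the fusion events.  Merged
    position is the volume-weighted midpoint re-projected on the NE;
    merged radius conserves volume exactly.
    """
    events: list[FusionEvent] = []
    merged_any = True
    while merged_any and assembly.n_bodies > 1:
        merged_any = False
        n = assembly.n_bodies
        pos = assembly.mtoc_positions
        rad = assembly.mtoc_radii
        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(pos[i] - pos[j]) <= rad[i] + rad[j] + contact_tolerance:
                    _merge_pair(assembly, i, j)
                    events.append(
                        FusionEvent(time_s, i, j, i, assembly.n_bodies)
                    )
                    merged_any = True
                    break
            if merged_any:
                break
    return events


def _merge_pair(assembly: NuclearAssembly, i: int, j: int) -> None:
    pos = assembly.mtoc_positions
    rad = assembly.mtoc_radii
    vi, vj = rad[i] ** 3, rad[j] ** 3
    new_pos = (vi * pos[i] + vj * pos[j]) / (vi + vj)
    rel = new_pos - assembly.nucleus_center
    new_pos = assembly.nucleus_center + rel * (assembly.r_nuc / np.linalg.norm(rel))
    new_rad = (vi + vj) ** (1.0 / 3.0)
    new_founders = assembly.mtoc_founders[i] + assembly.mtoc_founders[j]

    keep = np.ones(assembly.n_bodies, dtype=bool)
    keep[j] = False
    assembly.mtoc_positions = pos[keep]
    assembly.mtoc_radii = rad[keep]
    assembly.mtoc_founders = assembly.mtoc_founders[keep]
    assembly.mtoc_positions[i] = new_pos
    assembly.mtoc_radii[i] = new_rad
    assembly.mtoc_founders[i] = new_founders
    # re-associate kinetochores of the removed body, shift indices above j
    kt = assembly.kt_mtoc
    kt[kt == j] = i
    kt[kt > j] -= 1


# ----------------------------------------------------------------------
def ipmt_force(spindle: SpindleState, params: SimulationParams) -> np.ndarray:
    """Outward kinesin-5 sliding force on the two SPBs.

    Returns a (2, 3) array; magnitude ``l_overlap * lambda_ipmt *
    f_kinesin5`` applied equally and oppositely along the pole-to-pole
    axis.
    """
    if spindle.spb_positions is None or len(spindle.spb_positions) != 2:
        raise ValueError("ipMT forces require a duplicated spindle (two SPBs)")
    mag = spindle.ipmt_overlap * params.lambda_ipmt * params.f_kinesin5
    ax = spindle.axis
    return np.stack([-mag * ax, mag * ax])


def kmt_kt_forces(
    spindle: SpindleState,
    kt_positions: np.ndarray,
    params: SimulationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-kinetochore kMT forces and the SPB reactions.

    A growing tip penetrating the kinetochore by ``l_pen`` pushes the KT
    away from its pole with ``l_pen * K_fibril``; a shrinking tip with gap
    ``l_gap`` pulls it toward the pole with ``l_gap * K_c``.  Returns
    (forces_on_kts (n,3), forces_on_spbs (2,3)).
    """
    n = len(kt_positions)
    f_kt = np.zeros((n, 3))
    f_spb = np.zeros((2, 3))
    for i in range(n):
        s = int(spindle.kmt_spb[i])
        d = kt_positions[i] - spindle.spb_positions[s]
        dist = np.linalg.norm(d)
        if dist < 1e-12:
            continue
        u = d / dist
        pen = float(spindle.l_pen[i]) if spindle.l_pen is not None else 0.0
        gap = float(spindle.l_gap[i]) if spindle.l_gap is not None else 0.0
        f = pen * params.k_fibril * u - gap * params.k_c * u
        f_kt[i] += f
        f_spb[s] -= f
    return f_kt, f_spb


def kt_pair_forces(
    kt_positions: np.ndarray,
    params: SimulationParams,
    sister_pairs: np.ndarray | None = None,
    r_kt: float | None = None,
) -> np.ndarray:
    """Cohesin attraction between sisters plus hard-core repulsion.

    ``sister_pairs`` is an (n/2, 2) index array; by default consecutive
    kinetochores are sisters.  Repulsion ``C * d_overlap`` acts between any
    overlapping pair, cohesin ``K_cohesion * d_separation`` between
    sisters.
    """
    n = len(kt_positions)
    r = params.r_kt if r_kt is None else r_kt
    if sister_pairs is None:
        sister_pairs = np.arange(n - (n % 2)).reshape(-1, 2)
    f = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            d = kt_positions[i] - kt_positions[j]
            dist = np.linalg.norm(d)
            overlap = 2.0 * r - dist
            if overlap > 0 and dist > 1e-12:
                push = params.c_kt_repulsion * overlap * d / dist
                f[i] += push
                f[j] -= push
    for a, b in sister_pairs:
        d = kt_positions[b] - kt_positions[a]
        dist = np.linalg.norm(d)
        if dist > 1e-12:
            pull = params.k_cohesion * dist * d / dist
            f[a] += pull
            f[b] -= pull
    return f


def kmt_length_catastrophe(l_kmt: float, params: SimulationParams) -> float:
    """Length-dependent kMT catastrophe frequency h * l (1/min)."""
    if l_kmt < 0:
        raise ValueError("kMT length must be non-negative")
    return params.h_kmt * l_kmt


# ----------------------------------------------------------------------
def duplicate_spb(
    assembly: NuclearAssembly, params: SimulationParams, rng: np.random.Generator
) -> NuclearAssembly:
    """Replace the single fused SPB by two SPBs offset on the NE.

    Requires completed clustering.  The two daughters sit 2*r_spb apart
    along a random tangential direction, both re-projected onto the NE, and
    each carries half the fused volume.
    """
    if not assembly.clustering_complete:
        raise ValueError("SPB duplication requires completed MTOC clustering")
    center = assembly.nucleus_center
    fused = assembly.mtoc_positions[0]
    u = (fused - center) / assembly.r_nuc
    t = rng.normal(size=3)
    t -= (t @ u) * u
    t /= np.linalg.norm(t)
    offset = params.r_spb
    spbs = np.stack([fused + offset * t, fused - offset * t])
    for k in range(2):
        rel = spbs[k] - center
        spbs[k] = center + rel * (assembly.r_nuc / np.linalg.norm(rel))
    assembly.spb_positions = spbs
    return assembly
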