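"""Cell geometry: mother sphere, growing daughter bud, septin ring, cortex.

The cell is a "snowman" union of two spheres.  The mother is a fixed sphere
of radius ``r_mother`` centred at the origin.  The daughter bud is a second
sphere whose radius grows linearly in time until the budding index (bud
diameter over mother diameter) reaches ``final_budding_index``.  The two
spheres intersect in a circle -- the septin ring / bud neck -- whose radius
is held at a fixed fraction ``neck_fraction`` of the current bud radius; the
bud centre is placed on the (random, per-cell) bud axis so that both sphere
surfaces pass through that circle.  The septin plane is the plane of the
ring, oriented by the mother-to-daughter axis unit vector.

The cortex is the shell of width ``w_cor`` immediately inside the boundary.
Interior points are classified by the side of the septin plane they fall on
(mother vs daughter) and by their depth below the nearest boundary
(interior vs cortex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import SimulationParams

__all__ = [
    "Region",
    "PointClass",
    "CellGeometry",
    "NuclearAssembly",
    "PlacementError",
    "init_cell",
    "grow_bud",
    "classify_point",
    "neck_to_nucleus_distance",
]


class Region:
    MOTHER_INTERIOR = "mother_interior"
    DAUGHTER_INTERIOR = "daughter_interior"
    MOTHER_CORTEX = "mother_cortex"
    DAUGHTER_CORTEX = "daughter_cortex"
    OUTSIDE = "outside"


class PlacementError(RuntimeError):
    """Rejection sampling failed to place a body (pathological parameters)."""


@dataclass
class PointClass:
    region: str
    boundary_distance: float          # depth below the boundary; <0 outside
    inward_normal: np.ndarray         # unit vector pointing into the cell


@dataclass
class CellGeometry:
    r_mother: float
    bud_axis: np.ndarray              # unit vector, mother -> daughter
    final_budding_index: float
    bud_growth_duration_s: float
    neck_fraction: float
    w_cor: float
    time_s: float = 0.0               # time of the current snapshot

    # -- bud growth law ------------------------------------------------
    def budding_index(self, t_s: float | None = None) -> float:
        t = self.time_s if t_s is None else t_s
        frac = min(max(t, 0.0) / self.bud_growth_duration_s, 1.0)
        return self.final_budding_index * frac

    def bud_radius(self, t_s: float | None = None) -> float:
        return self.r_mother * self.budding_index(t_s)

    def neck_radius(self, t_s: float | None = None) -> float:
        return self.neck_fraction * self.bud_radius(t_s)

    def septin_plane_distance(self, t_s: float | None = None) -> float:
        """Distance of the septin plane from the mother centre, along the axis."""
        a = self.neck_radius(t_s)
        return math.sqrt(self.r_mother**2 - a**2)

    def bud_center(self, t_s: float | None = None) -> np.ndarray:
        rb = self.bud_radius(t_s)
        a = self.neck_fraction * rb
        if rb <= 0.0:
            return self.bud_axis * self.r_mother
        d = math.sqrt(self.r_mother**2 - a**2) + math.sqrt(rb**2 - a**2)
        return self.bud_axis * d

    # -- queries -------------------------------------------------------
    def classify_point(self, p: np.ndarray, t_s: float | None = None) -> PointClass:
        return classify_point(self, np.asarray(p, dtype=float), t_s)

    def contains(self, p: np.ndarray, t_s: float | None = None) -> bool:
        return self.classify_point(p, t_s).region != Region.OUTSIDE


@dataclass
class NuclearAssembly:
    nucleus_center: np.ndarray        # (3,)
    r_nuc: float
    mtoc_positions: np.ndarray        # (n_bodies, 3), centres on the NE sphere
    mtoc_radii: np.ndarray            # (n_bodies,)
    mtoc_founders: np.ndarray         # (n_bodies,) int, founding MTOCs merged in
    kt_positions: np.ndarray          # (n_kt, 3)
    kt_mtoc: np.ndarray               # (n_kt,) int, associated MTOC body
    r_kt: float
    spb_positions: np.ndarray | None = None   # (2, 3) after SPB duplication

    @property
    def n_bodies(self) -> int:
        return len(self.mtoc_radii)

    @property
    def clustering_complete(self) -> bool:
        return self.n_bodies == 1

    @property
    def duplicated(self) -> bool:
        return self.spb_positions is not None

    def ne_residuals(self) -> np.ndarray:
        """| |c - n| - r_nuc | for every MTOC body (NE-constraint residual)."""
        d = np.linalg.norm(self.mtoc_positions - self.nucleus_center, axis=1)
        return np.abs(d - self.r_nuc)


# ----------------------------------------------------------------------
def grow_bud(geometry: CellGeometry, t_s: float) -> CellGeometry:
    """Return the geometry advanced to time ``t_s`` (bud and septin plane)."""
    if t_s < 0:
        raise ValueError("time must be non-negative")
    out = CellGeometry(
        r_mother=geometry.r_mother,
        bud_axis=geometry.bud_axis,
        final_budding_index=geometry.final_budding_index,
        bud_growth_duration_s=geometry.bud_growth_duration_s,
        neck_fraction=geometry.neck_fraction,
        w_cor=geometry.w_cor,
        time_s=t_s,
    )
    return out


def classify_point(
    geometry: CellGeometry, p: np.ndarray, t_s: float | None = None
) -> PointClass:
    """Region label, boundary depth and inward normal for a point.

    Depth is measured below the boundary of whichever sphere contains the
    point more deeply; points outside both spheres get a negative depth (the
    out-of-domain result used for MT boundary handling).
    """
    R = geometry.r_mother
    rb = geometry.bud_radius(t_s)
    cb = geometry.bud_center(t_s)
    x_pl = geometry.septin_plane_distance(t_s)
    axis = geometry.bud_axis

    rm = float(np.linalg.norm(p))
    depth_m = R - rm
    if rb > 1e-12:
        db = float(np.linalg.norm(p - cb))
        depth_b = rb - db
    else:
        db = math.inf
        depth_b = -math.inf

    if depth_b > depth_m:
        depth = depth_b
        normal = (cb - p) / db if db > 1e-12 else -axis
    else:
        depth = depth_m
        normal = -p / rm if rm > 1e-12 else np.array([0.0, 0.0, 1.0])

    if depth < 0:
        return PointClass(Region.OUTSIDE, depth, normal)

    daughter = float(p @ axis) > x_pl
    if depth < geometry.w_cor:
        region = Region.DAUGHTER_CORTEX if daughter else Region.MOTHER_CORTEX
    else:
        region = Region.DAUGHTER_INTERIOR if daughter else Region.MOTHER_INTERIOR
    return PointClass(region, depth, normal)


def neck_to_nucleus_distance(
    geometry: CellGeometry,
    assembly: NuclearAssembly | np.ndarray,
    t_s: float | None = None,
) -> float:
    """Signed distance from the septin plane to the nucleus centre.

    Negative while the nucleus is inside the mother, positive once it has
    passed the neck into the daughter.
    """
    center = (
        assembly.nucleus_center
        if isinstance(assembly, NuclearAssembly)
        else np.asarray(assembly, dtype=float)
    )
    return float(center @ geometry.bud_axis) - geometry.septin_plane_distance(t_s)


# ----------------------------------------------------------------------
def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def init_cell(
    params: SimulationParams, rng_seed: int
) -> tuple[CellGeometry, NuclearAssembly]:
    """Seeded random initial configuration.

    The bud site is uniform on the mother surface, the nucleus centre
    uniform over positions of full containment, and the founding MTOCs
    uniform on the nuclear envelope subject to pairwise non-overlap.  One
    kinetochore sits just beneath each founding MTOC.
    """
    rng = np.random.default_rng(rng_seed)
    geometry = CellGeometry(
        r_mother=params.r_mother,
        bud_axis=_random_unit(rng),
        final_budding_index=params.final_budding_index,
        bud_growth_duration_s=params.bud_growth_duration * 60.0,
        neck_fraction=params.neck_fraction,
        w_cor=params.w_cor,
        time_s=0.0,
    )

    # nucleus: uniform in the ball of radius r_mother - r_nuc
    r_max = params.r_mother - params.r_nuc
    u = rng.random()
    nucleus = _random_unit(rng) * r_max * u ** (1.0 / 3.0)

    # MTOCs on the NE, rejection sampling against pairwise overlap
    n = params.n_kt
    positions = np.empty((n, 3))
    placed = 0
    attempts = 0
    min_sep = 2.0 * params.r_spb
    while placed < n:
        attempts += 1
        if attempts > 20000:
            raise PlacementError(
                f"could not place {n} non-overlapping MTOCs on the NE "
                f"(r_spb={params.r_spb}, r_nuc={params.r_nuc})"
            )
        cand = nucleus + params.r_nuc * _random_unit(rng)
        ok = True
        for j in range(placed):
            if np.linalg.norm(cand - positions[j]) < min_sep:
                ok = False
                break
        if ok:
            positions[placed] = cand
            placed += 1

    kt_positions = nucleus + (positions - nucleus) * (
        (params.r_nuc - 2.0 * params.r_kt) / params.r_nuc
    )

    assembly = NuclearAssembly(
        nucleus_center=nucleus,
        r_nuc=params.r_nuc,
        mtoc_positions=positions,
        mtoc_radii=np.full(n, params.r_spb),
        mtoc_founders=np.ones(n, dtype=np.int64),
        kt_positions=kt_positions,
        kt_mtoc=np.arange(n, dtype=np.int64),
        r_kt=params.r_kt,
    )
    return geometry, assembly
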