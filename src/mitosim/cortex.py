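"""Spatial program of cortical force generators.

Dynein is anchored in the cortex and pulls on cytoplasmic microtubule (cMT)
segments that penetrate the cortical shell.  In the refined ("punctate")
template the daughter cortex carries a condensed dynein patch -- a spherical
cap centred on the bud apex, i.e. opposite the neck -- whose density is
``lambda_dynein_patch`` times the base mother density, with a background of
``lambda_dynein_rest`` times the base density elsewhere in the daughter.
With both multipliers equal to one the field reduces to the uniform model.

Bim1, the EB1-family plus-end tracker, lives only on the mother cortex and
biases cortex-engaged plus ends toward the septin ring with a dynein-like
force law, f = B * l_cor * lambda_bim1 * f_dyn, directed tangentially along
the cortex toward the nearest point of the ring.  The dimensionless bias
scale B is 1 in the wild type and, when the length-dependent bias is
enabled (Ipl1 depletion), decays exponentially as the population-average
cMT length falls below the wild-type reference length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import CellGeometry, Region, classify_point
from .params import Scenario, SimulationParams, UnknownScenarioError

__all__ = [
    "CorticalField",
    "local_dynein_density",
    "bim1_bias_force",
    "effective_bias",
    "apply_scenario_perturbation",
    "ring_direction",
]


@dataclass(frozen=True)
class CorticalField:
    lambda_dyn: float                 # 1/um, base dynein density
    lambda_bim1: float                # 1/um, Bim1 density (mother cortex only)
    f_dyn: float                      # pN per dynein
    mother_multiplier: float = 1.0    # scales the mother-cortex density
    patch_multiplier: float = 1.0     # x base density in the daughter patch
    rest_multiplier: float = 1.0      # x base density elsewhere in daughter
    patch_area_fraction: float = 0.10
    bias_scale: float = 1.0           # B in [0, 1]
    bias_scales_dynein: bool = False

    @property
    def patch_cos_cap(self) -> float:
        """Polar-angle cosine bounding the apex cap of the given area fraction."""
        return 1.0 - 2.0 * self.patch_area_fraction

    @classmethod
    def from_params(cls, params: SimulationParams) -> "CorticalField":
        return cls(
            lambda_dyn=params.lambda_dyn,
            lambda_bim1=params.lambda_bim1,
            f_dyn=params.f_dyn,
            mother_multiplier=params.mother_dynein_multiplier,
            patch_multiplier=params.lambda_dynein_patch,
            rest_multiplier=params.lambda_dynein_rest,
            patch_area_fraction=params.patch_area_fraction,
            bias_scales_dynein=params.bias_scales_dynein,
        )


def in_daughter_patch(
    field: CorticalField, geometry: CellGeometry, p: np.ndarray, t_s: float | None = None
) -> bool:
    """Is a daughter-cortex point inside the condensed apex patch?"""
    cb = geometry.bud_center(t_s)
    rb = geometry.bud_radius(t_s)
    if rb <= 0:
        return False
    u = (np.asarray(p, float) - cb) / max(np.linalg.norm(p - cb), 1e-12)
    return float(u @ geometry.bud_axis) > field.patch_cos_cap


def local_dynein_density(
    field: CorticalField,
    geometry: CellGeometry,
    p: np.ndarray,
    t_s: float | None = None,
) -> float:
    """Dynein density (1/um) at a cortical surface point.

    Raises ``ValueError`` for points that are not in the cortex.
    """
    pc = classify_point(geometry, np.asarray(p, float), t_s)
    if pc.region == Region.MOTHER_CORTEX:
        return field.lambda_dyn * field.mother_multiplier
    if pc.region == Region.DAUGHTER_CORTEX:
        mult = (
            field.patch_multiplier
            if in_daughter_patch(field, geometry, p, t_s)
            else field.rest_multiplier
        )
        return field.lambda_dyn * mult
    raise ValueError(f"point {p} is not in the cortex (region={pc.region})")


def ring_direction(
    geometry: CellGeometry,
    tip: np.ndarray,
    inward_normal: np.ndarray,
    t_s: float | None = None,
) -> np.ndarray:
    """Unit vector tangent to the cortex at ``tip`` toward the septin ring.

    The target is the nearest point of the ring circle; the connecting
    vector is projected onto the local tangent plane.  Returns a zero
    vector in the degenerate case of a tip on the ring axis.
    """
    a = geometry.neck_radius(t_s)
    x_pl = geometry.septin_plane_distance(t_s)
    axis = geometry.bud_axis
    tip = np.asarray(tip, float)
    radial = tip - (tip @ axis) * axis
    rn = np.linalg.norm(radial)
    if rn < 1e-9:
        ring_pt = x_pl * axis + a * _any_perpendicular(axis)
    else:
        ring_pt = x_pl * axis + a * radial / rn
    w = ring_pt - tip
    n = np.asarray(inward_normal, float)
    w_t = w - (w @ n) * n
    norm = np.linalg.norm(w_t)
    if norm < 1e-9:
        return np.zeros(3)
    return w_t / norm


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w = np.cross(v, helper)
    return w / np.linalg.norm(w)


def bim1_bias_force(
    mt,
    field: CorticalField,
    geometry: CellGeometry,
    params: SimulationParams,
    t_s: float | None = None,
) -> np.ndarray:
    """Bim1 force (pN, 3-vector) on a cMT plus end in the mother cortex.

    Magnitude B * l_cor * lambda_bim1 * f_dyn, directed tangentially along
    the cortex toward the nearest point of the septin ring; zero for tips
    outside the cortex or in the daughter cortex, and zero when Bim1 is
    absent (bim1-delta).
    """
    tip = np.asarray(mt.tip_position, float)
    pc = classify_point(geometry, tip, t_s)
    if pc.region != Region.MOTHER_CORTEX or mt.l_cor <= 0 or field.lambda_bim1 <= 0:
        return np.zeros(3)
    mag = field.bias_scale * mt.l_cor * field.lambda_bim1 * field.f_dyn
    return mag * ring_direction(geometry, tip, pc.inward_normal, t_s)


def effective_bias(mean_cmt_length: float, params: SimulationParams) -> float:
    """Length-dependent bias scale B in [0, 1].

    B equals one at the wild-type reference mean cMT length and decays
    exponentially (e-folding ``bias_length_const``) as the average length
    shrinks -- the mechanism by which destabilised cMTs lose the
    Bim1/dynein-mediated cortical bias.
    """
    if mean_cmt_length <= 0:
        raise ValueError("mean cMT length must be positive")
    return min(
        1.0,
        math.exp((mean_cmt_length - params.l_wt_ref) / params.bias_length_const),
    )


def apply_scenario_perturbation(field: CorticalField, scenario: Scenario) -> CorticalField:
    """Return the cortical field under a named scenario perturbation."""
    name = scenario.name
    if name == "wild_type_cib":
        return field
    if name == "bim1_delta":
        return replace(field, lambda_bim1=0.0)
    if name == "dyn1_oe":
        factor = scenario.overrides.get("mother_dynein_multiplier", 3.0)
        return replace(field, mother_multiplier=factor)
    if name in ("ipl1_homogeneous", "ipl1_heterogeneous"):
        return field  # bias scale is driven by the running mean cMT length
    if name == "dynein_puncta_scan":
        return replace(
            field,
            patch_multiplier=scenario.overrides.get("lambda_dynein_patch", field.patch_multiplier),
            rest_multiplier=scenario.overrides.get("lambda_dynein_rest", field.rest_multiplier),
        )
    raise UnknownScenarioError(name)
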