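"""Cytoplasmic microtubule dynamic instability and cortex interaction.

A cMT is a straight, zero-thickness rod anchored (minus end) at an MTOC or
SPB on the nuclear envelope, free to pivot about that anchor.  Its plus end
switches stochastically between growth (speed ``v_g``) and shrinkage
(``v_s``); catastrophes occur at frequency ``f_c`` and rescues at ``f_r``.
A fully depolymerised cMT is immediately renucleated from its anchor with a
fresh random orientation in the outward hemisphere.

Compression of a tip in the cortical shell loads the rod.  Load slows
growth and promotes catastrophe according to the standard force-velocity
relations

    v_g(f)  = v_g0 * exp(-f / f_stall)
    f_c(f)  = f_c_stall / (1 + (f_c_stall / f_c0 - 1) * exp(-f / f_stall))

so that under stall v_g -> 0 and f_c -> f_c_stall.  A tip in the shell
feels an elastic push ``l_cor * K_cor`` inward and a collective dynein pull
``l_cor * lambda * f_dyn`` outward, where ``l_cor`` is the rod length
inside the shell.  A tip reaching the hard boundary at shallow incidence
slides tangentially along the cortex (its growth redirected along the
surface, and -- in the mother -- biased toward the septin ring by Bim1);
at steep incidence the rod stalls and either buckles (first-order Euler
force pi^2 * kappa / l^2) or undergoes catastrophe, receiving an inward
impulse of roughly 1 pN when it switches to shrinkage at the wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np
from numba import njit

from .geometry import CellGeometry, Region, classify_point
from .params import SimulationParams

__all__ = [
    "Microtubule",
    "CmtForceReport",
    "load_modulation",
    "modulate_by_load",
    "step_instability",
    "cortex_forces",
    "sliding_update",
    "stationary_mean_length",
    "mean_elongation_rate",
    "sample_free_lengths",
    "buckling_force",
]


@dataclass
class Microtubule:
    anchor_id: int
    anchor_position: np.ndarray       # (3,), on the NE
    direction: np.ndarray             # unit vector, minus -> plus end
    length: float                     # um
    growing: bool = True
    l_cor: float = 0.0                # um of rod inside the cortex shell
    region: str | None = None         # cortex region of the plus end
    buckling: bool = False
    sliding: bool = False
    f_load: float = 0.0               # pN, axial load opposing growth

    @property
    def tip_position(self) -> np.ndarray:
        return self.anchor_position + self.length * self.direction


@dataclass
class CmtForceReport:
    """Per-cMT cortical force contributions (pN, 3-vectors at the anchor)."""

    f_push: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    f_pull: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    f_wall: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    f_buckling: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    f_bim1: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    f_load: float = 0.0

    @property
    def resultant(self) -> np.ndarray:
        """Axial resultant transmitted to the anchor body and the nucleus.

        The Bim1 bias acts at the plus end, tangent to the cortex; a rod
        pivoting freely about its anchor transmits only axial components,
        so ``f_bim1`` reorients the rod rather than translating the anchor
        and is excluded here.
        """
        return self.f_push + self.f_pull + self.f_wall + self.f_buckling


# ----------------------------------------------------------------------
@njit(cache=True)
def load_modulation(
    v_g0: float, f_c0: float, f_c_stall: float, f_stall: float, f_load: float
) -> tuple[float, float]:
    """(v_g_eff, f_c_eff) under an axial load of magnitude ``f_load``."""
    e = math.exp(-f_load / f_stall)
    v_g_eff = v_g0 * e
    f_c_eff = f_c_stall / (1.0 + (f_c_stall / f_c0 - 1.0) * e)
    return v_g_eff, f_c_eff


def modulate_by_load(params: SimulationParams, f_load: float) -> tuple[float, float]:
    """Load-modulated growth velocity (um/min) and catastrophe rate (1/min).

    ``f_load`` is the magnitude (pN) of the axial load opposing growth.
    """
    if f_load < 0:
        raise ValueError("f_load is a magnitude and must be >= 0")
    f_c_stall_per_min = params.f_c_stall * 60.0
    v, c = load_modulation(
        params.v_g, params.f_c, f_c_stall_per_min, params.f_stall, f_load
    )
    return v, c


def buckling_force(params: SimulationParams, length: float) -> float:
    """First-order Euler buckling force (pN) of a rod of given length (um)."""
    return math.pi**2 * params.kappa_mt / max(length, 0.05) ** 2


# ----------------------------------------------------------------------
def step_instability(
    mt: Microtubule,
    params: SimulationParams,
    rng: np.random.Generator,
    dt_s: float,
) -> Microtubule:
    """Advance a free cMT by one step of the two-state instability process.

    Growth speed and catastrophe rate are modulated by the MT's current
    load; shrinkage and rescue are load-independent.  A rod hitting zero
    length is renucleated with a fresh random outward orientation.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    v_g_eff, f_c_eff = modulate_by_load(params, mt.f_load)
    dt_min = dt_s / 60.0
    if mt.growing:
        mt.length += v_g_eff * dt_min
        if rng.random() < -math.expm1(-f_c_eff * dt_min):
            mt.growing = False
    else:
        mt.length -= params.v_s * dt_min
        if mt.length <= 0.0:
            mt.length = 1e-3
            mt.growing = True
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            outward = mt.direction  # caller supplies NE normal via direction
            if v @ outward < 0:
                v -= 2.0 * (v @ outward) * outward
            mt.direction = v
        elif rng.random() < -math.expm1(-params.f_r * dt_min):
            mt.growing = True
    return mt


def stationary_mean_length(params: SimulationParams) -> float:
    """Mean of the stationary length distribution of an unbounded cMT.

    In the bounded-growth regime (v_s*f_c > v_g*f_r) the stationary
    distribution is exponential with mean v_g*v_s / (v_s*f_c - v_g*f_r).
    """
    denom = params.v_s * params.f_c - params.v_g * params.f_r
    if denom <= 0:
        raise ValueError(
            "unbounded growth regime: v_s*f_c <= v_g*f_r has no stationary length"
        )
    return params.v_g * params.v_s / denom


def mean_elongation_rate(params: SimulationParams) -> float:
    """Average plus-end drift (um/min); positive means unbounded growth."""
    return (params.v_g * params.f_r - params.v_s * params.f_c) / (
        params.f_c + params.f_r
    )


def sample_free_lengths(
    params: SimulationParams,
    n_samples: int,
    seed: int,
    n_mts: int = 500,
    dt_s: float = 0.5,
    sample_every_min: float = 2.0,
    burn_in_min: float = 60.0,
) -> np.ndarray:
    """Vectorised free-space instability run returning length samples.

    Used as the stochastic oracle for the stationary length distribution:
    ``n_mts`` independent MTs are evolved (renucleating at zero length) and
    lengths are recorded every ``sample_every_min`` after a burn-in.
    """
    rng = np.random.default_rng(seed)
    dt_min = dt_s / 60.0
    p_cat = -math.expm1(-params.f_c * dt_min)
    p_res = -math.expm1(-params.f_r * dt_min)
    length = np.zeros(n_mts)
    growing = np.ones(n_mts, dtype=bool)
    out = np.empty(n_samples)
    got = 0
    steps_per_sample = max(1, int(round(sample_every_min / dt_min)))
    burn_steps = int(round(burn_in_min / dt_min))
    step = 0
    while got < n_samples:
        step += 1
        dl = np.where(growing, params.v_g, -params.v_s) * dt_min
        length += dl
        renuc = length <= 0.0
        length[renuc] = 0.0
        growing[renuc] = True
        u = rng.random(n_mts)
        cat = growing & ~renuc & (u < p_cat)
        res = ~growing & (u < p_res)
        growing[cat] = False
        growing[res] = True
        if step > burn_steps and step % steps_per_sample == 0:
            take = min(n_mts, n_samples - got)
            out[got : got + take] = length[:take]
            got += take
    return out


# ----------------------------------------------------------------------
def cortex_forces(
    mt: Microtubule,
    geometry: CellGeometry,
    cortical_program,
    params: SimulationParams,
    t_s: float | None = None,
) -> CmtForceReport:
    """Cortical force report for a single cMT.

    Sign convention: the push points inward (against the rod axis), the
    dynein pull outward (toward the plus end).  All contributions vanish
    for a tip outside the cortex shell.
    """
    from .cortex import bim1_bias_force, in_daughter_patch  # cycle-free at call time

    report = CmtForceReport()
    tip = mt.tip_position
    pc = classify_point(geometry, tip, t_s)
    mt.region = pc.region
    if pc.region not in (Region.MOTHER_CORTEX, Region.DAUGHTER_CORTEX):
        mt.l_cor = 0.0
        mt.f_load = 0.0
        return report

    u = mt.direction
    if pc.region == Region.MOTHER_CORTEX:
        lam = cortical_program.lambda_dyn * cortical_program.mother_multiplier
        if cortical_program.bias_scales_dynein:
            lam *= cortical_program.bias_scale
    else:
        mult = (
            cortical_program.patch_multiplier
            if in_daughter_patch(cortical_program, geometry, tip, t_s)
            else cortical_program.rest_multiplier
        )
        lam = cortical_program.lambda_dyn * mult

    report.f_push = -mt.l_cor * params.k_cor * u
    report.f_pull = mt.l_cor * lam * cortical_program.f_dyn * u
    f_load = mt.l_cor * params.k_cor
    if mt.buckling:
        fb = buckling_force(params, mt.length)
        report.f_buckling = -fb * u
        f_load += fb
    if not mt.growing and pc.boundary_distance < 1e-9:
        report.f_wall = -params.f_wall * u
    report.f_bim1 = bim1_bias_force(mt, cortical_program, geometry, params, t_s)
    report.f_load = f_load
    mt.f_load = f_load
    return report


def sliding_update(
    mt: Microtubule,
    geometry: CellGeometry,
    angle_threshold_deg: float,
    t_s: float | None = None,
) -> Microtubule:
    """Decide the boundary branch for a plus end at the cell boundary.

    If the incidence angle measured from the local tangent plane is below
    the threshold the tip advances tangentially (sliding); otherwise the
    rod is marked as buckling (the catastrophe-with-impulse branch is
    resolved stochastically by the caller).
    """
    pc = classify_point(geometry, mt.tip_position, t_s)
    n_in = pc.inward_normal
    cos_from_normal = abs(float(mt.direction @ -n_in))
    angle_from_surface = math.degrees(math.asin(min(1.0, cos_from_normal)))
    if angle_from_surface < angle_threshold_deg:
        mt.sliding = True
        mt.buckling = False
        tang = mt.direction - (mt.direction @ -n_in) * (-n_in)
        norm = np.linalg.norm(tang)
        if norm > 1e-9:
            tip = mt.tip_position + 0.0 * tang  # direction only; advance is v_g*dt
            mt.direction = (tip + tang / norm * 1e-6 - mt.anchor_position)
            mt.direction /= np.linalg.norm(mt.direction)
    else:
        mt.sliding = False
        mt.buckling = True
    return mt
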