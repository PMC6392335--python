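"""Overdamped (Stokes-drag) equations of motion and the Euler update.

Every body moves with velocity F/xi, where the drag coefficient follows
Stokes' law xi = 6*pi*eta*r with the medium assigned per body: cytoplasm
for the translating nucleus, the effective nuclear-envelope viscosity for
MTOCs and SPBs (which move within the membrane), and nucleoplasm for
kinetochores.  Inertia and thermal noise are absent; all randomness enters
through microtubule dynamic instability and the initial configuration.

Constraints are enforced by re-projection after the unconstrained Euler
step: MTOC/SPB centres back onto the NE sphere, kinetochores into the
nucleus.  Tangential motion is preserved to first order in the step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import SimulationParams

__all__ = [
    "DragTable",
    "compute_drags",
    "euler_step",
    "assemble_forces",
    "IntegratorInstabilityError",
]


class IntegratorInstabilityError(RuntimeError):
    """Per-step displacement exceeded the stability bound; reduce dt."""


@dataclass(frozen=True)
class DragTable:
    """Drag coefficients (pN s/um) for each body class."""

    nucleus: float
    mtoc: float
    spb: float
    kt: float


def stokes_drag(eta: float, radius: float) -> float:
    return 6.0 * math.pi * eta * radius


def compute_drags(params: SimulationParams, mtoc_radius: float | None = None) -> DragTable:
    """Stokes drags with the per-body medium assignment.

    The nucleus translates through cytoplasm; MTOCs and SPBs move within
    the nuclear envelope (effective viscosity ``eta_ne``); kinetochores are
    immersed in nucleoplasm.  ``mtoc_radius`` defaults to the single-SPB
    radius but grows as bodies fuse.
    """
    r_mtoc = params.r_spb if mtoc_radius is None else mtoc_radius
    return DragTable(
        nucleus=stokes_drag(params.eta_cyt, params.r_nuc),
        mtoc=stokes_drag(params.eta_ne, r_mtoc),
        spb=stokes_drag(params.eta_ne, params.r_spb),
        kt=stokes_drag(params.eta_nu, params.r_kt),
    )


def euler_step(
    positions: np.ndarray,
    forces: np.ndarray,
    drags: np.ndarray,
    dt_s: float,
    max_displacement: float | None = None,
) -> np.ndarray:
    """X <- X + (F/xi) * dt for a stack of bodies.

    ``positions``/``forces`` are (n, 3); ``drags`` is (n,).  When
    ``max_displacement`` is given, any per-step displacement beyond it
    raises :class:`IntegratorInstabilityError` (the caller should reduce
    dt).
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    disp = forces / np.asarray(drags)[:, None] * dt_s
    if max_displacement is not None:
        worst = float(np.max(np.linalg.norm(disp, axis=1), initial=0.0))
        if worst > max_displacement:
            raise IntegratorInstabilityError(
                f"step displacement {worst:.3g} um exceeds bound "
                f"{max_displacement:.3g} um; reduce dt"
            )
    return positions + disp


def assemble_forces(
    n_bodies: dict,
    cmt_reports: list | None = None,
    spindle_forces: dict | None = None,
) -> dict:
    """Compose per-subsystem force reports into per-body resultants.

    ``n_bodies``: {"n_mtoc": int, "n_kt": int, "n_spb": int}.  Each cMT
    cortical report contributes its axial resultant to both the nucleus
    and its anchor body.  ``spindle_forces`` may carry "ipmt" (2, 3),
    "kmt_kt" (n_kt, 3) with "kmt_spb" (2, 3) reactions, and "kt_pair"
    (n_kt, 3) -- all internal, summing to zero over nuclear bodies.

    Returns {"nucleus": (3,), "mtoc": (n_mtoc, 3), "spb": (n_spb, 3),
    "kt": (n_kt, 3), "internal_sum": (3,)}.
    """
    f_nuc = np.zeros(3)
    f_mtoc = np.zeros((n_bodies.get("n_mtoc", 0), 3))
    f_spb = np.zeros((n_bodies.get("n_spb", 0), 3))
    f_kt = np.zeros((n_bodies.get("n_kt", 0), 3))
    internal = np.zeros(3)

    for anchor_kind, anchor_idx, report in cmt_reports or []:
        f = report.resultant
        f_nuc += f
        if anchor_kind == "mtoc":
            f_mtoc[anchor_idx] += f
        else:
            f_spb[anchor_idx] += f

    if spindle_forces:
        if "ipmt" in spindle_forces:
            f_spb += spindle_forces["ipmt"]
            internal += spindle_forces["ipmt"].sum(axis=0)
        if "kmt_kt" in spindle_forces:
            f_kt += spindle_forces["kmt_kt"]
            f_spb += spindle_forces["kmt_spb"]
            internal += spindle_forces["kmt_kt"].sum(axis=0)
            internal += spindle_forces["kmt_spb"].sum(axis=0)
        if "kt_pair" in spindle_forces:
            f_kt += spindle_forces["kt_pair"]
            internal += spindle_forces["kt_pair"].sum(axis=0)

    return {
        "nucleus": f_nuc,
        "mtoc": f_mtoc,
        "spb": f_spb,
        "kt": f_kt,
        "internal_sum": internal,
    }
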