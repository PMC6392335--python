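"""Orchestration: single cells, populations and dynein-density scans.

The simulation loop follows the phase schedule of mitosis in this system:
bud emergence at t = 0, cortical interaction with bias (dynein pull plus
Bim1 bias) active from emergence onward, MTOC clustering on the nuclear
envelope, SPB duplication triggered by clustering completion, spindle
assembly (ipMT/kMT forces active only after duplication), and nuclear
migration through the neck, with the run ending at completion or at the
60-minute cutoff.
"""

from __future__ import annotations

import hashlib
import math

import numpy as np

from . import _engine, geometry, observables
from ._engine import simulate_cell
from .integrator import IntegratorInstabilityError
from .params import Scenario, SimulationParams, make_scenario

__all__ = ["run_cell", "run_population", "run_scan", "params_to_vector", "config_hash"]

_MAX_SEED = 2**31 - 1

# Fibonacci-sphere directions used for the soft nucleus-containment penalty
_N_CONTAIN = 64


def _containment_directions(n: int = _N_CONTAIN) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_CONTAIN_DIRS = _containment_directions()


def params_to_vector(params: SimulationParams, f_c_cell: float | None = None) -> np.ndarray:
    """Flatten a parameter set into the (um, pN, s) vector the kernel uses."""
    p = np.zeros(_engine.NPARAMS)
    p[_engine.P_R] = params.r_mother
    p[_engine.P_RNUC] = params.r_nuc
    p[_engine.P_RSPB] = params.r_spb
    p[_engine.P_RKT] = params.r_kt
    p[_engine.P_KCOR] = params.k_cor
    p[_engine.P_ETACYT] = params.eta_cyt
    p[_engine.P_ETANU] = params.eta_nu
    p[_engine.P_ETANE] = params.eta_ne
    p[_engine.P_VG] = params.v_g / 60.0
    p[_engine.P_VS] = params.v_s / 60.0
    p[_engine.P_FC] = (params.f_c if f_c_cell is None else f_c_cell) / 60.0
    p[_engine.P_FR] = params.f_r / 60.0
    p[_engine.P_FCSTALL] = params.f_c_stall
    p[_engine.P_FSTALL] = params.f_stall
    p[_engine.P_FDYN] = params.f_dyn
    p[_engine.P_LAMDYN] = params.lambda_dyn
    p[_engine.P_LAMIP] = params.lambda_ipmt
    p[_engine.P_FK5] = params.f_kinesin5
    p[_engine.P_KCOH] = params.k_cohesion
    p[_engine.P_KC] = params.k_c
    p[_engine.P_KFIB] = params.k_fibril
    p[_engine.P_CREP] = params.c_kt_repulsion
    p[_engine.P_FWALL] = params.f_wall
    p[_engine.P_WCOR] = params.w_cor
    p[_engine.P_DT] = params.dt
    p[_engine.P_HKMT] = params.h_kmt / 60.0
    p[_engine.P_LAMBIM] = params.lambda_bim1
    p[_engine.P_FBI] = params.final_budding_index
    p[_engine.P_TGROW] = params.bud_growth_duration * 60.0
    p[_engine.P_BLC] = params.bias_length_const
    p[_engine.P_LREF] = params.l_wt_ref
    p[_engine.P_PATCH] = params.lambda_dynein_patch
    p[_engine.P_REST] = params.lambda_dynein_rest
    p[_engine.P_PATCHCOS] = 1.0 - 2.0 * params.patch_area_fraction
    p[_engine.P_NECKFRAC] = params.neck_fraction
    p[_engine.P_SINSLIDE] = math.sin(math.radians(params.sliding_angle_deg))
    p[_engine.P_KAPPA] = params.kappa_mt
    p[_engine.P_MOTHERMULT] = params.mother_dynein_multiplier
    p[_engine.P_BCELL] = 1.0
    p[_engine.P_CUTOFF] = params.migration_cutoff * 60.0
    p[_engine.P_MIGTH] = params.migration_threshold * params.r_nuc
    p[_engine.P_SAMPINT] = params.sample_interval
    p[_engine.P_NCMT] = params.n_cmt_per_mtoc
    p[_engine.P_BSCALED] = 1.0 if params.bias_scales_dynein else 0.0
    p[_engine.P_RENUC] = 0.05
    p[_engine.P_NKT] = params.n_kt
    p[_engine.P_NCMTSPB] = params.n_cmt_per_spb
    p[_engine.P_TENG] = params.dynein_engagement_time
    p[_engine.P_ASEP] = params.septin_ring_radius
    p[_engine.P_KSEP] = params.k_septum
    return p


def config_hash(params: SimulationParams, scenario: Scenario) -> str:
    text = repr(sorted(params.asdict().items())) + repr(
        (scenario.name, sorted(scenario.overrides.items()))
    )
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_cell(
    params: SimulationParams,
    scenario: Scenario,
    seed: int,
    keep_series: bool = False,
) -> observables.RunRecord:
    """Simulate one cell under a scenario; deterministic given the seed."""
    cell_params = scenario.resolve(params)
    rng = np.random.default_rng(seed)
    if scenario.heterogeneous_f_c:
        f_c_cell = float(
            rng.uniform(cell_params.f_c_min, cell_params.f_c_max)
        )
    else:
        f_c_cell = cell_params.f_c
    geom, assembly = geometry.init_cell(cell_params, seed)

    p = params_to_vector(cell_params, f_c_cell)
    if cell_params.length_dependent_bias:
        # the cell's expected (unconfined) mean cMT length sets its bias
        from .cortex import effective_bias
        from .microtubule import stationary_mean_length

        try:
            l_est = stationary_mean_length(cell_params.replace(f_c=f_c_cell))
        except ValueError:  # unbounded growth regime: bias saturates
            l_est = cell_params.l_wt_ref
        p[_engine.P_BCELL] = effective_bias(l_est, cell_params)
    kernel_seed = int(rng.integers(0, _MAX_SEED))
    out = simulate_cell(
        p,
        geom.bud_axis.astype(np.float64),
        assembly.nucleus_center.astype(np.float64),
        assembly.mtoc_positions.astype(np.float64),
        _CONTAIN_DIRS,
        kernel_seed,
    )
    (
        status,
        clustering_t,
        migration_t,
        mean_len,
        fusion_t,
        fusion_nrem,
        n_fus,
        samp_t,
        samp_neck,
        samp_nbod,
        samp_mlen,
        samp_spb,
        samp_ndau,
        samp_fax,
        n_samp,
        max_ne_res,
        final_nuc,
    ) = out
    if status == _engine.UNSTABLE:
        raise IntegratorInstabilityError(
            f"seed {seed}: per-step displacement exceeded 0.1*r_spb; "
            f"reduce dt (currently {cell_params.dt} s)"
        )

    cutoff_min = cell_params.migration_cutoff
    run_end_min = (samp_t[n_samp - 1] / 60.0) if n_samp else cutoff_min
    cl_min, cl_cens = observables.detect_clustering_time(
        fusion_t[:n_fus] / 60.0,
        fusion_nrem[:n_fus],
        cell_params.n_kt,
        run_end_min,
    )
    mg_min, mg_cens = observables.detect_migration_time(
        samp_t[:n_samp] / 60.0,
        samp_neck[:n_samp],
        cell_params.migration_threshold * cell_params.r_nuc,
        cutoff_min,
    )
    # the kernel sees events between samples; prefer its event times
    if clustering_t >= 0.0:
        cl_min, cl_cens = clustering_t / 60.0, False
    if migration_t >= 0.0:
        mg_min, mg_cens = migration_t / 60.0, False

    rec = observables.RunRecord(
        seed=seed,
        scenario=scenario.name,
        clustering_time_min=cl_min,
        clustering_censored=cl_cens,
        migration_time_min=mg_min,
        migration_censored=mg_cens,
        mean_cmt_length_um=float(mean_len),
        final_neck_to_nucleus_um=float(samp_neck[n_samp - 1]) if n_samp else float("nan"),
        f_c_cell=f_c_cell,
        n_bodies_final=int(samp_nbod[n_samp - 1]) if n_samp else -1,
        max_ne_residual_um=float(max_ne_res),
    )
    if keep_series:
        rec.times_min = samp_t[:n_samp] / 60.0
        rec.neck_distance_um = samp_neck[:n_samp].copy()
        rec.n_bodies_series = samp_nbod[:n_samp].copy()
        rec.spb_separation_um = samp_spb[:n_samp].copy()
    return rec


def run_population(
    params: SimulationParams,
    scenario: Scenario,
    n: int | None = None,
    base_seed: int | None = None,
    keep_series: bool = False,
) -> tuple[observables.PopulationSummary, list[observables.RunRecord]]:
    """Simulate n independent cells with seeds base_seed .. base_seed+n-1."""
    n = scenario.n_reps if n is None else n
    base_seed = scenario.seed if base_seed is None else base_seed
    if n < 1:
        raise ValueError("population size must be >= 1")
    records = [
        run_cell(params, scenario, (base_seed + i) % _MAX_SEED, keep_series)
        for i in range(n)
    ]
    summary = observables.summarize_population(
        records, cutoff_min=scenario.migration_cutoff
    )
    return summary, records


def run_scan(
    params: SimulationParams,
    patch_grid,
    rest_grid,
    n_per_point: int = 20,
    base_seed: int = 0,
    time_window_min: tuple[float, float] = (35.0, 40.0),
    fraction_threshold: float = 0.9,
):
    """Scan the daughter-cortex dynein program (patch x background grid).

    Returns a long-format DataFrame with one row per grid point carrying
    the mean migration time, the fraction of cells migrating within the
    cutoff, and the favourable-region flag (mean within ``time_window_min``
    and fraction at or above ``fraction_threshold``).
    """
    import pandas as pd

    rows = []
    for ip, patch in enumerate(patch_grid):
        for ir, rest in enumerate(rest_grid):
            scenario = make_scenario(
                "dynein_puncta_scan",
                {"lambda_dynein_patch": float(patch), "lambda_dynein_rest": float(rest)},
                n_reps=n_per_point,
                seed=base_seed,
            )
            summary, _ = run_population(params, scenario, n_per_point, base_seed)
            favorable = (
                summary.fraction_proper_migration >= fraction_threshold
                and time_window_min[0]
                <= summary.mean_migration_min
                <= time_window_min[1]
            )
            rows.append(
                {
                    "lambda_dynein_patch": float(patch),
                    "lambda_dynein_rest": float(rest),
                    "n": n_per_point,
                    "mean_migration_min": summary.mean_migration_min,
                    "fraction_proper_migration": summary.fraction_proper_migration,
                    "mean_clustering_min": summary.mean_clustering_min,
                    "favorable": bool(favorable),
                }
            )
    return pd.DataFrame(rows)
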