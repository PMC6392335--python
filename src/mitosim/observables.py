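"""Event detection and population summaries.

The two headline observables, both measured since bud emergence (t = 0 of a
run): the MTOC clustering time -- the first moment a single fused body
carries every founding MTOC -- and the nuclear migration time -- the first
moment the signed neck-to-nucleus distance exceeds one nuclear radius,
i.e. the nucleus centre has moved a full radius past the septin plane into
the daughter.  Runs in which an event never happens are censored: they
carry the cutoff (or run-end) time and a flag, never a fabricated value,
and are excluded from means but included in completion fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RunRecord",
    "PopulationSummary",
    "detect_clustering_time",
    "detect_migration_time",
    "summarize_population",
    "records_to_dataframe",
]


@dataclass
class RunRecord:
    seed: int
    scenario: str
    clustering_time_min: float        # censoring value if censored
    clustering_censored: bool
    migration_time_min: float
    migration_censored: bool
    mean_cmt_length_um: float         # time-average over the run
    final_neck_to_nucleus_um: float
    f_c_cell: float                   # per-cell catastrophe frequency (1/min)
    n_bodies_final: int
    max_ne_residual_um: float = 0.0
    times_min: np.ndarray | None = None
    neck_distance_um: np.ndarray | None = None
    n_bodies_series: np.ndarray | None = None
    spb_separation_um: np.ndarray | None = None


@dataclass
class PopulationSummary:
    n: int
    scenario: str
    mean_clustering_min: float
    sem_clustering_min: float
    n_clustered: int
    mean_migration_min: float
    sem_migration_min: float
    n_migrated: int
    fraction_complete_fusion: float
    fraction_proper_migration: float
    cutoff_min: float
    distance_histogram: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "n": self.n,
            "scenario": self.scenario,
            "mean_clustering_min": self.mean_clustering_min,
            "sem_clustering_min": self.sem_clustering_min,
            "n_clustered": self.n_clustered,
            "mean_migration_min": self.mean_migration_min,
            "sem_migration_min": self.sem_migration_min,
            "n_migrated": self.n_migrated,
            "fraction_complete_fusion": self.fraction_complete_fusion,
            "fraction_proper_migration": self.fraction_proper_migration,
            "cutoff_min": self.cutoff_min,
        }
        out.update(self.distance_histogram)
        return out


# ----------------------------------------------------------------------
def detect_clustering_time(
    fusion_times_min: np.ndarray,
    fusion_n_remaining: np.ndarray,
    n_founders: int,
    run_end_min: float,
) -> tuple[float, bool]:
    """First time a single body holds all founders, from the fusion log.

    Returns (time_min, censored).  A single-founder cell is clustered at
    t = 0; a log that never reaches one remaining body is censored at run
    end.
    """
    if n_founders <= 1:
        return 0.0, False
    for t, nrem in zip(fusion_times_min, fusion_n_remaining):
        if t >= 0 and nrem == 1:
            return float(t), False
    return float(run_end_min), True


def detect_migration_time(
    times_min: np.ndarray,
    neck_distance_um: np.ndarray,
    threshold_um: float,
    cutoff_min: float,
) -> tuple[float, bool]:
    """First time the signed neck-to-nucleus distance reaches the threshold.

    Works on a sampled distance series; censored at the cutoff when the
    nucleus never passes.  A trajectory that starts past the threshold
    migrates at time zero.
    """
    mask = np.isfinite(times_min) & np.isfinite(neck_distance_um)
    t = np.asarray(times_min)[mask]
    d = np.asarray(neck_distance_um)[mask]
    hit = np.nonzero(d >= threshold_um)[0]
    if hit.size:
        return float(t[hit[0]]), False
    return float(cutoff_min), True


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return math.nan, math.nan
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, sem


def summarize_population(
    records: list[RunRecord],
    cutoff_min: float = 60.0,
    histogram_bin_um: float = 0.5,
) -> PopulationSummary:
    """Population means (over uncensored runs), SEMs and completion fractions.

    Censored runs count in the denominators of the fractions but never in
    the means; the histogram collects final neck-to-nucleus distances of
    all runs at fixed bin width.
    """
    if not records:
        raise ValueError("cannot summarise an empty population")
    cl = np.array(
        [r.clustering_time_min for r in records if not r.clustering_censored]
    )
    mg = np.array(
        [
            r.migration_time_min
            for r in records
            if not r.migration_censored and r.migration_time_min <= cutoff_min
        ]
    )
    mean_cl, sem_cl = _mean_sem(cl)
    mean_mg, sem_mg = _mean_sem(mg)
    n = len(records)

    final_d = np.array([r.final_neck_to_nucleus_um for r in records])
    lo = math.floor(final_d.min() / histogram_bin_um) * histogram_bin_um
    hi = math.ceil(final_d.max() / histogram_bin_um) * histogram_bin_um
    edges = np.arange(lo, hi + histogram_bin_um, histogram_bin_um)
    if len(edges) < 2:
        edges = np.array([lo, lo + histogram_bin_um])
    counts, edges = np.histogram(final_d, bins=edges)
    hist = {
        "histogram_edges_um": edges.tolist(),
        "histogram_counts": counts.tolist(),
    }

    return PopulationSummary(
        n=n,
        scenario=records[0].scenario,
        mean_clustering_min=mean_cl,
        sem_clustering_min=sem_cl,
        n_clustered=int(cl.size),
        mean_migration_min=mean_mg,
        sem_migration_min=sem_mg,
        n_migrated=int(mg.size),
        fraction_complete_fusion=cl.size / n,
        fraction_proper_migration=mg.size / n,
        cutoff_min=cutoff_min,
        distance_histogram=hist,
    )


def records_to_dataframe(records: list[RunRecord]) -> pd.DataFrame:
    """One row per run; the long-format table written by the CLI."""
    return pd.DataFrame(
        {
            "seed": [r.seed for r in records],
            "scenario": [r.scenario for r in records],
            "clustering_time_min": [r.clustering_time_min for r in records],
            "clustering_censored": [r.clustering_censored for r in records],
            "migration_time_min": [r.migration_time_min for r in records],
            "migration_censored": [r.migration_censored for r in records],
            "mean_cmt_length_um": [r.mean_cmt_length_um for r in records],
            "final_neck_to_nucleus_um": [
                r.final_neck_to_nucleus_um for r in records
            ],
            "f_c_cell": [r.f_c_cell for r in records],
            "n_bodies_final": [r.n_bodies_final for r in records],
        }
    )
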