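"""Model parameters and scenario definitions.

All quantities are stored in the units in which they are conventionally
reported for this system: lengths in micrometres, forces in piconewton,
spring constants in pN/um, viscosities in pN s/um^2, microtubule speeds in
um/min and transition frequencies in 1/min -- with the single exception of
the stalled-tip catastrophe rate ``f_c_stall`` which is a per-second rate.
The simulation engine converts everything to a (um, pN, s) system once, at
the moment a parameter vector is handed to the integrator, so that no
per-minute quantity ever leaks into the inner loop.

Parameters that come straight from measured or literature values carry
their customary symbols (``v_g``, ``f_c``, ``lambda_dyn`` ...).  A second
group closes gaps the physical description leaves open (cortex width,
integration step, bud growth schedule, the length scale of the
Bim1/dynein bias).  Those are ordinary configuration values with
documented defaults; see ``docs/methods.md`` for how each default was
chosen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "SimulationParams",
    "Scenario",
    "ParameterError",
    "UnknownScenarioError",
    "SCENARIO_NAMES",
    "load_params",
    "make_scenario",
    "serialize_params",
]


class ParameterError(ValueError):
    """A parameter failed validation; carries the field name and value."""

    def __init__(self, name: str, value: Any, reason: str):
        self.name = name
        self.value = value
        super().__init__(f"invalid parameter {name}={value!r}: {reason}")


class UnknownScenarioError(KeyError):
    pass


@dataclass(frozen=True)
class SimulationParams:
    # -- counts and geometry -------------------------------------------------
    n_kt: int = 14                  # kinetochores (= founding MTOCs)
    r_mother: float = 3.0           # um, mother cell radius
    r_nuc: float = 1.0              # um, nucleus radius
    r_spb: float = 0.125            # um, radius of a single MTOC/SPB
    r_kt: float = 0.1               # um, kinetochore radius (not tabulated)

    # -- passive mechanics ---------------------------------------------------
    k_cor: float = 5.0              # pN/um, cortex spring constant
    eta_cyt: float = 5.0            # pN s/um^2, cytoplasm viscosity
    eta_nu: float = 10.0            # pN s/um^2, nucleoplasm viscosity
    eta_ne: float = 10.0            # pN s/um^2, effective NE viscosity

    # -- cytoplasmic MT dynamic instability ----------------------------------
    v_g: float = 10.4               # um/min, growth speed
    v_s: float = 28.6               # um/min, shrink speed
    f_c: float = 1.0                # 1/min, catastrophe frequency (wild type)
    f_c_min: float = 1.0            # 1/min, lower end of mutant range
    f_c_max: float = 21.0           # 1/min, upper end of mutant range
    f_r: float = 0.02               # 1/min, rescue frequency
    f_c_stall: float = 0.04         # 1/s, catastrophe rate of a stalled tip
    f_stall: float = 1.7            # pN, stall force of a growing MT

    # -- motors and crosslinkers ---------------------------------------------
    f_dyn: float = 1.0              # pN, force per dynein
    lambda_dyn: float = 6.0         # 1/um, dynein per unit MT length in cortex
    lambda_ipmt: float = 1.0        # 1/um, kinesin-5 per unit ipMT overlap
    f_kinesin5: float = 1.0         # pN, force per kinesin-5
    k_cohesion: float = 0.1         # pN/um, sister-KT cohesin spring
    k_c: float = 10.0               # pN/um, KT <- shrinking-kMT spring
    k_fibril: float = 5.0           # pN/um, KT fibril (growing-kMT) spring
    c_kt_repulsion: float = 1.0     # pN/um, KT-KT hard-core repulsion
    f_wall: float = 1.0             # pN, push impulse on wall-induced catastrophe

    # -- gap-filling configuration (not tabulated; see docs/methods.md) ------
    w_cor: float = 0.18             # um, cortex shell width
    dt: float = 0.05                # s, Euler step
    h_kmt: float = 50.0             # 1/(min um), kMT length-catastrophe slope
    lambda_bim1: float = 6.0        # 1/um, Bim1 density on mother cortex
    final_budding_index: float = 0.8
    bud_growth_duration: float = 42.0   # min, linear growth to final index
    bias_length_const: float = 0.65     # um, e-folding of the length bias
    l_wt_ref: float = 2.63              # um, wild-type reference mean cMT length
    lambda_dynein_patch: float = 1.0    # x lambda_dyn in the daughter patch
    lambda_dynein_rest: float = 1.0     # x lambda_dyn elsewhere in daughter
    patch_area_fraction: float = 0.10   # daughter-cortex area in the patch
    n_cmt_per_mtoc: int = 1
    n_cmt_per_spb: int = 20
    neck_fraction: float = 0.85         # septin-ring radius / bud radius
    dynein_engagement_time: float = 60.0   # s, plus-end motor recruitment
    septin_ring_radius: float = 0.9     # um, constriction the nucleus squeezes through
    k_septum: float = 0.0               # pN/um, septum constriction (0 = off)
    sliding_angle_deg: float = 30.0     # deg, incidence below which tips slide
    kappa_mt: float = 0.2               # pN um^2, effective MT bending modulus
    mother_dynein_multiplier: float = 1.0
    length_dependent_bias: bool = False
    bias_scales_dynein: bool = False    # if True, B also scales mother dynein
    migration_cutoff: float = 60.0      # min
    migration_threshold: float = 1.0    # x r_nuc past the septin plane
    sample_interval: float = 5.0        # s, trajectory sampling

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "r_mother r_nuc r_spb r_kt k_cor eta_cyt eta_nu eta_ne v_g v_s "
            "f_c f_c_min f_c_max f_r f_c_stall f_stall f_dyn lambda_dyn "
            "lambda_ipmt f_kinesin5 k_cohesion k_c k_fibril c_kt_repulsion "
            "f_wall w_cor dt h_kmt bud_growth_duration bias_length_const "
            "l_wt_ref neck_fraction sliding_angle_deg kappa_mt "
            "mother_dynein_multiplier migration_cutoff migration_threshold "
            "sample_interval dynein_engagement_time septin_ring_radius"
        ).split()
        for name in positive:
            v = getattr(self, name)
            if not v > 0:
                raise ParameterError(name, v, "must be strictly positive")
        nonneg = (
            "lambda_bim1 lambda_dynein_patch lambda_dynein_rest k_septum"
        ).split()
        for name in nonneg:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(name, v, "must be non-negative")
        if self.n_kt < 1:
            raise ParameterError("n_kt", self.n_kt, "need at least one kinetochore")
        if self.n_cmt_per_mtoc < 1:
            raise ParameterError(
                "n_cmt_per_mtoc", self.n_cmt_per_mtoc, "need at least one cMT"
            )
        if self.n_cmt_per_spb < 1:
            raise ParameterError(
                "n_cmt_per_spb", self.n_cmt_per_spb, "need at least one cMT"
            )
        if not self.r_nuc < self.r_mother:
            raise ParameterError(
                "r_nuc", self.r_nuc,
                f"nucleus must fit inside the mother cell (r_mother={self.r_mother})",
            )
        if not self.r_spb < self.r_nuc:
            raise ParameterError(
                "r_spb", self.r_spb, f"SPB must be smaller than the nucleus (r_nuc={self.r_nuc})"
            )
        if not 0 < self.final_budding_index <= 1:
            raise ParameterError(
                "final_budding_index", self.final_budding_index, "must lie in (0, 1]"
            )
        if self.f_c_min > self.f_c_max:
            raise ParameterError(
                "f_c_min", self.f_c_min, f"exceeds f_c_max={self.f_c_max}"
            )
        if not 0 < self.patch_area_fraction < 1:
            raise ParameterError(
                "patch_area_fraction", self.patch_area_fraction, "must lie in (0, 1)"
            )
        if not 0 < self.neck_fraction < 1:
            raise ParameterError(
                "neck_fraction", self.neck_fraction, "must lie in (0, 1)"
            )

    # ------------------------------------------------------------------
    def replace(self, **overrides: Any) -> "SimulationParams":
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ParameterError(sorted(unknown)[0], overrides[sorted(unknown)[0]],
                                 "unknown parameter")
        return dataclasses.replace(self, **overrides)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


def load_params(config_text: str | None = None) -> SimulationParams:
    """Build a :class:`SimulationParams` from a YAML key-value document.

    An empty or ``None`` document yields the defaults.  Unknown keys are
    rejected, and the resulting parameter set is validated.
    """
    data: Mapping[str, Any] = {}
    if config_text:
        loaded = yaml.safe_load(config_text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ParameterError("<document>", loaded, "expected a key-value mapping")
        data = loaded
    valid = {f.name for f in dataclasses.fields(SimulationParams)}
    for key in data:
        if key not in valid:
            raise ParameterError(key, data[key], "unknown parameter")
    return SimulationParams(**data)


def serialize_params(params: SimulationParams) -> str:
    """Serialize to YAML such that ``load_params`` round-trips exactly."""
    return yaml.safe_dump(params.asdict(), sort_keys=True)


# ----------------------------------------------------------------------
SCENARIO_NAMES = (
    "wild_type_cib",
    "ipl1_homogeneous",
    "ipl1_heterogeneous",
    "bim1_delta",
    "dyn1_oe",
    "dynein_puncta_scan",
)

#: per-scenario parameter overrides, applied before any user overrides
_SCENARIO_DEFAULTS: dict[str, dict[str, Any]] = {
    "wild_type_cib": {},
    # homogeneous population with uniformly destabilised cMTs (f_c chosen so
    # the free-space mean length is ~1.3 um) and an unchanged, uniform bias
    "ipl1_homogeneous": {"f_c": 8.0, "length_dependent_bias": False},
    # per-cell f_c drawn from the mutant range plus the exponential
    # length-dependent loss of cortical bias
    "ipl1_heterogeneous": {
        "length_dependent_bias": True,
        "bias_scales_dynein": True,
    },
    "bim1_delta": {"lambda_bim1": 0.0},
    "dyn1_oe": {"mother_dynein_multiplier": 3.0},
    "dynein_puncta_scan": {},
}


@dataclass(frozen=True)
class Scenario:
    """A named perturbation of the wild-type parameter set.

    ``heterogeneous_f_c`` marks scenarios in which each simulated cell draws
    its own catastrophe frequency uniformly from ``[f_c_min, f_c_max]``.
    """

    name: str
    overrides: dict = field(default_factory=dict)
    n_reps: int = 100
    seed: int = 0
    migration_cutoff: float = 60.0
    heterogeneous_f_c: bool = False

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise UnknownScenarioError(self.name)
        if self.n_reps < 1:
            raise ParameterError("n_reps", self.n_reps, "need at least one replicate")
        valid = {f.name for f in dataclasses.fields(SimulationParams)}
        for key in self.overrides:
            if key not in valid:
                raise ParameterError(key, self.overrides[key], "unknown parameter override")

    def resolve(self, base: SimulationParams) -> SimulationParams:
        """Apply this scenario to a base parameter set (base is untouched)."""
        merged = dict(self.overrides)
        merged.setdefault("migration_cutoff", self.migration_cutoff)
        return base.replace(**merged)


def make_scenario(
    name: str,
    overrides: Mapping[str, Any] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    migration_cutoff: float = 60.0,
) -> Scenario:
    """Construct a named scenario with its documented default overrides.

    User ``overrides`` win over the scenario defaults; the base defaults
    object is never mutated.
    """
    if name not in SCENARIO_NAMES:
        raise UnknownScenarioError(name)
    merged = dict(_SCENARIO_DEFAULTS[name])
    if overrides:
        merged.update(overrides)
    return Scenario(
        name=name,
        overrides=merged,
        n_reps=n_reps,
        seed=seed,
        migration_cutoff=migration_cutoff,
        heterogeneous_f_c=(name == "ipl1_heterogeneous"),
    )
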