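"""Versioned parameter registry and simulation configuration.

Every model constant lives here with a provenance tag:

* ``table`` — printed in the source model's parameter table,
* ``text``  — stated in the surrounding model description,
* ``surrogate`` — a constant of this package's reduced-order closure
  (electro-vascular surrogate, NO kinetics, balloon constants), chosen
  once and documented in ``docs/methods.md``.

Configurations are plain frozen dataclasses with eager validation; they can
be overridden from a YAML/JSON mapping keyed by the registry symbol names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Literal

import yaml

from .errors import ConfigurationError, InvalidParameterError

REGISTRY_VERSION = "1.0"


@dataclass(frozen=True)
class ParamSpec:
    """One registered model constant."""

    symbol: str
    value: float
    units: str
    provenance: Literal["table", "text", "surrogate"]
    description: str


#: The parameter registry: symbol -> ParamSpec. Rates are per millisecond,
#: potentials in mV, conductances in uM mV^-1 ms^-1, concentrations as noted.
REGISTRY: dict[str, ParamSpec] = {
    p.symbol: p
    for p in [
        # --- interneuron signalling -------------------------------------
        ParamSpec("alpha_gaba", 1.6e-3, "ms^-1", "table",
                  "nondimensional GABA production rate during stimulation"),
        ParamSpec("beta_gaba", 2.2e-3, "ms^-1", "table",
                  "GABA activity (degradation) rate, scaled by GABA-T activity"),
        ParamSpec("alpha_npy", 4.2e-3, "ms^-1", "table",
                  "nondimensional NPY production rate during stimulation"),
        ParamSpec("beta_npy", 2.2e-3, "ms^-1", "table",
                  "NPY degradation rate"),
        ParamSpec("beta_glu", 4.2e-3, "ms^-1", "table",
                  "glutamate degradation rate"),
        ParamSpec("gaba_base", 0.0, "nondimensional", "text",
                  "resting GABA concentration (zero by nondimensionalisation)"),
        ParamSpec("npy_base", 0.0, "nondimensional", "text",
                  "resting NPY concentration"),
        ParamSpec("gt_min", 1.0, "unitless", "table",
                  "minimum GABA-T activity (NO saturating)"),
        ParamSpec("gt_max", 2.0, "unitless", "table",
                  "maximum GABA-T activity (NO ~ 0)"),
        ParamSpec("gt_midpoint", 0.06, "uM", "table",
                  "NO concentration at half-maximal GABA-T activity"),
        ParamSpec("gt_slope", 0.02128, "uM", "table",
                  "width of the GABA-T inhibition sigmoid"),
        ParamSpec("glu_max", 1.0, "nondimensional", "surrogate",
                  "maximal K+-triggered glutamate release magnitude"),
        ParamSpec("ke_switch", 5.0, "mM", "text",
                  "extracellular K+ above which the excitatory neuron releases glutamate"),
        ParamSpec("glu_slope", 0.1, "mM", "text",
                  "width of the glutamate-release sigmoid"),
        ParamSpec("no_rest", 0.02047, "uM", "text",
                  "resting neuronal NO concentration"),
        ParamSpec("no_alpha", 4.5034e-4, "uM ms^-1", "surrogate",
                  "stimulation-gated NO production rate (sustained elevation ~10x rest)"),
        ParamSpec("no_beta", 2.2e-3, "ms^-1", "surrogate",
                  "first-order NO decay rate"),
        # --- membrane channels -------------------------------------------
        ParamSpec("g_cl_i", 1.34e-6, "uM mV^-1 ms^-1", "text",
                  "SMC Cl- leak conductance"),
        ParamSpec("g_gaba_max", 4.02e-7, "uM mV^-1 ms^-1", "table",
                  "maximal GABA-gated Cl- conductance (0.3 x g_cl_i)"),
        ParamSpec("e_gaba", -75.0, "mV", "table",
                  "Cl- reversal potential of the GABA-gated channels"),
        ParamSpec("g_ca_i", 1.29e-6, "uM mV^-1 ms^-1", "text",
                  "base VOCC conductance on the SMC"),
        ParamSpec("v_ca1", 100.0, "mV", "text", "VOCC reversal potential"),
        ParamSpec("v_ca2", -24.0, "mV", "text", "VOCC activation half-point"),
        ParamSpec("r_ca", 8.5, "mV", "text", "VOCC activation slope"),
        ParamSpec("n_inc", 0.05, "unitless", "text",
                  "fractional VOCC conductance increase at maximal NPY"),
        ParamSpec("n_mid", 0.5, "nondimensional", "table",
                  "NPY sigmoid midpoint for the VOCC conductance"),
        ParamSpec("n_slope", 0.15, "nondimensional", "table",
                  "NPY sigmoid width for the VOCC conductance"),
        ParamSpec("g_mid", 0.5, "nondimensional", "table",
                  "GABA sigmoid midpoint for the Cl- conductance"),
        ParamSpec("g_slope", 0.15, "nondimensional", "table",
                  "GABA sigmoid width for the Cl- conductance"),
        # --- electro-vascular surrogate ----------------------------------
        ParamSpec("surrogate.k_e_base", 3.0, "mM", "surrogate",
                  "resting extracellular K+"),
        ParamSpec("surrogate.k_amp", 0.01, "mM ms^-1", "surrogate",
                  "stimulation-gated K+ source (sustained elevation ~5 mM)"),
        ParamSpec("surrogate.tau_ke", 500.0, "ms", "surrogate",
                  "extracellular K+ clearance time constant"),
        ParamSpec("surrogate.tau_kp", 500.0, "ms", "surrogate",
                  "astrocytic relay lag from K_e to perivascular K+"),
        ParamSpec("surrogate.v_k_rest", -80.0, "mV", "surrogate",
                  "astrocyte resting membrane potential"),
        ParamSpec("surrogate.k_dep_amp", 20.0, "mV", "surrogate",
                  "saturating astrocyte depolarisation at high K_e"),
        ParamSpec("surrogate.k_dep_scale", 3.0, "mM", "surrogate",
                  "K_e scale of the astrocyte depolarisation"),
        ParamSpec("surrogate.tau_vk", 200.0, "ms", "surrogate",
                  "astrocyte membrane relaxation time"),
        ParamSpec("surrogate.v_i_rest", -45.0, "mV", "surrogate",
                  "SMC resting membrane potential"),
        ParamSpec("surrogate.kir_amp", 15.0, "mV", "surrogate",
                  "saturating KIR-mediated SMC hyperpolarisation at high perivascular K+"),
        ParamSpec("surrogate.kir_scale", 3.0, "mM", "surrogate",
                  "perivascular-K+ scale of the KIR hyperpolarisation"),
        ParamSpec("surrogate.tau_vi", 200.0, "ms", "surrogate",
                  "SMC membrane relaxation time"),
        ParamSpec("surrogate.w_gaba", 4000.0, "mV uM^-1", "surrogate",
                  "voltage gain converting GABA Cl- flux to membrane drive"),
        ParamSpec("surrogate.tau_ca", 300.0, "ms", "surrogate",
                  "SMC cytosolic Ca2+ relaxation time"),
        ParamSpec("surrogate.r_amp", 0.15, "unitless", "surrogate",
                  "maximal fractional radius excursion"),
        ParamSpec("surrogate.ca_scale", 0.5, "nondimensional", "surrogate",
                  "Ca2+ scale of the radius response"),
        ParamSpec("surrogate.tau_r", 500.0, "ms", "surrogate",
                  "arteriolar radius relaxation time"),
        ParamSpec("surrogate.tau_act", 1000.0, "ms", "surrogate",
                  "first-order lag smoothing the stimulus into metabolic activity"),
        ParamSpec("surrogate.hete_gain", 0.0, "mV", "surrogate",
                  "optional 20-HETE-like depolarising term driven by glutamate (off)"),
        # --- balloon hemodynamics ----------------------------------------
        ParamSpec("balloon.tau", 2000.0, "ms", "surrogate",
                  "venous mean transit time"),
        ParamSpec("balloon.alpha_g", 0.38, "unitless", "surrogate",
                  "Grubb flow-volume exponent"),
        ParamSpec("balloon.e0", 0.4, "unitless", "surrogate",
                  "baseline oxygen extraction fraction"),
        ParamSpec("balloon.cmro_gain", 0.1, "unitless", "surrogate",
                  "fractional CMRO2 increase at full sustained activity (whisker)"),
        ParamSpec("balloon.cmro_gain_opto", 0.0, "unitless", "surrogate",
                  "metabolic coupling for optogenetic interneuron stimulation"),
    ]
}


def registry_defaults() -> dict[str, float]:
    """Return ``{symbol: default value}`` for every registered parameter."""
    return {k: v.value for k, v in REGISTRY.items()}


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SignallingParams:
    """Kinetic constants of the interneuron GABA/NPY/Glu/NO system."""

    alpha_gaba: float = REGISTRY["alpha_gaba"].value
    beta_gaba: float = REGISTRY["beta_gaba"].value
    alpha_npy: float = REGISTRY["alpha_npy"].value
    beta_npy: float = REGISTRY["beta_npy"].value
    beta_glu: float = REGISTRY["beta_glu"].value
    gaba_base: float = REGISTRY["gaba_base"].value
    npy_base: float = REGISTRY["npy_base"].value
    gt_min: float = REGISTRY["gt_min"].value
    gt_max: float = REGISTRY["gt_max"].value
    gt_midpoint: float = REGISTRY["gt_midpoint"].value
    gt_slope: float = REGISTRY["gt_slope"].value
    glu_max: float = REGISTRY["glu_max"].value
    ke_switch: float = REGISTRY["ke_switch"].value
    glu_slope: float = REGISTRY["glu_slope"].value
    no_rest: float = REGISTRY["no_rest"].value
    no_alpha: float = REGISTRY["no_alpha"].value
    no_beta: float = REGISTRY["no_beta"].value

    def __post_init__(self):
        if self.gt_min > self.gt_max:
            raise InvalidParameterError("gt_min must not exceed gt_max")
        for name in ("alpha_gaba", "beta_gaba", "alpha_npy", "beta_npy",
                     "beta_glu", "no_alpha", "no_beta"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"rate {name} must be > 0")
        if self.gt_slope <= 0 or self.glu_slope <= 0:
            raise InvalidParameterError("sigmoid slopes must be > 0")
        if self.no_rest < 0:
            raise InvalidParameterError("no_rest must be >= 0")


@dataclass(frozen=True)
class ChannelParams:
    """Conductances and gating constants of the GABA Cl- and VOCC channels."""

    g_gaba_max: float = REGISTRY["g_gaba_max"].value
    e_gaba: float = REGISTRY["e_gaba"].value
    g_cl_i: float = REGISTRY["g_cl_i"].value
    g_ca_i: float = REGISTRY["g_ca_i"].value
    v_ca1: float = REGISTRY["v_ca1"].value
    v_ca2: float = REGISTRY["v_ca2"].value
    r_ca: float = REGISTRY["r_ca"].value
    n_inc: float = REGISTRY["n_inc"].value
    n_mid: float = REGISTRY["n_mid"].value
    n_slope: float = REGISTRY["n_slope"].value
    g_mid: float = REGISTRY["g_mid"].value
    g_slope: float = REGISTRY["g_slope"].value
    #: 'endpoint' rescales the NPY sigmoid so the conductance equals the base
    #: value at NPY=0 and 1+n_inc times it at NPY=1; 'literal' keeps the raw
    #: tanh form for comparison.
    vocc_sigmoid: Literal["endpoint", "literal"] = "endpoint"

    def __post_init__(self):
        if self.v_ca1 <= self.v_ca2:
            raise InvalidParameterError("v_ca1 must exceed v_ca2")
        for name in ("g_gaba_max", "g_cl_i", "g_ca_i"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"conductance {name} must be >= 0")
        if self.n_inc < 0:
            raise InvalidParameterError("n_inc must be >= 0")
        if self.n_slope <= 0 or self.g_slope <= 0 or self.r_ca <= 0:
            raise InvalidParameterError("sigmoid slopes must be > 0")
        if self.vocc_sigmoid not in ("endpoint", "literal"):
            raise InvalidParameterError(
                f"vocc_sigmoid must be 'endpoint' or 'literal', got {self.vocc_sigmoid!r}")


@dataclass(frozen=True)
class SurrogateParams:
    """Constants of the reduced electro-vascular surrogate (all first-order)."""

    k_e_base: float = REGISTRY["surrogate.k_e_base"].value
    k_amp: float = REGISTRY["surrogate.k_amp"].value
    tau_ke: float = REGISTRY["surrogate.tau_ke"].value
    tau_kp: float = REGISTRY["surrogate.tau_kp"].value
    v_k_rest: float = REGISTRY["surrogate.v_k_rest"].value
    k_dep_amp: float = REGISTRY["surrogate.k_dep_amp"].value
    k_dep_scale: float = REGISTRY["surrogate.k_dep_scale"].value
    tau_vk: float = REGISTRY["surrogate.tau_vk"].value
    v_i_rest: float = REGISTRY["surrogate.v_i_rest"].value
    kir_amp: float = REGISTRY["surrogate.kir_amp"].value
    kir_scale: float = REGISTRY["surrogate.kir_scale"].value
    tau_vi: float = REGISTRY["surrogate.tau_vi"].value
    w_gaba: float = REGISTRY["surrogate.w_gaba"].value
    tau_ca: float = REGISTRY["surrogate.tau_ca"].value
    r_amp: float = REGISTRY["surrogate.r_amp"].value
    ca_scale: float = REGISTRY["surrogate.ca_scale"].value
    tau_r: float = REGISTRY["surrogate.tau_r"].value
    tau_act: float = REGISTRY["surrogate.tau_act"].value
    hete_gain: float = REGISTRY["surrogate.hete_gain"].value

    def __post_init__(self):
        for name in ("tau_ke", "tau_kp", "tau_vk", "tau_vi", "tau_ca",
                     "tau_r", "tau_act"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"time constant {name} must be > 0")
        if self.k_e_base < 0 or self.k_amp < 0:
            raise InvalidParameterError("K+ constants must be >= 0")
        if not 0 < self.r_amp < 1:
            raise InvalidParameterError("r_amp must lie in (0, 1)")


@dataclass(frozen=True)
class BalloonParams:
    """Venous balloon constants and metabolic coupling."""

    tau: float = REGISTRY["balloon.tau"].value
    alpha_g: float = REGISTRY["balloon.alpha_g"].value
    e0: float = REGISTRY["balloon.e0"].value
    cmro_gain: float = REGISTRY["balloon.cmro_gain"].value
    cmro_gain_opto: float = REGISTRY["balloon.cmro_gain_opto"].value
    #: 'flow' uses the multiplicative CBF*HbR/CMRO closure for total Hb;
    #: 'volume' uses the standard balloon d_hbt = v - 1 for sensitivity checks.
    hbt_closure: Literal["flow", "volume"] = "flow"

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidParameterError("balloon tau must be > 0")
        if not 0 < self.alpha_g < 1:
            raise InvalidParameterError("alpha_g must lie in (0, 1)")
        if not 0 < self.e0 < 1:
            raise InvalidParameterError("e0 must lie in (0, 1)")
        if self.hbt_closure not in ("flow", "volume"):
            raise InvalidParameterError("hbt_closure must be 'flow' or 'volume'")


@dataclass(frozen=True)
class SolverSettings:
    """scipy.integrate.solve_ivp settings used throughout."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    dt_out: float = 10.0  # ms, output sampling interval
    post_window: float = 18000.0  # ms simulated after stimulus offset

    def __post_init__(self):
        if self.dt_out <= 0 or self.post_window < 0:
            raise InvalidParameterError("dt_out must be > 0 and post_window >= 0")


@dataclass(frozen=True)
class Config:
    """Full simulation configuration."""

    signalling: SignallingParams = field(default_factory=SignallingParams)
    channels: ChannelParams = field(default_factory=ChannelParams)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    balloon: BalloonParams = field(default_factory=BalloonParams)
    solver: SolverSettings = field(default_factory=SolverSettings)


_SECTION_FIELDS = {
    "signalling": SignallingParams,
    "channels": ChannelParams,
    "surrogate": SurrogateParams,
    "balloon": BalloonParams,
    "solver": SolverSettings,
}


def _field_names(cls) -> set[str]:
    return {f.name for f in fields(cls)}


def config_from_dict(overrides: dict[str, Any] | None = None) -> Config:
    """Build a :class:`Config` from a flat or sectioned override mapping.

    Keys may be registry symbols (``beta_gaba``, ``surrogate.tau_ca``,
    ``balloon.e0``) or nested sections (``{"balloon": {"e0": 0.35}}``).
    Unknown keys raise :class:`ConfigurationError`.
    """
    overrides = dict(overrides or {})
    section_over: dict[str, dict[str, Any]] = {k: {} for k in _SECTION_FIELDS}

    def assign(section: str, key: str, value: Any) -> None:
        if key not in _field_names(_SECTION_FIELDS[section]):
            raise ConfigurationError(f"unknown parameter {section}.{key}")
        section_over[section][key] = value

    for key, value in overrides.items():
        if key in _SECTION_FIELDS and isinstance(value, dict):
            for sub, v in value.items():
                assign(key, sub, v)
        elif "." in key:
            section, sub = key.split(".", 1)
            if section not in _SECTION_FIELDS:
                raise ConfigurationError(f"unknown section {section!r}")
            assign(section, sub, value)
        else:
            for section in ("signalling", "channels"):
                if key in _field_names(_SECTION_FIELDS[section]):
                    assign(section, key, value)
                    break
            else:
                raise ConfigurationError(f"unknown parameter {key!r}")

    try:
        return Config(**{
            name: cls(**section_over[name]) for name, cls in _SECTION_FIELDS.items()
        })
    except InvalidParameterError:
        raise
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(str(exc)) from exc


def load_config(path: str | Path | None = None) -> Config:
    """Load a configuration from a YAML or JSON file (defaults if None)."""
    if path is None:
        return Config()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a mapping")
    return config_from_dict(data)


def with_override(config: Config, symbol: str, value: float) -> Config:
    """Return a copy of ``config`` with one registry-symbol override applied."""
    for section in _SECTION_FIELDS:
        key = symbol
        if symbol.startswith(section + "."):
            key = symbol.split(".", 1)[1]
        if key in _field_names(_SECTION_FIELDS[section]) and (
            "." not in symbol or symbol.startswith(section + ".")
        ):
            return replace(config, **{section: replace(getattr(config, section), **{key: value})})
    raise ConfigurationError(f"unknown parameter {symbol!r}")
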