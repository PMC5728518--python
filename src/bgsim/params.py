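"""Parameter tables and configuration loading.

All intrinsic, synaptic, anatomical and neuromodulatory constants ship as
versioned YAML files under ``bgsim/data``.  This module parses them into
typed containers used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import yaml

STANDARD_TYPES = ("MSN_D1", "MSN_D2", "FSI", "GPe_A", "GPe_B", "GPe_C", "SNr")
STN_TYPES = ("STN_RB", "STN_LLRS", "STN_NR")
CELL_TYPES = STANDARD_TYPES + STN_TYPES

#: population each cell type belongs to (GPe/STN sub-types share a nucleus)
NUCLEUS_OF = {
    "MSN_D1": "MSN_D1", "MSN_D2": "MSN_D2", "FSI": "FSI",
    "GPe_A": "GPe", "GPe_B": "GPe", "GPe_C": "GPe",
    "STN_RB": "STN", "STN_LLRS": "STN", "STN_NR": "STN",
    "SNr": "SNr",
}


class ConfigurationError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass(frozen=True)
class IzhiParams:
    """Single-recovery-variable quadratic integrate-and-fire parameters.

    The membrane obeys ``C dv/dt = k (v-v_r)(v-v_t) - u + I`` with recovery
    ``du/dt = a (b (v-v_r) - u)`` and reset ``v -> c, u -> u + d`` when
    ``v >= v_peak``.
    """

    C_mu: float
    k: float
    v_r: float
    v_t: float
    v_peak: float
    a: float
    b: float
    c: float
    d: float
    sigma: float = 0.0
    I_vitro: float = 0.0
    I_vivo: float = 0.0

    def __post_init__(self):
        if not (self.v_r < self.v_t < self.v_peak):
            raise ConfigurationError(
                f"require v_r < v_t < v_peak, got {self.v_r}, {self.v_t}, {self.v_peak}")
        if self.C_mu <= 0:
            raise ConfigurationError("capacitance must be positive")
        if self.sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")


@dataclass(frozen=True)
class StnParams:
    """Two-recovery-variable extension used for subthalamic neurons.

    A second recovery variable u2 models low-threshold calcium and
    calcium-activated potassium currents: it activates below the secondary
    threshold ``v_r2`` (for the gated RB/LLRS types), couples into dv/dt
    with weight ``w2``, and attenuates spike height via
    ``U = 1 / (w1*|u2| + 1/w1)`` (spike when ``v >= v_peak + U*u2``, reset
    to ``c - U*u2``).
    """

    C_mu: float
    k: float
    v_r: float
    v_t: float
    v_peak: float
    c: float
    a1: float
    b1: float
    d1: float
    a2: float
    b2: float
    d2: float
    v_r2: float
    w1: float
    w2: float
    gating: str = "heaviside"   # 'heaviside' | 'always_on'
    sigma: float = 0.0
    I_vitro: float = 0.0
    I_vivo: float = 0.0

    def __post_init__(self):
        if self.gating not in ("heaviside", "always_on"):
            raise ConfigurationError(f"unknown gating {self.gating!r}")
        if self.w1 <= 0:
            raise ConfigurationError("w1 must be positive")
        if not (self.v_r < self.v_t < self.v_peak):
            raise ConfigurationError("require v_r < v_t < v_peak")


@dataclass(frozen=True)
class DopamineState:
    """Receptor-family dopamine levels (dimensionless, 0 = full depletion)."""

    d1: float = 0.3
    d2: float = 0.3

    def __post_init__(self):
        if not (0.0 <= self.d1 <= 1.0 and 0.0 <= self.d2 <= 1.0):
            raise ConfigurationError("dopamine levels must lie in [0, 1]")


@dataclass(frozen=True)
class PlasticityParams:
    """Tsodyks-Markram short-term facilitation/depression constants."""

    U: float
    tau_f: float
    tau_d: float
    mode: str = "static"        # 'facilitating' | 'depressing' | 'static'
    tonic_rate: float = 0.0     # Hz; rate at which G0*scale == G

    def __post_init__(self):
        if self.mode != "static" and not (0.0 < self.U < 1.0):
            raise ConfigurationError("plastic synapses require 0 < U < 1")


def _load_yaml(name: str) -> dict:
    with resources.files("bgsim.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def neuron_params() -> dict:
    """All cell-type parameter sets keyed by type name."""
    raw = _load_yaml("neurons.yaml")
    out: dict[str, IzhiParams | StnParams] = {}
    for name, vals in raw["standard"].items():
        v = dict(vals)
        out[name] = IzhiParams(**v)
    for name, vals in raw["stn"].items():
        out[name] = StnParams(**vals)
    out["_capacitance"] = raw["capacitance"]
    return out


@lru_cache(maxsize=None)
def dopamine_tables() -> dict:
    return _load_yaml("dopamine.yaml")


@lru_cache(maxsize=None)
def network_tables() -> dict:
    return _load_yaml("network.yaml")


@lru_cache(maxsize=None)
def synapse_tables() -> dict:
    return _load_yaml("synapses.yaml")


def get_params(cell_type: str) -> IzhiParams | StnParams:
    try:
        return neuron_params()[cell_type]
    except KeyError:
        raise ConfigurationError(f"unknown cell type {cell_type!r}") from None


def with_overrides(p, **kw):
    """Return a copy of a parameter set with selected fields replaced."""
    return replace(p, **kw)
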