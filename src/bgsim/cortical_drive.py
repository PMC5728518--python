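"""Oscillatory cortical input ensembles.

Each basal-ganglia channel is driven by an ensemble of inhomogeneous
Poisson generators sharing the rate

    lambda(t) = max(0, A cos(2 pi f t + phi) + F_spon)    [spikes/s]

Tonic ensembles sit at F_spon = 3 spikes/s; a phasically active channel is
driven at a fixed 10 spikes/s (static experiments) or with oscillation
amplitude A = 10 on the 3 spikes/s base (frequency sweeps).  Negative
instantaneous rates are clamped at zero.  Parkinsonian input modifications
either raise the cortical rate by 20% or the cortical synaptic conductances
by 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .params import ConfigurationError

__all__ = [
    "EnsembleSpec",
    "tonic_spec",
    "phasic_static_spec",
    "rate_at",
    "clamped_mean_rate",
    "compensated_fspon",
    "sample_events",
    "pd_modify",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """One cortical ensemble: n independent generators with a shared rate."""

    A: float = 0.0            # oscillation amplitude (spikes/s)
    f: float = 0.0            # Hz
    phi: float = 0.0          # rad in [0, 2pi)
    F_spon: float = 3.0       # tonic rate (spikes/s)
    n_generators: int = 1000

    def __post_init__(self):
        if self.n_generators < 1:
            raise ConfigurationError("need at least one generator")


def tonic_spec(**kw) -> EnsembleSpec:
    return EnsembleSpec(A=0.0, F_spon=3.0, **kw)


def phasic_static_spec(**kw) -> EnsembleSpec:
    return EnsembleSpec(A=0.0, F_spon=10.0, **kw)


def rate_at(spec: EnsembleSpec, t: float) -> float:
    """Instantaneous generator rate (spikes/s) at time t (ms), clamped at 0."""
    raw = spec.A * np.cos(2.0 * np.pi * spec.f * t / 1000.0 + spec.phi) + spec.F_spon
    return float(max(0.0, raw))


def clamped_mean_rate(A: float, F_spon: float) -> float:
    """Cycle-averaged rate of the clamped sinusoid (spikes/s)."""
    th = np.linspace(0.0, 2.0 * np.pi, 20001)
    return float(np.trapezoid(np.maximum(0.0, A * np.cos(th) + F_spon), th)
                 / (2.0 * np.pi))


def compensated_fspon(A: float, target_mean: float) -> float:
    """F_spon such that the clamped oscillation keeps a given mean rate.

    Used for weak-amplitude entrainment drives ("oscillate without changing
    the overall cortical firing rate"): when clamping removes mass from the
    troughs, the baseline must drop below the target mean.
    """
    if target_mean >= A:
        return target_mean          # no clamping: mean == F_spon
    return float(brentq(lambda F: clamped_mean_rate(A, F) - target_mean,
                        -A, target_mean + A))


def sample_events(spec: EnsembleSpec, duration: float, dt: float = 0.1,
                  seed=None) -> list[np.ndarray]:
    """Bernoulli-thinned event log per generator (times in ms).

    Reference implementation used for testing the drive statistics; the
    simulation engine draws the same per-step thinning inline.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    lam = np.maximum(0.0, spec.A * np.cos(2 * np.pi * spec.f * t / 1000.0 + spec.phi)
                     + spec.F_spon)
    p = lam * dt / 1000.0
    if np.any(p > 1.0):
        raise ConfigurationError("rate*dt exceeds 1; decrease dt")
    out = []
    for _ in range(spec.n_generators):
        out.append(t[rng.random(t.size) < p])
    return out


def pd_modify(specs: list[EnsembleSpec], mode: str
              ) -> tuple[list[EnsembleSpec], float]:
    """Parkinsonian cortical modification.

    ``rate_up_20`` scales every ensemble's baseline and amplitude by 1.2 and
    leaves conductances untouched; ``conductance_up_10`` returns the specs
    unchanged and a 1.1 multiplier for all cortically originating synapses.
    Dopamine depletion (d1 = d2 = 0) is applied at the engine level.
    """
    if mode == "rate_up_20":
        return [replace(s, A=s.A * 1.2, F_spon=s.F_spon * 1.2) for s in specs], 1.0
    if mode == "conductance_up_10":
        return list(specs), 1.1
    raise ConfigurationError(f"unknown PD mode {mode!r}")
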