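"""Single-neuron dynamics for the eight basal-ganglia cell models.

Every cell is a quadratic integrate-and-fire ("simple model") neuron with
biophysically scaled parameters; subthalamic neurons carry a second recovery
variable for low-threshold calcium dynamics.  The functions here are the
reference (scalar/NumPy) integrators: they define the exact per-step update
semantics that the vectorized simulation kernel in :mod:`bgsim.engine`
reproduces, and they serve as the oracle for cross-checking it.

Integration is explicit forward Euler.  Membrane noise is additive voltage
noise of standard deviation ``sigma * sqrt(dt / 1 ms)`` per step, which makes
the noise magnitude dt-invariant (referenced at 1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    ConfigurationError,
    DopamineState,
    IzhiParams,
    StnParams,
    dopamine_tables,
    get_params,
    neuron_params,
    with_overrides,
)

__all__ = [
    "NeuronState",
    "NeuronPopulation",
    "make_population",
    "step_standard",
    "step_stn",
    "apply_dopamine",
    "stn_spike_gain",
]


class IntegrationError(RuntimeError):
    """Raised when a membrane trajectory becomes non-finite."""


@dataclass
class NeuronState:
    """Dynamical state of one neuron (u2 stays 0 for non-STN types)."""

    v: float
    u1: float = 0.0
    u2: float = 0.0
    C: float = 0.0


@dataclass
class NeuronPopulation:
    """Per-neuron state and realized parameters for one cell type."""

    cell_type: str
    n: int
    params: IzhiParams | StnParams
    C: np.ndarray          # realized capacitances (pF)
    v: np.ndarray
    u1: np.ndarray
    u2: np.ndarray


def draw_capacitance(C_mu: float, n: int, rng: np.random.Generator,
                     rel_std: float = 0.1, trunc_rel: float = 0.2) -> np.ndarray:
    """Heterogeneous capacitances: N(C_mu, rel_std*C_mu) truncated below
    trunc_rel*C_mu (redrawn, keeping the draw strictly positive)."""
    C = rng.normal(C_mu, rel_std * C_mu, size=n)
    lo = trunc_rel * C_mu
    bad = C < lo
    while np.any(bad):
        C[bad] = rng.normal(C_mu, rel_std * C_mu, size=int(bad.sum()))
        bad = C < lo
    return C


def make_population(cell_type: str, n: int, seed=None) -> NeuronPopulation:
    """Create ``n`` neurons of one type, initialized at rest.

    Capacitance is drawn per neuron; all other parameters are shared.
    """
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    p = get_params(cell_type)
    cap = neuron_params()["_capacitance"]
    rng = np.random.default_rng(seed)
    C = draw_capacitance(p.C_mu, n, rng, cap["rel_std"], cap["trunc_rel"])
    return NeuronPopulation(
        cell_type=cell_type, n=n, params=p, C=C,
        v=np.full(n, p.v_r, dtype=float),
        u1=np.zeros(n), u2=np.zeros(n),
    )


def step_standard(state: NeuronState, p: IzhiParams, I: float, dt: float,
                  noise_draw: float = 0.0) -> tuple[NeuronState, bool]:
    """One forward-Euler step of the standard (single-u) model.

    Returns the updated state and whether the neuron fired this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    C = state.C if state.C > 0 else p.C_mu
    v, u = state.v, state.u1
    dv = (p.k * (v - p.v_r) * (v - p.v_t) - u + I) / C
    du = p.a * (p.b * (v - p.v_r) - u)
    v = v + dt * dv + p.sigma * noise_draw * np.sqrt(dt)
    u = u + dt * du
    if not np.isfinite(v):
        raise IntegrationError(f"non-finite membrane potential in {type(p).__name__}")
    fired = v >= p.v_peak
    if fired:
        v = p.c
        u = u + p.d
    return NeuronState(v=v, u1=u, u2=0.0, C=C), bool(fired)


def stn_spike_gain(u2: float, w1: float) -> float:
    """Spike-height attenuation U = 1/(w1*|u2| + 1/w1).

    Equals w1 at u2 = 0 and vanishes for |u2| >> 0, so action-potential
    height converges to v_peak when the calcium variable is large.
    """
    return 1.0 / (w1 * abs(u2) + 1.0 / w1)


def step_stn(state: NeuronState, p: StnParams, I: float, dt: float,
             noise_draw: float = 0.0) -> tuple[NeuronState, bool]:
    """One forward-Euler step of the two-recovery-variable STN model."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    C = state.C if state.C > 0 else p.C_mu
    v, u1, u2 = state.v, state.u1, state.u2
    gate = 1.0 if p.gating == "always_on" else (1.0 if v < p.v_r2 else 0.0)
    dv = (p.k * (v - p.v_r) * (v - p.v_t) - u1 - p.w2 * u2 + I) / C
    du1 = p.a1 * (p.b1 * (v - p.v_r) - u1)
    du2 = p.a2 * (gate * p.b2 * (v - p.v_r2) - u2)
    v = v + dt * dv + p.sigma * noise_draw * np.sqrt(dt)
    u1 = u1 + dt * du1
    u2 = u2 + dt * du2
    if not np.isfinite(v):
        raise IntegrationError("non-finite membrane potential in STN model")
    U = stn_spike_gain(u2, p.w1)
    fired = v >= p.v_peak + U * u2
    if fired:
        v = p.c - U * u2
        u1 = u1 + p.d1
        u2 = u2 + p.d2
    return NeuronState(v=v, u1=u1, u2=u2, C=C), bool(fired)


def apply_dopamine(p: IzhiParams | StnParams, pop: str,
                   da: DopamineState) -> IzhiParams | StnParams:
    """Dopamine modulation of intrinsic parameters (striatal cells only).

    D1 receptor activation hyperpolarizes the MSN_D1 resting potential and
    reduces its after-spike adaptation increment; D2 activation reduces
    MSN_D2 input gain k; FSIs hyperpolarize via D1.  All other populations
    are modulated synaptically, not intrinsically.
    """
    tab = dopamine_tables()["intrinsic"]
    if pop == "MSN_D1":
        b = tab["MSN_D1"]
        return with_overrides(p, v_r=p.v_r * (1 + b["v_r_beta1"] * da.d1),
                              d=p.d * (1 - b["d_beta2"] * da.d1))
    if pop == "MSN_D2":
        b = tab["MSN_D2"]
        return with_overrides(p, k=p.k * (1 - b["k_beta1"] * da.d2))
    if pop == "FSI":
        b = tab["FSI"]
        return with_overrides(p, v_r=p.v_r * (1 + b["v_r_beta1"] * da.d1))
    return p


def simulate_constant_current(cell_type: str, I: float, duration: float,
                              dt: float = 0.1, sigma: float | None = None,
                              C: float | None = None,
                              I_profile=None) -> np.ndarray:
    """Noiseless (or fixed-sigma) single-neuron run; returns spike times (ms).

    ``I_profile`` may be a callable t -> pA overriding the constant current;
    used for hyperpolarize-and-release rebound protocols.
    """
    p = get_params(cell_type)
    if sigma is not None:
        p = with_overrides(p, sigma=sigma)
    st = NeuronState(v=p.v_r, C=C if C is not None else p.C_mu)
    stepper = step_stn if isinstance(p, StnParams) else step_standard
    n_steps = int(round(duration / dt))
    spikes = []
    for i in range(n_steps):
        t = i * dt
        cur = I_profile(t) if I_profile is not None else I
        st, fired = stepper(st, p, cur, dt)
        if fired:
            spikes.append(t + dt)
    return np.asarray(spikes)
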