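"""Chemical and electrical synapse models.

Chemical synapses are conductance-based with single-exponential decay per
receptor (AMPA, NMDA, GABA_A); NMDA currents are attenuated by the
voltage-dependent magnesium block B(v).  Short-term plasticity follows the
Tsodyks-Markram scheme: a running utilization u+ (facilitation) and a
resource fraction x- (depression) relax exponentially between presynaptic
events and update multiplicatively at each event.  Electrical coupling uses
a shared-compartment gap junction: both neurons couple to a common potential
v_gap that relaxes toward their mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    DopamineState,
    PlasticityParams,
    dopamine_tables,
    synapse_tables,
)

__all__ = [
    "ReceptorKinetics",
    "PlasticityState",
    "GapJunction",
    "nmda_block",
    "synaptic_current",
    "plasticity_event",
    "decay_plasticity",
    "steady_state_scale",
    "gap_step",
    "dopamine_scale_current",
]


@dataclass(frozen=True)
class ReceptorKinetics:
    kind: str           # 'AMPA' | 'NMDA' | 'GABA_A'
    E_s: float          # reversal potential (mV)
    tau_s: float        # decay constant (ms)

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.kind in ("AMPA", "NMDA") and self.E_s != 0.0:
            raise ValueError("glutamatergic reversal potential is 0 mV")
        if self.kind == "GABA_A" and self.E_s >= -55.0:
            raise ValueError("GABA_A reversal potential must be below -55 mV")


@dataclass
class PlasticityState:
    """Running utilization and available resource of one plastic synapse."""

    u_plus: float
    x_minus: float = 1.0


@dataclass
class GapJunction:
    i: int
    j: int
    g_gap: float        # nS
    tau_gap: float      # ms
    v_gap: float = 0.0


def nmda_block(v) -> float | np.ndarray:
    """Voltage-dependent magnesium block B(v) = 1/(1 + 0.28 e^{-0.062 v})."""
    nb = synapse_tables()["nmda_block"]
    return 1.0 / (1.0 + nb["scale"] * np.exp(-nb["slope"] * np.asarray(v, dtype=float)))


def synaptic_current(t: float, t_arrival: float, G_eff: float,
                     r: ReceptorKinetics, v_post: float) -> float:
    """Instantaneous current (pA) of one synaptic event.

    Zero before the (delay-shifted) arrival time; afterwards the conductance
    decays exponentially from G_eff.  NMDA currents include the magnesium
    block.
    """
    if t < t_arrival:
        return 0.0
    g = G_eff * np.exp(-(t - t_arrival) / r.tau_s)
    I = g * (r.E_s - v_post)
    if r.kind == "NMDA":
        I *= nmda_block(v_post)
    return float(I)


def decay_plasticity(st: PlasticityState, p: PlasticityParams,
                     dt: float) -> PlasticityState:
    """Relax u+ toward U and x- toward 1 over an inter-event interval dt."""
    ef = np.exp(-dt / p.tau_f) if p.tau_f > 0 else 0.0
    ed = np.exp(-dt / p.tau_d) if p.tau_d > 0 else 0.0
    return PlasticityState(
        u_plus=p.U + (st.u_plus - p.U) * ef,
        x_minus=1.0 + (st.x_minus - 1.0) * ed,
    )


def plasticity_event(st: PlasticityState, p: PlasticityParams
                     ) -> tuple[PlasticityState, float]:
    """Apply one presynaptic event; returns new state and the release scale.

    Ordering is facilitate-then-release-then-depress: u+ increments by
    U(1 - u+), the event releases u+ * x-, and x- is then reduced by the
    utilized fraction.
    """
    if p.mode == "static":
        raise ValueError("plasticity_event on a static synapse")
    u = st.u_plus + p.U * (1.0 - st.u_plus)
    release = u * st.x_minus
    x = st.x_minus * (1.0 - u)
    return PlasticityState(u_plus=u, x_minus=x), release


def steady_state_scale(rate_hz: float, p: PlasticityParams) -> float:
    """Closed-form steady-state release scale u+*x- under periodic drive.

    This is the ratio of the steady-state effective conductance to the
    initial (G0) conductance, the quantity the calibrated G/G0 table entries
    encode at the tonic presynaptic rate.
    """
    if rate_hz <= 0:
        return p.U * (2.0 - p.U) if p.tau_f == 0 else p.U
    T = 1000.0 / rate_hz
    ef = np.exp(-T / p.tau_f) if p.tau_f > 0 else 0.0
    ed = np.exp(-T / p.tau_d) if p.tau_d > 0 else 0.0
    u = p.U / (1.0 - (1.0 - p.U) * ef)
    up = u + p.U * (1.0 - u)
    x = (1.0 - ed) / (1.0 - (1.0 - up) * ed)
    return float(up * x)


def gap_step(j: GapJunction, v_i: float, v_j: float, dt: float
             ) -> tuple[float, float, float]:
    """One Euler step of the shared-compartment gap junction.

    Each neuron receives g_gap*(v_gap - v_self); the shared potential
    relaxes with tau_gap d(v_gap)/dt = v_i + v_j - 2 v_gap.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    I_i = j.g_gap * (j.v_gap - v_i)
    I_j = j.g_gap * (j.v_gap - v_j)
    v_gap = j.v_gap + dt * (v_i + v_j - 2.0 * j.v_gap) / j.tau_gap
    return I_i, I_j, v_gap


def dopamine_scale_current(pop: str, currents: dict, da: DopamineState) -> dict:
    """Scale per-receptor currents {ampa, nmda, gaba} by dopamine level.

    D1 activation potentiates MSN_D1 NMDA input; D2 activation depresses
    MSN_D2 AMPA, FSI GABA, and all STN/GPe afferent currents.
    """
    tab = dopamine_tables()["currents"]
    out = dict(currents)
    if pop == "MSN_D1":
        out["nmda"] = out.get("nmda", 0.0) * (1 + tab["MSN_D1"]["nmda_gain_beta3"] * da.d1)
    elif pop == "MSN_D2":
        out["ampa"] = out.get("ampa", 0.0) * (1 - tab["MSN_D2"]["ampa_loss_beta2"] * da.d2)
    elif pop == "FSI":
        out["gaba"] = out.get("gaba", 0.0) * (1 - tab["FSI"]["gaba_loss_beta2"] * da.d2)
    elif pop in ("STN", "GPe"):
        t = tab[pop]
        f_glut = 1 - t["glut_loss_beta1"] * da.d2
        out["ampa"] = out.get("ampa", 0.0) * f_glut
        out["nmda"] = out.get("nmda", 0.0) * f_glut
        out["gaba"] = out.get("gaba", 0.0) * (1 - t["gaba_loss_beta2"] * da.d2)
    return out


def receptor_gain_tables(da: DopamineState) -> dict[str, dict[str, float]]:
    """Per-population multiplicative gains for ampa/nmda/gaba class currents."""
    pops = ("MSN_D1", "MSN_D2", "FSI", "GPe", "STN", "SNr")
    out = {}
    for pop in pops:
        base = {"ampa": 1.0, "nmda": 1.0, "gaba": 1.0}
        out[pop] = dopamine_scale_current(pop, base, da)
    return out
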