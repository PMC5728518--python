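"""Simulation loop and experiment configurations.

``run`` integrates a :class:`~bgsim.network.NetworkGraph` under a
per-channel cortical drive: forward Euler at dt = 0.1 ms, delayed event
queues at step granularity, short-term plasticity, dopamine scaling of
intrinsic parameters and receptor-class currents, and spike recording into
a tidy columnar :class:`SpikeRecord`.  Runs are bit-reproducible under a
fixed (config, seed) pair.

Experiment helpers reproduce the study conditions: tonic drive (all
channels at 3 spikes/s), phasic selection (one channel at a fixed
10 spikes/s), oscillatory frequency sweeps, weak-beta entrainment, and the
Parkinsonian 'off' state (full dopamine depletion plus potentiated cortical
input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .cortical_drive import (EnsembleSpec, compensated_fspon, pd_modify,
                             phasic_static_spec, tonic_spec)
from .neurons import apply_dopamine, draw_capacitance
from .network import NetworkGraph
from .params import (ConfigurationError, DopamineState, StnParams,
                     get_params, neuron_params, with_overrides)
from .synapses import receptor_gain_tables

__all__ = ["SimulationConfig", "SpikeRecord", "run",
           "experiment_tonic", "experiment_phasic", "experiment_entrainment",
           "experiment_sweep", "experiment_pd"]

CTX_PROJECTIONS = ("Ctx-MSN_D1", "Ctx-MSN_D2", "Ctx-FSI", "Ctx-STN")


@dataclass
class SimulationConfig:
    duration: float                       # ms
    seed: int = 0
    dt: float = 0.1                       # ms
    dopamine: DopamineState = field(default_factory=DopamineState)
    drive: list | None = None             # EnsembleSpec per channel
    pd_mode: str | None = None            # None | rate_up_20 | conductance_up_10
    warmup: float = 500.0                 # ms discarded from statistics
    spike_cap_hz: float = 120.0           # output-buffer budget per neuron
    force: dict = field(default_factory=dict)       # pop -> Poisson rate (Hz)
    param_overrides: dict = field(default_factory=dict)  # cell type -> fields
    g_scale: dict = field(default_factory=dict)     # projection name -> mult

    def __post_init__(self):
        if self.duration < 100 * self.dt:
            raise ConfigurationError("duration must be at least 100 steps")


class SimulationError(RuntimeError):
    pass


@dataclass
class SpikeRecord:
    """Columnar spike event log plus the neuron lookup table."""

    times: np.ndarray          # ms, sorted
    neurons: np.ndarray        # global neuron ids
    table: pd.DataFrame        # neuron, population, subtype, channel
    duration: float
    warmup: float
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.times, "neuron": self.neurons})
        return df.merge(self.table, on="neuron", how="left")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def _mask_ids(self, population=None, channel=None, subtype=None) -> np.ndarray:
        t = self.table
        m = np.ones(len(t), dtype=bool)
        if population is not None:
            m &= (t["population"] == population).to_numpy()
        if channel is not None:
            m &= (t["channel"] == channel).to_numpy()
        if subtype is not None:
            m &= (t["subtype"] == subtype).to_numpy()
        return t.loc[m, "neuron"].to_numpy()

    def select(self, population=None, channel=None, subtype=None,
               tmin=None, tmax=None):
        """Spike (times, ids) of a sub-population inside a time window."""
        ids = self._mask_ids(population, channel, subtype)
        keep = np.isin(self.neurons, ids)
        t, n = self.times[keep], self.neurons[keep]
        tmin = self.warmup if tmin is None else tmin
        tmax = self.duration if tmax is None else tmax
        w = (t >= tmin) & (t < tmax)
        return t[w], n[w]

    def mean_rate(self, population=None, channel=None, subtype=None,
                  tmin=None, tmax=None) -> float:
        """Population-mean firing rate (spikes/s) over the analysis window."""
        ids = self._mask_ids(population, channel, subtype)
        if ids.size == 0:
            raise ValueError("empty selection")
        t, _ = self.select(population, channel, subtype, tmin, tmax)
        tmin = self.warmup if tmin is None else tmin
        tmax = self.duration if tmax is None else tmax
        return 1000.0 * t.size / (ids.size * (tmax - tmin))

    def spike_trains(self, population=None, channel=None, subtype=None,
                     tmin=None, tmax=None) -> dict:
        """Per-neuron spike-time arrays (ms) for the selection."""
        ids = self._mask_ids(population, channel, subtype)
        t, n = self.select(population, channel, subtype, tmin, tmax)
        order = np.argsort(n, kind="stable")
        t, n = t[order], n[order]
        out = {int(i): np.empty(0) for i in ids}
        for i, grp in zip(*_group_sorted(n, t)):
            out[int(i)] = np.sort(grp)
        return out


def _group_sorted(keys, vals):
    if keys.size == 0:
        return [], []
    cut = np.nonzero(np.diff(keys))[0] + 1
    groups = np.split(vals, cut)
    labels = [g[0] for g in np.split(keys, cut)]
    return labels, groups


def _neuron_arrays(graph: NetworkGraph, da: DopamineState, rng,
                   overrides: dict | None = None):
    n = graph.n_neurons
    names = ("vr", "vt", "vpeak", "kk", "a1", "b1", "cc", "d1", "a2", "b2",
             "d2", "vr2", "w1", "w2", "sig", "Ispon", "C")
    arr = {k: np.zeros(n) for k in names}
    arr["heavi"] = np.zeros(n, dtype=np.int8)
    cap = neuron_params()["_capacitance"]
    for ctype in np.unique(graph.subtype):
        idx = np.nonzero(graph.subtype == ctype)[0]
        p = get_params(str(ctype))
        if overrides and str(ctype) in overrides:
            p = with_overrides(p, **overrides[str(ctype)])
        pop_name = _population_of(graph, idx[0])
        p = apply_dopamine(p, pop_name, da)
        stn = isinstance(p, StnParams)
        arr["vr"][idx] = p.v_r
        arr["vt"][idx] = p.v_t
        arr["vpeak"][idx] = p.v_peak
        arr["kk"][idx] = p.k
        arr["cc"][idx] = p.c
        arr["sig"][idx] = p.sigma
        arr["Ispon"][idx] = p.I_vivo
        arr["C"][idx] = draw_capacitance(p.C_mu, idx.size, rng,
                                         cap["rel_std"], cap["trunc_rel"])
        if stn:
            arr["a1"][idx], arr["b1"][idx], arr["d1"][idx] = p.a1, p.b1, p.d1
            arr["a2"][idx], arr["b2"][idx], arr["d2"][idx] = p.a2, p.b2, p.d2
            arr["vr2"][idx] = p.v_r2
            arr["w1"][idx], arr["w2"][idx] = p.w1, p.w2
            arr["heavi"][idx] = 1 if p.gating == "heaviside" else 0
        else:
            arr["a1"][idx], arr["b1"][idx], arr["d1"][idx] = p.a, p.b, p.d
            arr["w1"][idx] = 1.0      # inert second recovery variable
            arr["vr2"][idx] = 0.0
    return arr


def _population_of(graph: NetworkGraph, idx: int) -> str:
    for pop, (a, b) in graph.pop_slices.items():
        if a <= idx < b:
            return pop
    raise IndexError(idx)


def _pack_projections(graph: NetworkGraph, ctx_g_mult: float, dt: float,
                      g_scale: dict | None = None):
    """Fuse logical projections into packed pathways for the kernel.

    Projections that share target population, receptor kinetics, delay and
    (absence of) plasticity are merged into one conductance buffer; edges
    carry per-edge weights and are CSR-indexed by global source id
    (generator id for cortical pathways).
    """
    n_neurons = graph.n_neurons
    n_gen = graph.n_generators * graph.spec.n_channels
    groups: dict = {}
    order: list = []
    for p in graph.projections:
        is_ctx = p.src_pop == "Ctx"
        delay_steps = max(1, int(round(p.delay_ms / dt)))
        pkey = id(p) if p.plasticity is not None else None
        key = (is_ctx, p.tgt_pop, delay_steps, p.E, p.tau_ampa,
               p.tau_nmda, p.nmda_ratio, p.receptor, pkey)
        if key not in groups:
            groups[key] = {"members": [], "proj": p, "is_ctx": is_ctx,
                           "delay": delay_steps}
            order.append(key)
        g = p.G * (ctx_g_mult if p.name in CTX_PROJECTIONS else 1.0)
        if g_scale:
            g *= g_scale.get(p.name, 1.0)
        src_start = 0 if is_ctx else graph.pop_slices[p.src_pop][0]
        src = np.repeat(np.arange(p.indptr.size - 1),
                        np.diff(p.indptr)) + src_start
        groups[key]["members"].append((src, p.targets,
                                       np.full(p.targets.size, g)))

    np_ = len(order)
    f = {k: np.zeros(np_) for k in
         ("dec_a", "dec_n", "E", "ratio", "U", "tauf", "taud")}
    i8 = {k: np.zeros(np_, dtype=np.int8) for k in ("ctx", "gaba", "plastic")}
    i64 = {k: np.zeros(np_, dtype=np.int64) for k in
           ("ip_off", "ed_off", "delay", "t0", "t1", "g_off", "pl_off")}
    indptrs, targets, weights = [], [], []
    pl_u_parts, pl_x_parts, pl_t_parts = [], [], []
    ip_off = ed_off = g_off = pl_off = 0
    for j, key in enumerate(order):
        grp = groups[key]
        p = grp["proj"]
        src = np.concatenate([m[0] for m in grp["members"]])
        tgt = np.concatenate([m[1] for m in grp["members"]])
        w = np.concatenate([m[2] for m in grp["members"]])
        n_src = n_gen if grp["is_ctx"] else n_neurons
        o = np.argsort(src, kind="stable")
        src, tgt, w = src[o], tgt[o], w[o]
        indptr = np.zeros(n_src + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        indptr = np.cumsum(indptr)
        i8["ctx"][j] = 1 if grp["is_ctx"] else 0
        i8["gaba"][j] = 1 if p.receptor == "gaba" else 0
        i64["ip_off"][j] = ip_off
        i64["ed_off"][j] = ed_off
        t0, t1 = graph.pop_slices[p.tgt_pop]
        i64["t0"][j], i64["t1"][j] = t0, t1
        i64["g_off"][j] = g_off
        i64["delay"][j] = grp["delay"]
        f["E"][j] = p.E
        f["ratio"][j] = p.nmda_ratio
        f["dec_a"][j] = np.exp(-dt / p.tau_ampa)
        f["dec_n"][j] = np.exp(-dt / p.tau_nmda)
        if p.plasticity is not None:
            i8["plastic"][j] = 1
            i64["pl_off"][j] = pl_off
            f["U"][j] = p.plasticity.U
            f["tauf"][j] = p.plasticity.tau_f
            f["taud"][j] = p.plasticity.tau_d
            pl_u_parts.append(np.full(tgt.size, p.plasticity.U))
            pl_x_parts.append(np.ones(tgt.size))
            pl_t_parts.append(np.full(tgt.size, -1e12))
            pl_off += tgt.size
        indptrs.append(indptr)
        targets.append(tgt.astype(np.int64))
        weights.append(w)
        ip_off += indptr.size
        ed_off += tgt.size
        g_off += t1 - t0
    cat = (lambda parts, dt_: np.concatenate(parts) if parts
           else np.zeros(0, dtype=dt_))
    return (f, i8, i64, np.concatenate(indptrs), np.concatenate(targets),
            np.concatenate(weights), g_off,
            cat(pl_u_parts, float), cat(pl_x_parts, float),
            cat(pl_t_parts, float))


def _drive_probabilities(drive, n_steps, dt):
    nch = len(drive)
    prob = np.zeros((n_steps, nch))
    t = np.arange(n_steps) * dt
    for c, s in enumerate(drive):
        lam = np.maximum(0.0, s.A * np.cos(2 * np.pi * s.f * t / 1000.0 + s.phi)
                         + s.F_spon)
        prob[:, c] = lam * dt / 1000.0
    if prob.max() > 1.0:
        raise ConfigurationError("generator rate*dt exceeds 1; decrease dt")
    return prob


def run(config: SimulationConfig, graph: NetworkGraph) -> SpikeRecord:
    """Simulate the circuit and return the spike record."""
    nch = graph.spec.n_channels
    drive = list(config.drive) if config.drive is not None \
        else [tonic_spec() for _ in range(nch)]
    if len(drive) != nch:
        raise ConfigurationError("one drive spec per channel required")
    ctx_mult = 1.0
    if config.pd_mode is not None:
        drive, ctx_mult = pd_modify(drive, config.pd_mode)

    ss = np.random.SeedSequence(config.seed)
    s_caps, s_kernel = ss.spawn(2)
    rng = np.random.default_rng(s_caps)
    arr = _neuron_arrays(graph, config.dopamine, rng, config.param_overrides)
    forced_p = np.full(graph.n_neurons, -1.0)
    for pop, rate in config.force.items():
        a, b = graph.pop_slices[pop]
        forced_p[a:b] = max(0.0, rate) * config.dt / 1000.0

    gains = receptor_gain_tables(config.dopamine)
    n = graph.n_neurons
    gain_a, gain_n, gain_g = np.ones(n), np.ones(n), np.ones(n)
    for pop, (a, b) in graph.pop_slices.items():
        g = gains[pop]
        gain_a[a:b], gain_n[a:b], gain_g[a:b] = g["ampa"], g["nmda"], g["gaba"]

    dt = config.dt
    (f, i8, i64, indptr_all, targets_all, weights_all, gbuf_size,
     pl_u, pl_x, pl_t) = _pack_projections(graph, ctx_mult, dt, config.g_scale)

    n_steps = int(round(config.duration / dt))
    prob = _drive_probabilities(drive, n_steps, dt)
    gen_channel = np.repeat(np.arange(nch, dtype=np.int16), graph.n_generators)

    L = int(i64["delay"].max()) + 2
    ring_ids = np.zeros((L, n), dtype=np.int32)
    ring_n = np.zeros(L, dtype=np.int64)
    gring_ids = np.zeros((L, gen_channel.size), dtype=np.int32)
    gring_n = np.zeros(L, dtype=np.int64)

    cap = int(n * config.duration / 1000.0 * config.spike_cap_hz) + 10000
    out_t = np.zeros(cap)
    out_id = np.zeros(cap, dtype=np.int32)

    v = arr["vr"].copy()
    u1 = np.zeros(n)
    u2 = np.zeros(n)
    gj = graph.spec.tables["gap_junctions"]

    krng = np.random.default_rng(s_kernel)
    sig_step = arr["sig"] * np.sqrt(dt)
    gap_i = (graph.gap_pairs[:, 0].astype(np.int64)
             if graph.gap_pairs.size else np.zeros(0, np.int64))
    gap_j = (graph.gap_pairs[:, 1].astype(np.int64)
             if graph.gap_pairs.size else np.zeros(0, np.int64))
    v_gapst = np.full(graph.gap_pairs.shape[0], float(get_params("FSI").v_r))
    g_a_buf = np.zeros(gbuf_size)
    g_n_buf = np.zeros(gbuf_size)
    out_state = np.zeros(1, dtype=np.int64)
    I_scr, vth_scr, vnw_scr = np.zeros(n), np.zeros(n), np.zeros(n)
    rng_state = np.array([krng.integers(1, 2 ** 63, dtype=np.uint64)],
                         dtype=np.uint64)
    err = _kernel.ERR_OK
    err_neuron = err_step = -1
    chunk = 1024
    step0 = 0
    while step0 < n_steps:
        nc = min(chunk, n_steps - step0)
        n_out, err, err_neuron, err_step = _kernel.simulate_chunk(
            step0, nc, dt,
            arr["vr"], arr["vt"], arr["vpeak"], arr["kk"], arr["a1"],
            arr["b1"], arr["cc"], arr["d1"], arr["a2"], arr["b2"], arr["d2"],
            arr["vr2"], arr["w1"], arr["w2"], arr["heavi"], sig_step,
            arr["Ispon"], 1.0 / arr["C"], forced_p, gain_a, gain_n, gain_g,
            v, u1, u2,
            rng_state,
            gen_channel, prob,
            i8["ctx"], i64["ip_off"], i64["ed_off"], i64["delay"],
            f["dec_a"], f["dec_n"], f["E"], i8["gaba"], f["ratio"],
            i64["t0"], i64["t1"], i64["g_off"], i8["plastic"], i64["pl_off"],
            f["U"], f["tauf"], f["taud"],
            indptr_all, targets_all, weights_all,
            g_a_buf, g_n_buf,
            pl_u, pl_x, pl_t,
            gap_i, gap_j, float(gj["g_gap"]), float(gj["tau_gap"]), v_gapst,
            ring_ids, ring_n, gring_ids, gring_n,
            out_t, out_id, out_state, I_scr, vth_scr, vnw_scr)
        if err != _kernel.ERR_OK:
            break
        if not np.all(np.isfinite(v)):
            err = _kernel.ERR_NONFINITE
            err_neuron = int(np.nonzero(~np.isfinite(v))[0][0])
            err_step = step0 + nc - 1
            break
        step0 += nc
    if err == _kernel.ERR_NONFINITE:
        raise SimulationError(
            f"integration failure: non-finite state, neuron {err_neuron} "
            f"({_population_of(graph, err_neuron)}) at t={err_step * dt:.1f} ms")
    if err == _kernel.ERR_OVERFLOW:
        raise SimulationError("spike buffer overflow; raise spike_cap_hz")

    return SpikeRecord(times=out_t[:n_out].copy(),
                       neurons=out_id[:n_out].copy(),
                       table=graph.neuron_table(),
                       duration=config.duration, warmup=config.warmup,
                       meta={"seed": config.seed,
                             "dopamine": (config.dopamine.d1, config.dopamine.d2),
                             "pd_mode": config.pd_mode,
                             "drive": [vars(d) for d in drive]})


# --- experiment configurations -------------------------------------------

def experiment_tonic(graph, seed=0, duration=3500.0, dopamine=None, **kw):
    """All channels at the tonic 3 spikes/s drive."""
    cfg = SimulationConfig(duration=duration, seed=seed,
                           dopamine=dopamine or DopamineState(), **kw)
    return run(cfg, graph)


def experiment_phasic(graph, seed=0, duration=3500.0, phasic_channel=0,
                      dopamine=None, phasic_rate=10.0, **kw):
    """One channel driven at a fixed phasic rate, neighbours tonic."""
    drive = [tonic_spec() for _ in range(graph.spec.n_channels)]
    drive[phasic_channel] = EnsembleSpec(A=0.0, F_spon=phasic_rate)
    cfg = SimulationConfig(duration=duration, seed=seed, drive=drive,
                           dopamine=dopamine or DopamineState(), **kw)
    return run(cfg, graph)


def experiment_entrainment(graph, seed=0, duration=3500.0, phasic_channel=0,
                           f=25.0, A=6.0, dopamine=None, **kw):
    """Weak oscillatory drive at unchanged mean cortical rates.

    Every ensemble oscillates at frequency f with amplitude A; baselines are
    compensated so the clamped mean rate matches the static phasic/tonic
    means (10 and 3 spikes/s).
    """
    nch = graph.spec.n_channels
    drive = []
    for c in range(nch):
        mean = 10.0 if c == phasic_channel else 3.0
        drive.append(EnsembleSpec(A=A, f=f, phi=0.0,
                                  F_spon=compensated_fspon(A, mean)))
    cfg = SimulationConfig(duration=duration, seed=seed, drive=drive,
                           dopamine=dopamine or DopamineState(), **kw)
    return run(cfg, graph)


def experiment_sweep(graph, f_grid, trials=1, seed=0, duration=3500.0,
                     phasic_channel=0, phasic_amp=10.0, tonic_amp=3.0,
                     phasic_base=10.0, tonic_base=3.0, dopamine=None, **kw):
    """Oscillatory drive across a frequency grid.

    The phasic channel oscillates with amplitude ``phasic_amp`` around the
    10 spikes/s activation level, so the mean drive matches the static
    phasic experiment; tonic channels oscillate with ``tonic_amp`` around
    the 3 spikes/s base with random relative phases.  Yields
    (frequency, trial, SpikeRecord).
    """
    ss = np.random.SeedSequence(seed)
    for fi, fhz in enumerate(f_grid):
        for tr in range(trials):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            drive = []
            for c in range(graph.spec.n_channels):
                ph = c == phasic_channel
                amp = phasic_amp if ph else tonic_amp
                phi = 0.0 if ph else rng.uniform(0, 2 * np.pi)
                drive.append(EnsembleSpec(A=amp, f=fhz, phi=phi,
                                          F_spon=phasic_base if ph else tonic_base))
            cfg = SimulationConfig(
                duration=duration, dopamine=dopamine or DopamineState(),
                seed=int(child.generate_state(1)[0] % (2 ** 31)),
                drive=drive, **kw)
            yield fhz, tr, run(cfg, graph)


def experiment_pd(graph, seed=0, duration=3500.0, phasic_channel=0,
                  mode="rate_up_20", **kw):
    """Parkinsonian 'off' state: zero dopamine + potentiated cortical input."""
    drive = [tonic_spec() for _ in range(graph.spec.n_channels)]
    drive[phasic_channel] = phasic_static_spec()
    cfg = SimulationConfig(duration=duration, seed=seed, drive=drive,
                           dopamine=DopamineState(0.0, 0.0), pd_mode=mode, **kw)
    return run(cfg, graph)
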