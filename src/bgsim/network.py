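"""Instantiation of the three-channel basal-ganglia circuit.

Population sizes are rat-brain counts divided by a scale factor S (default
300, giving 9586 neurons); each nucleus is split into parallel "microscopic
channels" — the action-selection units tied to one cortical ensemble each.
Projections between nuclei are topographic (same channel only) except for
the diffuse STN efferents and the GPe/SNr local collaterals, which spread
uniformly over all channels.  Striatal lateral inhibition uses separate
within- and between-channel probabilities derived from a spherical-volume
model of the striatum, with a D1/D2 asymmetry factor W biasing inhibition
onto the direct pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ConfigurationError, PlasticityParams, network_tables, synapse_tables

POPULATIONS = ("MSN_D1", "MSN_D2", "FSI", "GPe", "STN", "SNr")

__all__ = [
    "NetworkSpec",
    "Projection",
    "NetworkGraph",
    "population_counts",
    "subtype_counts",
    "striatal_channel_radius",
    "apply_asymmetry",
    "build_graph",
]


@dataclass
class NetworkSpec:
    """Structural parameters of the circuit (defaults from shipped config)."""

    S: float = 300.0
    n_channels: int = 3
    W: float = 1.5
    tables: dict = field(default_factory=network_tables)

    def __post_init__(self):
        if self.S <= 0:
            raise ConfigurationError("scale divisor S must be positive")
        if not (0.0 <= self.W <= 2.0):
            raise ConfigurationError("W must lie in [0, 2]")


@dataclass
class Projection:
    """One source->target pathway as an explicit synapse-level edge list."""

    name: str
    src_pop: str                 # population name or 'Ctx'
    tgt_pop: str
    indptr: np.ndarray           # CSR over local source index
    targets: np.ndarray          # global neuron ids
    G: float                     # nS (G0 for plastic synapses)
    nmda_ratio: float
    delay_ms: float
    tau_ampa: float              # decay of AMPA (glut) or GABA_A (gaba)
    tau_nmda: float
    E: float
    receptor: str                # 'glut' | 'gaba'
    plasticity: PlasticityParams | None = None

    @property
    def n_edges(self) -> int:
        return int(self.targets.size)


@dataclass
class NetworkGraph:
    """The instantiated circuit handed to the simulation engine."""

    spec: NetworkSpec
    counts: dict
    pop_slices: dict             # pop -> (start, stop) in global neuron ids
    channel: np.ndarray          # per-neuron channel label
    subtype: np.ndarray          # per-neuron cell-type name
    projections: list
    gap_pairs: np.ndarray        # (n_pairs, 2) global FSI ids
    n_generators: int            # cortical generators per channel

    @property
    def n_neurons(self) -> int:
        return int(self.channel.size)

    def neurons_of(self, pop: str, channel: int | None = None) -> np.ndarray:
        s = self.pop_slices[pop]
        ids = np.arange(s[0], s[1])
        if channel is not None:
            ids = ids[self.channel[ids] == channel]
        return ids

    def neuron_table(self) -> pd.DataFrame:
        pop = np.empty(self.n_neurons, dtype=object)
        for name, (a, b) in self.pop_slices.items():
            pop[a:b] = name
        return pd.DataFrame({
            "neuron": np.arange(self.n_neurons),
            "population": pop,
            "subtype": self.subtype,
            "channel": self.channel,
        })

    def export_edges(self) -> pd.DataFrame:
        """Tabular edge list (source, target, projection, delay, G)."""
        frames = []
        for p in self.projections:
            src = np.repeat(np.arange(p.indptr.size - 1), np.diff(p.indptr))
            frames.append(pd.DataFrame({
                "source": src, "target": p.targets,
                "projection": p.name, "delay_ms": p.delay_ms, "G": p.G,
            }))
        return pd.concat(frames, ignore_index=True)


def _largest_remainder(total: int, fractions: dict) -> dict:
    """Apportion ``total`` into integer parts proportional to fractions."""
    names = list(fractions)
    raw = np.array([fractions[k] * total for k in names])
    base = np.floor(raw).astype(int)
    rem = raw - base
    for i in np.argsort(-rem)[: total - base.sum()]:
        base[i] += 1
    return dict(zip(names, (int(x) for x in base)))


def population_counts(spec: NetworkSpec) -> dict:
    """Integer neuron counts per population at scale S.

    The striatum is 99% medium spiny neurons (split equally into D1/D2) and
    1% fast-spiking interneurons.
    """
    t = spec.tables["counts"]
    msn = int(round(t["MSN"]["total"] * t["MSN"]["fraction"] / spec.S))
    fsi = int(round(t["FSI"]["total"] * t["FSI"]["fraction"] / spec.S))
    d1 = msn - msn // 2
    return {
        "MSN_D1": d1,
        "MSN_D2": msn - d1,
        "FSI": fsi,
        "GPe": int(round(t["GPe"]["total"] / spec.S)),
        "STN": int(round(t["STN"]["total"] / spec.S)),
        "SNr": int(round(t["SNr"]["total"] / spec.S)),
    }


def subtype_counts(spec: NetworkSpec, counts: dict | None = None) -> dict:
    """GPe and STN sub-type counts per channel.

    Largest-remainder apportionment at the nucleus level first (so e.g. the
    dominant GPe type gets round(ratio * N_nucleus) cells overall), then
    across channels.
    """
    counts = counts or population_counts(spec)
    out = {}
    nch = spec.n_channels
    for nuc in ("GPe", "STN"):
        per_type = _largest_remainder(counts[nuc], spec.tables["ratios"][nuc])
        split = {st: _largest_remainder(n, {c: 1 / nch for c in range(nch)})
                 for st, n in per_type.items()}
        out[nuc] = {c: {st: split[st][c] for st in per_type}
                    for c in range(nch)}
    return out


def striatal_channel_radius(spec: NetworkSpec) -> float:
    """Radius (um) of the spherical volume holding one striatal channel.

    N_ch = (N_MSN + N_FSI)/n_channels neurons occupy V = N_ch/84900 mm^3
    (the striatal packing density); R = (3V/4pi)^(1/3).
    """
    c = population_counts(spec)
    n_ch = (c["MSN_D1"] + c["MSN_D2"] + c["FSI"]) / spec.n_channels
    V = n_ch / spec.tables["striatal_density_per_mm3"]     # mm^3
    return float((3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0) * 1000.0)


def apply_asymmetry(spec: NetworkSpec) -> dict:
    """Striatal D1/D2 inhibition asymmetry: adjusted probabilities and
    conductance multipliers.

    P(D2->D1) = P_MSN-MSN * W and P(D1->D2) = P_MSN-MSN * (2-W), likewise
    for FSI targets; recurrent D1 collaterals are strengthened (x1.2) and
    D2->D1 weakened (x0.4) relative to the base MSN->MSN conductance.
    """
    P = spec.tables["probabilities"]
    A = spec.tables["asymmetry"]
    W = spec.W
    out = {"G_mult": {"D1-D1": A["G_D1_D1_mult"], "D2-D1": A["G_D2_D1_mult"],
                      "D1-D2": 1.0, "D2-D2": 1.0}}
    for loc in ("int", "ext"):
        pm, pf = P["MSN-MSN"][loc], P["FSI-MSN"][loc]
        probs = {
            "D2-D1": pm * W, "D1-D2": pm * (2 - W),
            "D1-D1": pm, "D2-D2": pm,
            "FSI-D1": pf * W, "FSI-D2": pf * (2 - W),
        }
        if any(v > 1.0 for v in probs.values()):
            raise ConfigurationError("asymmetry-adjusted probability exceeds 1")
        out[loc] = probs
    return out


def _sample_block(rng, src_ids, tgt_ids, p, exclude_self=False, chunk=512):
    """Bernoulli(p) edges between two id sets; returns (src, tgt) arrays."""
    if p <= 0 or src_ids.size == 0 or tgt_ids.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    srcs, tgts = [], []
    for lo in range(0, src_ids.size, chunk):
        sub = src_ids[lo:lo + chunk]
        mask = rng.random((sub.size, tgt_ids.size)) < p
        if exclude_self:
            eq = sub[:, None] == tgt_ids[None, :]
            mask &= ~eq
        si, ti = np.nonzero(mask)
        srcs.append(sub[si])
        tgts.append(tgt_ids[ti])
    return np.concatenate(srcs), np.concatenate(tgts)


def _to_csr(src_local, tgt, n_src):
    order = np.argsort(src_local, kind="stable")
    src_local, tgt = src_local[order], tgt[order]
    indptr = np.zeros(n_src + 1, dtype=np.int64)
    np.add.at(indptr, src_local + 1, 1)
    return np.cumsum(indptr), tgt.astype(np.int64)


def build_graph(spec: NetworkSpec, seed=None) -> NetworkGraph:
    """Sample the full synapse-level circuit graph.

    Deterministic under a fixed seed: every projection draws from its own
    seed stream spawned from the master seed.
    """
    counts = population_counts(spec)
    nch = spec.n_channels
    P = spec.tables["probabilities"]
    syn = synapse_tables()["projections"]
    asym = apply_asymmetry(spec)

    # --- neuron layout: population-major, channel-major, subtype-major
    pop_slices, channel_parts, subtype_parts = {}, [], []
    stypes = subtype_counts(spec, counts)
    start = 0
    for pop in POPULATIONS:
        n = counts[pop]
        per_ch = _largest_remainder(n, {c: 1 / nch for c in range(nch)})
        for c in range(nch):
            if pop in stypes:
                for st, k in stypes[pop][c].items():
                    channel_parts.append(np.full(k, c, dtype=np.int16))
                    subtype_parts.append(np.full(k, st, dtype=object))
            else:
                channel_parts.append(np.full(per_ch[c], c, dtype=np.int16))
                subtype_parts.append(np.full(per_ch[c], pop, dtype=object))
        pop_slices[pop] = (start, start + n)
        start += n
    channel = np.concatenate(channel_parts)
    subtype = np.concatenate(subtype_parts)
    n_total = start

    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(64))

    def ids(pop, ch=None):
        a, b = pop_slices[pop]
        out = np.arange(a, b)
        return out if ch is None else out[channel[a:b] == ch]

    ngen = spec.tables["generators_per_channel"]

    def gen_ids(ch):
        return np.arange(ch * ngen, (ch + 1) * ngen)

    projections: list[Projection] = []

    def mk_proj(name, src_pop, tgt_pop, cfg, prob, topology, G=None):
        rng = np.random.default_rng(next(streams))
        src_all, tgt_all = [], []
        n_src = nch * ngen if src_pop == "Ctx" else counts[src_pop]
        src_of = (gen_ids if src_pop == "Ctx" else (lambda c: ids(src_pop, c)))
        for cs in range(nch):
            for ct in range(nch):
                if topology == "topographic" and cs != ct:
                    continue
                p = prob(cs, ct) if callable(prob) else prob
                if topology == "striatal":
                    p = prob["int"] if cs == ct else prob["ext"]
                s, t = _sample_block(rng, src_of(cs), ids(tgt_pop, ct), p,
                                     exclude_self=(src_pop == tgt_pop))
                src_all.append(s)
                tgt_all.append(t)
        src = np.concatenate(src_all)
        tgt = np.concatenate(tgt_all)
        base = pop_slices[src_pop][0] if src_pop != "Ctx" else 0
        indptr, targets = _to_csr(src - base, tgt, n_src)
        plast = None
        if "plasticity" in cfg:
            pc = cfg["plasticity"]
            plast = PlasticityParams(U=pc["U"], tau_f=pc["tau_f"],
                                     tau_d=pc["tau_d"], mode=pc["mode"],
                                     tonic_rate=pc["tonic_rate"])
        projections.append(Projection(
            name=name, src_pop=src_pop, tgt_pop=tgt_pop,
            indptr=indptr, targets=targets,
            G=float(G if G is not None else cfg.get("G0", cfg["G"])),
            nmda_ratio=float(cfg.get("nmda_ratio", 0.0)),
            delay_ms=float(cfg["delay"]),
            tau_ampa=float(cfg.get("tau_ampa", cfg.get("tau", 1.0))),
            tau_nmda=float(cfg.get("tau_nmda", 100.0)),
            E=float(cfg["E"]), receptor=cfg["receptor"], plasticity=plast))

    # cortical afferents (topographic: ensemble i -> channel i)
    mk_proj("Ctx-MSN_D1", "Ctx", "MSN_D1", syn["Ctx-MSN_D1"], P["Ctx-MSN"], "topographic")
    mk_proj("Ctx-MSN_D2", "Ctx", "MSN_D2", syn["Ctx-MSN_D2"], P["Ctx-MSN"], "topographic")
    mk_proj("Ctx-FSI", "Ctx", "FSI", syn["Ctx-FSI"], P["Ctx-FSI"], "topographic")
    mk_proj("Ctx-STN", "Ctx", "STN", syn["Ctx-STN"], P["Ctx-STN"], "topographic")
    # striatal lateral inhibition with D1/D2 asymmetry
    base_msn = syn["MSN-MSN"]
    for sd, td in (("D1", "D1"), ("D1", "D2"), ("D2", "D1"), ("D2", "D2")):
        key = f"{sd}-{td}"
        prob = {"int": asym["int"][key], "ext": asym["ext"][key]}
        mk_proj(f"MSN_{sd}-MSN_{td}", f"MSN_{sd}", f"MSN_{td}", base_msn,
                prob, "striatal", G=base_msn["G"] * asym["G_mult"][key])
    for td in ("D1", "D2"):
        prob = {"int": asym["int"][f"FSI-{td}"], "ext": asym["ext"][f"FSI-{td}"]}
        mk_proj(f"FSI-MSN_{td}", "FSI", f"MSN_{td}", syn["FSI-MSN"], prob, "striatal")
    mk_proj("FSI-FSI", "FSI", "FSI", syn["FSI-FSI"], P["FSI-FSI"], "striatal")
    # projections between nuclei
    mk_proj("SD1-SNr", "MSN_D1", "SNr", syn["SD1-SNr"], P["SD1-SNr"], "topographic")
    mk_proj("SD2-GPe", "MSN_D2", "GPe", syn["SD2-GPe"], P["SD2-GPe"], "topographic")
    diffuse = set(spec.tables["diffuse"])
    for name in ("STN-SNr", "STN-GPe", "GPe-STN", "GPe-SNr", "GPe-GPe", "SNr-SNr"):
        src, tgt = name.split("-")
        topo = "diffuse" if name in diffuse else "topographic"
        mk_proj(name, src, tgt, syn[name], P[name], topo)

    # FSI-FSI gap junctions (within channel, unordered pairs)
    gj = spec.tables["gap_junctions"]
    rng = np.random.default_rng(next(streams))
    pairs = []
    for c in range(nch):
        f = ids("FSI", c)
        iu, ju = np.triu_indices(f.size, k=1)
        keep = rng.random(iu.size) < gj["probability"]
        pairs.append(np.column_stack([f[iu[keep]], f[ju[keep]]]))
    gap_pairs = np.concatenate(pairs) if pairs else np.empty((0, 2), np.int64)

    return NetworkGraph(spec=spec, counts=counts, pop_slices=pop_slices,
                        channel=channel, subtype=subtype,
                        projections=projections, gap_pairs=gap_pairs,
                        n_generators=ngen)
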