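"""Standard measurement protocols of the study's headline quantities.

Each function runs the model under the stated study conditions and returns
the measured quantity; they are shared by the acceptance machinery and the
examples so that every reported number comes from one code path.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import analysis as an
from .cortical_drive import EnsembleSpec, sample_events
from .engine import (experiment_entrainment, experiment_pd, experiment_phasic,
                     experiment_sweep, experiment_tonic)

__all__ = [
    "tonic_snr_rate",
    "phi_static",
    "phi_entrained",
    "sweep_spearman",
    "d2_over_d1_crossing",
    "neighbour_snr_reduction",
    "pd_rb_isi_stats",
    "te_surrogate_null",
]


def tonic_snr_rate(graph, seeds=(0, 1, 2), duration=3000.0):
    """Full-model tonic-mode SNr mean rate (spikes/s), averaged over seeds."""
    recs = [experiment_tonic(graph, seed=s, duration=duration) for s in seeds]
    return float(np.mean([r.mean_rate("SNr") for r in recs])), recs


def phi_static(graph, seeds, duration=3000.0, records=None):
    """STN phase synchrony under static drive: (phasic-channel, tonic-channel).

    One channel receives the fixed 10 spikes/s activation; Phi is computed
    per trial on the stimulated channel's STN and on a tonic neighbour, then
    averaged over trials.
    """
    records = records or [experiment_phasic(graph, seed=s, duration=duration)
                          for s in seeds]
    ph = [an.hilbert_synchrony(r, "STN", channel=0).Phi for r in records]
    to = [an.hilbert_synchrony(r, "STN", channel=1).Phi for r in records]
    return float(np.mean(ph)), float(np.mean(to)), records


def phi_entrained(graph, seeds, duration=3000.0, f=25.0, A=6.0):
    """Phasic-channel STN Phi under weak beta drive at unchanged mean rate."""
    vals = []
    for s in seeds:
        rec = experiment_entrainment(graph, seed=s, duration=duration, f=f, A=A)
        vals.append(an.hilbert_synchrony(rec, "STN", channel=0).Phi)
    return float(np.mean(vals))


def sweep_spearman(graph, f_grid, seed=0, duration=3000.0, trials=1):
    """Spearman rho between cortical frequency and phasic-channel SNr rate."""
    fr, rr = [], []
    for f, tr, rec in experiment_sweep(graph, f_grid, trials=trials,
                                       seed=seed, duration=duration):
        fr.append(f)
        rr.append(rec.mean_rate("SNr", channel=0))
    rho = spearmanr(fr, rr).statistic
    return float(rho), list(zip(fr, rr))


def d2_over_d1_crossing(graph, drives=(2, 6, 8, 10, 12, 14, 16, 20),
                        seed=7, duration=2500.0):
    """Cortical rate at which mean MSN_D2 first exceeds MSN_D1 (spikes/s).

    Measured at baseline dopamine by sweeping the fixed activation of one
    channel and interpolating the sign change of (D2 - D1).
    """
    diffs = []
    for d in drives:
        rec = experiment_phasic(graph, seed=seed, duration=duration,
                                phasic_rate=float(d))
        d1 = rec.mean_rate("MSN_D1", channel=0)
        d2 = rec.mean_rate("MSN_D2", channel=0)
        diffs.append(d2 - d1)
    drives = np.asarray(drives, dtype=float)
    diffs = np.asarray(diffs)
    for i in range(1, drives.size):
        if diffs[i - 1] < 0.0 <= diffs[i]:
            f = diffs[i - 1] / (diffs[i - 1] - diffs[i])
            return float(drives[i - 1] + f * (drives[i] - drives[i - 1])), \
                list(zip(drives, diffs))
    return float("nan"), list(zip(drives, diffs))


def neighbour_snr_reduction(tonic_records, phasic_records,
                            phasic_channel=0):
    """Percent reduction of neighbouring-channel SNr rate vs tonic baseline.

    Channel-matched: each neighbouring channel is compared against its own
    tonic-mode rate, which cancels the structural rate differences between
    channels of one finite-size graph realization.
    """
    nch = int(max(r.table["channel"].max() for r in tonic_records)) + 1
    others = [c for c in range(nch) if c != phasic_channel]
    ratios = []
    for c in others:
        base = np.mean([r.mean_rate("SNr", channel=c) for r in tonic_records])
        nb = np.mean([r.mean_rate("SNr", channel=c) for r in phasic_records])
        ratios.append(nb / base)
    return float(100.0 * (1.0 - np.mean(ratios)))


def pd_rb_isi_stats(graph, seeds=(40,), duration=3000.0, mode="rate_up_20"):
    """CV (percent) and AI of rebound-bursting STN cells in the PD 'off' state.

    One phasic channel, full dopamine depletion, potentiated cortical input;
    statistics averaged across the RB neurons of the stimulated channel.
    Also returns the mean CV of the non-RB types.
    """
    cvs, ais, cv_non = [], [], []
    for s in seeds:
        rec = experiment_pd(graph, seed=s, duration=duration, mode=mode)
        rb = an.population_isi_stats(rec, "STN", channel=0, subtype="STN_RB")
        cvs.append(rb["CV"])
        ais.append(rb["AI"])
        for st in ("STN_LLRS", "STN_NR"):
            other = an.population_isi_stats(rec, "STN", channel=0, subtype=st)
            if np.isfinite(other["CV"]):
                cv_non.append(other["CV"])
    return {"CV_percent": float(100.0 * np.mean(cvs)),
            "AI": float(np.mean(ais)),
            "CV_non_rb_percent": float(100.0 * np.mean(cv_non))}


TE_CONNECTIONS = [("Ctx", "MSN_D1"), ("Ctx", "MSN_D2"), ("Ctx", "FSI"),
                  ("Ctx", "STN"), ("MSN_D1", "SNr"), ("MSN_D2", "GPe"),
                  ("STN", "GPe"), ("GPe", "STN"), ("GPe", "SNr"),
                  ("STN", "SNr"), ("GPe", "GPe")]


def te_surrogate_null(graph, seed=0, duration=10500.0, n_estimates=100,
                      tau=3, max_samples=4000):
    """Mean transfer entropy across time-shuffled surrogate series.

    A 10-s tonic record is reduced to per-nucleus RC-filtered rate series
    (plus a sampled cortical-ensemble series); each estimate shuffles both
    series of a connection in time, destroying temporal structure.
    Negative estimator noise is clamped at zero (TE is non-negative by
    definition).  Silent populations are skipped.
    """
    rec = experiment_tonic(graph, seed=seed, duration=duration)
    series = {}
    for pop in ("MSN_D1", "MSN_D2", "FSI", "GPe", "STN", "SNr"):
        try:
            s = an.preprocess(rec, pop, channel=0, smooth_sigma=0.0)
            series[pop] = an.rc_filter(s.values)
        except an.EmptySelectionError:
            continue
    T = duration - rec.warmup
    ev = sample_events(EnsembleSpec(), T, seed=seed + 1)
    ctx = np.sum([np.histogram(e, bins=np.arange(0.0, T + 1.0, 1.0))[0]
                  for e in ev], axis=0).astype(float)
    series["Ctx"] = an.rc_filter(ctx - ctx.mean())
    pairs = [(a, b) for a, b in TE_CONNECTIONS if a in series and b in series]
    rng = np.random.default_rng(seed + 2)
    vals = []
    rep = 0
    while len(vals) < n_estimates:
        for a, b in pairs:
            xs = rng.permutation(series[a])
            ys = rng.permutation(series[b])
            te = an.transfer_entropy(xs, ys, tau=tau, max_samples=max_samples,
                                     seed=rep)
            vals.append(max(te, 0.0))
            if len(vals) >= n_estimates:
                break
        rep += 1
    return float(np.mean(vals))
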