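"""Numba inner loop of the network simulation.

``simulate_chunk`` advances the whole network by a block of steps.  All
randomness (membrane noise, cortical Poisson thinning) is pre-drawn by the
caller with a seeded numpy Generator and passed in as arrays, so the kernel
itself is purely deterministic.  Per step it: samples cortical generator
events, delivers delayed spikes into per-pathway receptor conductances
(with lazy per-edge short-term-plasticity updates), accumulates receptor
currents (NMDA under the magnesium block, all classes under their dopamine
gains), adds gap-junction and spontaneous currents, and applies the unified
two-recovery-variable Euler update (standard cell types run with the second
recovery variable inert: a2 = d2 = w2 = 0, w1 = 1).

Pathways are packed by the engine: logical projections sharing target
population, receptor kinetics, delay and plasticity mode are fused into one
conductance buffer with per-edge weights, and edge lists are CSR-indexed by
global source id (generator id for cortical pathways).
"""

import numpy as np
from numba import njit

ERR_OK = 0
ERR_NONFINITE = 1
ERR_OVERFLOW = 2

# --- ziggurat tables for the normal sampler (128 layers) -----------------


def _build_ziggurat():
    m1 = 2147483648.0
    dn = tn = 3.442619855899
    vn = 9.91256303526217e-3
    kn = np.zeros(128, dtype=np.int64)
    wn = np.zeros(128)
    fn = np.zeros(128)
    q = vn / np.exp(-0.5 * dn * dn)
    kn[0] = int((dn / q) * m1)
    kn[1] = 0
    wn[0] = q / m1
    wn[127] = dn / m1
    fn[0] = 1.0
    fn[127] = np.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = np.sqrt(-2.0 * np.log(vn / dn + np.exp(-0.5 * dn * dn)))
        kn[i + 1] = int((dn / tn) * m1)
        tn = dn
        fn[i] = np.exp(-0.5 * dn * dn)
        wn[i] = dn / m1
    return kn, wn, fn


_ZIG_KN, _ZIG_WN, _ZIG_FN = _build_ziggurat()
_U64_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _next_u64(state):
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & _U64_MASK
    x ^= x >> np.uint64(27)
    state[0] = x
    return (x * np.uint64(2685821657736338717)) & _U64_MASK


@njit(cache=True, inline="always")
def _uniform(state):
    return float(_next_u64(state) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True)
def _randn(state):
    """Marsaglia-Tsang ziggurat sample from the standard normal."""
    while True:
        u = _next_u64(state)
        hz = np.int64(u & np.uint64(0xFFFFFFFF))
        if hz >= 2147483648:
            hz -= 4294967296
        iz = hz & 127
        if abs(hz) < _ZIG_KN[iz]:
            return hz * _ZIG_WN[iz]
        # tail / wedge rejection
        if iz == 0:
            r = 3.442619855899
            while True:
                x = -np.log(_uniform(state)) / r
                y = -np.log(_uniform(state))
                if y + y >= x * x:
                    break
            return r + x if hz > 0 else -(r + x)
        x = hz * _ZIG_WN[iz]
        if (_ZIG_FN[iz] + _uniform(state) * (_ZIG_FN[iz - 1] - _ZIG_FN[iz])
                < np.exp(-0.5 * x * x)):
            return x


@njit(cache=True, fastmath=True)
def simulate_chunk(step0, n_chunk, dt,
                   # per-neuron parameters
                   vr, vt, vpeak, kk, a1, b1, cc, d1, a2, b2, d2, vr2, w1, w2,
                   heavi, sig_step, Ispon, Cinv, forced_p,
                   gain_a, gain_n, gain_g,
                   # per-neuron state (updated in place)
                   v, u1, u2,
                   # xorshift64* state for noise and Poisson thinning
                   rng_state,
                   # cortical generators
                   gen_channel, prob_step,
                   # packed pathways (parallel arrays)
                   pr_ctx, pr_ip_off, pr_ed_off, pr_delay,
                   pr_dec_a, pr_dec_n, pr_E, pr_gaba, pr_ratio,
                   pr_t0, pr_t1, pr_g_off, pr_plastic, pr_pl_off,
                   pr_U, pr_tauf, pr_taud,
                   indptr_all, targets_all, weights_all,
                   g_a_buf, g_n_buf,
                   pl_u, pl_x, pl_t,
                   # gap junctions
                   gap_i, gap_j, g_gap, tau_gap, v_gapst,
                   # ring buffers, output, scratch
                   ring_ids, ring_n, gring_ids, gring_n,
                   out_t, out_id, out_state, I, vth, vnw):
    N = v.size
    NG = gen_channel.size
    L = ring_n.size
    n_proj = pr_ctx.size
    n_out = out_state[0]
    cap = out_t.size

    for sc in range(n_chunk):
        step = step0 + sc
        cur = step % L
        ring_n[cur] = 0
        gring_n[cur] = 0

        # --- cortical generator events for this step
        for g in range(NG):
            if _uniform(rng_state) < prob_step[step, gen_channel[g]]:
                gring_ids[cur, gring_n[cur]] = g
                gring_n[cur] += 1

        # --- delayed spike delivery into receptor conductances
        t_now = step * dt
        for p in range(n_proj):
            lag = step - pr_delay[p]
            if lag < 0:
                continue
            slot = lag % L
            ip0 = pr_ip_off[p]
            ed0 = pr_ed_off[p]
            t0 = pr_t0[p]
            off = pr_g_off[p]
            plastic = pr_plastic[p] == 1
            is_ctx = pr_ctx[p] == 1
            ratio = pr_ratio[p]
            nsp = gring_n[slot] if is_ctx else ring_n[slot]
            for si in range(nsp):
                local = gring_ids[slot, si] if is_ctx else ring_ids[slot, si]
                e0 = indptr_all[ip0 + local]
                e1 = indptr_all[ip0 + local + 1]
                for e in range(e0, e1):
                    tgt = targets_all[ed0 + e]
                    w = weights_all[ed0 + e]
                    if plastic:
                        ei = pr_pl_off[p] + e
                        dtev = t_now - pl_t[ei]
                        U = pr_U[p]
                        if pr_tauf[p] > 0.0:
                            uu = U + (pl_u[ei] - U) * np.exp(-dtev / pr_tauf[p])
                        else:
                            uu = U
                        xx = 1.0 + (pl_x[ei] - 1.0) * np.exp(-dtev / pr_taud[p])
                        uu = uu + U * (1.0 - uu)
                        w = w * uu * xx
                        pl_x[ei] = xx * (1.0 - uu)
                        pl_u[ei] = uu
                        pl_t[ei] = t_now
                    gi = off + tgt - t0
                    g_a_buf[gi] += w
                    if ratio > 0.0:
                        g_n_buf[gi] += w * ratio

        # --- receptor currents (fused with conductance decay)
        for i in range(N):
            I[i] = Ispon[i]
        for p in range(n_proj):
            off = pr_g_off[p] - pr_t0[p]
            t0 = pr_t0[p]
            t1 = pr_t1[p]
            E = pr_E[p]
            da = pr_dec_a[p]
            dn = pr_dec_n[p]
            if pr_gaba[p] == 1:
                for i in range(t0, t1):
                    I[i] += gain_g[i] * g_a_buf[off + i] * (E - v[i])
                    g_a_buf[off + i] *= da
            elif pr_ratio[p] > 0.0:
                for i in range(t0, t1):
                    drive = E - v[i]
                    Bv = 1.0 / (1.0 + 0.28 * np.exp(-0.062 * v[i]))
                    I[i] += (gain_a[i] * g_a_buf[off + i]
                             + gain_n[i] * g_n_buf[off + i] * Bv) * drive
                    g_a_buf[off + i] *= da
                    g_n_buf[off + i] *= dn
            else:
                for i in range(t0, t1):
                    I[i] += gain_a[i] * g_a_buf[off + i] * (E - v[i])
                    g_a_buf[off + i] *= da

        # --- gap junctions
        for gidx in range(gap_i.size):
            i = gap_i[gidx]
            j = gap_j[gidx]
            vg = v_gapst[gidx]
            I[i] += g_gap * (vg - v[i])
            I[j] += g_gap * (vg - v[j])
            v_gapst[gidx] = vg + dt * (v[i] + v[j] - 2.0 * vg) / tau_gap

        # --- neuron update: noise fill, then branch-free integration...
        for i in range(N):
            if forced_p[i] < 0.0:
                vnw[i] = sig_step[i] * _randn(rng_state)
            else:
                vnw[i] = 0.0
        for i in range(N):
            vi = v[i]
            gate = 1.0
            if heavi[i] == 1 and vi >= vr2[i]:
                gate = 0.0
            dv = (kk[i] * (vi - vr[i]) * (vi - vt[i]) - u1[i] - w2[i] * u2[i]
                  + I[i]) * Cinv[i]
            vnw[i] = vi + dt * dv + vnw[i]
            u1[i] += dt * a1[i] * (b1[i] * (vi - vr[i]) - u1[i])
            u2[i] += dt * a2[i] * (gate * b2[i] * (vi - vr2[i]) - u2[i])
            U = 1.0 / (w1[i] * abs(u2[i]) + 1.0 / w1[i])
            vth[i] = vpeak[i] + U * u2[i]

        # ... then the (rare) spike/reset scan
        for i in range(N):
            if forced_p[i] >= 0.0:
                # population replaced by a Poisson process (calibration)
                v[i] = vr[i]
                u1[i] = 0.0
                u2[i] = 0.0
                if _uniform(rng_state) < forced_p[i]:
                    ring_ids[cur, ring_n[cur]] = i
                    ring_n[cur] += 1
                    if n_out >= cap:
                        return n_out, ERR_OVERFLOW, i, step
                    out_t[n_out] = (step + 1) * dt
                    out_id[n_out] = i
                    n_out += 1
                continue
            vn = vnw[i]
            if vn >= vth[i]:
                U = 1.0 / (w1[i] * abs(u2[i]) + 1.0 / w1[i])
                vn = cc[i] - U * u2[i]
                u1[i] += d1[i]
                u2[i] += d2[i]
                ring_ids[cur, ring_n[cur]] = i
                ring_n[cur] += 1
                if n_out >= cap:
                    return n_out, ERR_OVERFLOW, i, step
                out_t[n_out] = (step + 1) * dt
                out_id[n_out] = i
                n_out += 1
            elif not np.isfinite(vn):
                return n_out, ERR_NONFINITE, i, step
            v[i] = vn

    out_state[0] = n_out
    return n_out, ERR_OK, -1, -1
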