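"""Spectral, synchrony, ISI and information-flow estimators on fixtures."""

import numpy as np
import pytest
from scipy import stats

from bgsim import analysis as an


def poisson_trains(rate_hz, n_neurons, T_ms, seed=0):
    rng = np.random.default_rng(seed)
    return [np.sort(rng.uniform(0, T_ms, rng.poisson(rate_hz * T_ms / 1000)))
            for _ in range(n_neurons)]


class FakeRecord:
    """Minimal SpikeRecord stand-in built from explicit spike trains."""

    def __init__(self, trains, duration, warmup=0.0):
        self._trains = {i: np.asarray(t) for i, t in enumerate(trains)}
        self.duration = duration
        self.warmup = warmup

    def select(self, population=None, channel=None, subtype=None,
               tmin=None, tmax=None):
        tmin = self.warmup if tmin is None else tmin
        tmax = self.duration if tmax is None else tmax
        ts = np.concatenate(list(self._trains.values())) if self._trains \
            else np.empty(0)
        ids = np.concatenate([[i] * len(t) for i, t in self._trains.items()]) \
            if self._trains else np.empty(0)
        keep = (ts >= tmin) & (ts < tmax)
        return ts[keep], ids[keep]

    def spike_trains(self, population=None, channel=None, subtype=None,
                     tmin=None, tmax=None):
        tmin = self.warmup if tmin is None else tmin
        tmax = self.duration if tmax is None else tmax
        return {i: t[(t >= tmin) & (t < tmax)]
                for i, t in self._trains.items()}


class TestPreprocess:
    def test_mean_centred(self):
        rec = FakeRecord(poisson_trains(20, 5, 5000), 5000.0)
        s = an.preprocess(rec, smooth_sigma=3.0)
        assert abs(s.values.mean()) < 1e-9

    def test_single_spike_gives_gaussian_bump(self):
        rec = FakeRecord([[500.0]], 1000.0)
        s = an.preprocess(rec, smooth_sigma=3.0)
        x = s.values - s.values.min()
        assert abs(int(np.argmax(x)) - 500) <= 1

    def test_kernel_preserves_mass(self):
        # spikes kept away from the window edges (truncated kernel support)
        trains = [t[(t > 100) & (t < 2900)]
                  for t in poisson_trains(30, 3, 3000, seed=2)]
        rec = FakeRecord(trains, 3000.0)
        t, _ = rec.select()
        x = an.bin_spikes(t, 0, 3000.0)
        from scipy.ndimage import gaussian_filter1d
        sm = gaussian_filter1d(x, 3.0, mode="constant")
        assert sm.sum() == pytest.approx(x.sum(), rel=1e-9)

    def test_empty_selection_raises(self):
        rec = FakeRecord([], 1000.0)
        with pytest.raises(an.EmptySelectionError):
            an.preprocess(rec)


class TestMultitaper:
    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(0)
        s = an.RateSeries(rng.normal(size=4000))
        fr, pw = an.multitaper_spectrum(s)
        band = (fr > 0) & (fr <= 100)
        res = stats.linregress(fr[band], np.log(pw[band]))
        assert res.pvalue > 0.05

    def test_modulated_poisson_peak_located(self):
        rng = np.random.default_rng(1)
        t = np.arange(4000)
        lam = 0.05 * (1 + 0.8 * np.sin(2 * np.pi * 0.020 * t))
        x = (rng.random(4000) < lam).astype(float)
        s = an.RateSeries(x - x.mean())
        fr, pw = an.multitaper_spectrum(s)
        band = (fr > 5) & (fr < 80)
        assert fr[band][np.argmax(pw[band])] == pytest.approx(20.0, abs=1.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            an.multitaper_spectrum(an.RateSeries(np.zeros(500)))


class TestCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(2)
        x = an.RateSeries(rng.normal(size=3000))
        fr, C = an.coherence(x, x)
        assert np.allclose(C, 1.0)

    def test_independent_series_near_floor(self):
        rng = np.random.default_rng(3)
        x = an.RateSeries(rng.normal(size=8000))
        y = an.RateSeries(rng.normal(size=8000))
        _, C = an.coherence(x, y)
        assert np.median(C) < 0.2


class TestSynchrony:
    def test_identical_trains_fully_synchronous(self):
        base = poisson_trains(25, 1, 3000, seed=5)[0]
        rec = FakeRecord([base] * 8, 3000.0)
        assert an.hilbert_synchrony(rec).Phi == pytest.approx(1.0, abs=1e-6)

    def test_independent_trains_match_random_phasor_oracle(self):
        # Monte-Carlo of N random phasors predicts the incoherent floor
        N = 40
        rng = np.random.default_rng(7)
        mc = np.mean([np.abs(np.exp(1j * rng.uniform(0, 2 * np.pi, N)).mean())
                      for _ in range(4000)])
        rec = FakeRecord(poisson_trains(60, N, 8000, seed=8), 8000.0)
        phi = an.hilbert_synchrony(rec, smooth_sigma=10.0).Phi
        assert phi == pytest.approx(mc, abs=0.12)
        assert phi < 0.4

    def test_sparse_neurons_excluded(self):
        trains = poisson_trains(20, 4, 2000, seed=9) + [np.array([100.0])]
        res = an.hilbert_synchrony(FakeRecord(trains, 2000.0))
        assert res.n_excluded == 1
        assert 0.0 <= res.Phi <= 1.0


class TestIsiStats:
    def test_regular_train(self):
        st = an.isi_stats(np.arange(0.0, 1000.0, 20.0))
        assert st["CV"] == pytest.approx(0.0, abs=1e-12)
        assert st["AI"] == pytest.approx(1.0, abs=0.05)

    def test_poisson_cv_approaches_one(self):
        rng = np.random.default_rng(11)
        isi = rng.exponential(20.0, 20000)
        st = an.isi_stats(np.cumsum(isi))
        assert st["CV"] == pytest.approx(1.0, abs=0.05)

    def test_too_few_spikes_undefined(self):
        assert an.isi_stats(np.array([1.0, 2.0]))["defined"] is False


class TestXcorr:
    def test_shuffled_record_corrected_to_zero(self):
        rec = FakeRecord(poisson_trains(30, 10, 4000, seed=12), 4000.0)
        out = an.xcorr_with_surrogates(rec, n_shuffles=10, seed=0)
        assert abs(out["C_corrected"]) < 0.01

    def test_shared_oscillation_raises_correlation(self):
        rng = np.random.default_rng(13)
        t = np.arange(4000)
        res = []
        for amp in (0.0, 0.6):
            lam = 0.03 * (1 + amp * np.sin(2 * np.pi * t / 50.0))
            trains = [t[rng.random(4000) < lam] * 1.0 for _ in range(10)]
            rec = FakeRecord(trains, 4000.0)
            res.append(an.xcorr_with_surrogates(rec, n_shuffles=8,
                                                seed=1)["C_corrected"])
        assert res[1] > res[0] + 0.02


class TestTransferEntropy:
    def test_matches_gaussian_closed_form(self):
        x, y = an.make_te_fixture(coupling=0.5, delay=5, n=10000, seed=3)
        gt = an.gaussian_ar_te(x, y, 5)
        est = an.transfer_entropy(x, y, tau=5)
        assert est == pytest.approx(gt, rel=0.10)

    def test_independent_series_near_zero(self):
        x, _ = an.make_te_fixture(0.0, 5, 6000, seed=4)
        _, y = an.make_te_fixture(0.0, 5, 6000, seed=5)
        assert abs(an.transfer_entropy(x, y, tau=5)) < 0.01

    def test_estimator_consistency_with_sample_size(self):
        errs = []
        for n in (2500, 10000):
            x, y = an.make_te_fixture(0.5, 3, n, seed=6)
            gt = an.gaussian_ar_te(x, y, 3)
            est = an.transfer_entropy(x, y, tau=3, max_samples=n)
            errs.append(abs(est - gt))
        assert errs[1] < errs[0] + 0.005

    def test_delay_recovered_by_tau_scan(self):
        x, y = an.make_te_fixture(coupling=0.5, delay=5, n=8000, seed=7)
        tes = {tau: an.transfer_entropy(x, y, tau=tau) for tau in range(1, 10)}
        assert max(tes, key=tes.get) == 5

    def test_direction_reverses_with_swap(self):
        x, y = an.make_te_fixture(coupling=0.5, delay=4, n=8000, seed=8)
        assert an.transfer_entropy(x, y, tau=4) > \
            an.transfer_entropy(y, x, tau=4) + 0.02

    def test_fixture_zero_coupling_ground_truth(self):
        x, y = an.make_te_fixture(0.0, 4, 5000, seed=9)
        assert an.gaussian_ar_te(x, y, 4) == pytest.approx(0.0, abs=0.002)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            an.transfer_entropy(np.zeros(300), np.zeros(300), tau=5)


class TestPathwaysAndZscore:
    def test_uniform_te_gives_identical_scores(self):
        te = {f: {e: 1.0 for chain in an.PATHWAYS.values() for e in chain}
              for f in (5, 10, 20)}
        out = an.pathway_activation(te)
        for scores in out.values():
            assert len(set(scores.values())) == 1

    def test_dominating_frequency_normalizes_to_one(self):
        edges = [e for chain in an.PATHWAYS.values() for e in chain]
        te = {5: {e: 0.1 for e in edges}, 20: {e: 0.5 for e in edges}}
        out = an.pathway_activation(te)
        for scores in out.values():
            assert scores[20] == pytest.approx(1.0)
            assert scores[5] == pytest.approx(0.0)

    def test_flat_spectrum_zscore_near_zero(self):
        fr = np.linspace(0, 100, 200)
        assert abs(an.spectral_zscore(fr, np.ones(200), 20.0)) < 1e-9

    def test_delta_peak_large_positive_z(self):
        fr = np.linspace(0, 100, 200)
        pw = np.ones(200)
        pw[40] = 100.0
        assert an.spectral_zscore(fr, pw, fr[40]) > 5.0
        assert abs(an.spectral_zscore(fr, pw, fr[100])) < 1.0

    def test_rc_filter_form(self):
        y = an.rc_filter(np.ones(50), RC=2.0, dt=0.1)
        alpha = 0.1 / 2.1
        assert y[0] == pytest.approx(alpha)
        assert y[1] == pytest.approx(alpha + alpha * (1 - alpha))
        assert y[-1] == pytest.approx(1.0, abs=0.15)
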