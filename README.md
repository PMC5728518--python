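# bgsim

A spiking neural network model of the basal-ganglia (BG) canonical
circuit, built for studying how the frequency and phase of cortical
oscillations gate information flow through the direct, indirect and
hyper-direct BG pathways.

The package provides, for computational neuroscientists and systems
biologists:

* eight tuned phenomenological neuron models (quadratic
  integrate-and-fire with biophysically scaled parameters): striatal
  MSN_D1, MSN_D2 and FSI; GPe types A/B/C; STN rebound-bursting (RB),
  long-lasting-rebound (LLRS) and no-rebound (NR) cells; and SNr output
  neurons — the STN types carry a second recovery variable
  `du2/dt = a2(G·b2(v − v_r2) − u2)` for low-threshold calcium dynamics;
* conductance synapses (AMPA/NMDA/GABA_A) with axonal delays,
  Tsodyks–Markram short-term facilitation/depression
  (`u⁺ ← u⁺ + U(1−u⁺)`, release `u⁺x⁻`, `x⁻ ← x⁻(1−u⁺)`), NMDA magnesium
  block, FSI–FSI gap junctions and dopaminergic scaling of both intrinsic
  parameters and receptor currents;
* the three-channel topographic circuit (9586 neurons at scale S = 300)
  with diffuse STN efferents and pallidal/nigral collaterals, and the
  spherical-volume derivation of striatal lateral connectivity;
* oscillatory inhomogeneous-Poisson cortical drive
  `λ(t) = max(0, A cos(2πft + φ) + F_spon)`, with tonic (3 spikes/s),
  phasic (10 spikes/s) and Parkinsonian-'off' conventions;
* a fast deterministic simulation engine (numba) and the full analysis
  suite: multitaper spectra, coherence, Hilbert phase synchrony Φ,
  ISI statistics (CV and the asynchrony index mode/mean),
  surrogate-corrected cross-correlation, and transfer entropy with a
  Kraskov-style k-nearest-neighbour estimator;
* the staged firing-rate calibration protocols used to set the
  connectivity (`bgsim.calibration`).

See `docs/methods.md` for the model equations, parameter provenance,
numerical choices and known limitations.

## Worked example

```python
from bgsim import NetworkSpec, build_graph, experiment_phasic, experiment_tonic
from bgsim.analysis import hilbert_synchrony

graph = build_graph(NetworkSpec(), seed=1)        # 9586 neurons, 3 channels

tonic = experiment_tonic(graph, seed=5, duration=3000.0)
for pop in ("MSN_D1", "FSI", "STN", "GPe", "SNr"):
    print(f"{pop:7s} {tonic.mean_rate(pop):5.1f} spikes/s")

phasic = experiment_phasic(graph, seed=20, duration=3000.0)  # channel 0 at 10 sp/s
print("stimulated SNr :", round(phasic.mean_rate("SNr", channel=0), 2))
print("neighbour  SNr :", round(phasic.mean_rate("SNr", channel=1), 2))
print("STN synchrony  :", round(hilbert_synchrony(phasic, "STN", channel=0).Phi, 3))
```

prints (rates in spikes/s, averaged over the population after a 500 ms
warm-up):

```
MSN_D1    0.0 spikes/s
FSI      12.8 spikes/s
STN       8.6 spikes/s
GPe      31.8 spikes/s
SNr      25.3 spikes/s
stimulated SNr : 0.28
neighbour  SNr : 23.43
STN synchrony  : 0.273
```

The tonic mode sits at the calibrated operating point (MSNs nearly
silent, GPe ≈ 30, STN ≈ 10, SNr ≈ 25 spikes/s).  Driving one channel at a
fixed 10 spikes/s silences that channel's GPe and collapses its SNr
output to ~0 — the circuit's action-selection signature, releasing the
thalamic target of the stimulated channel from inhibition — while
neighbouring channels keep tonic-like output.

A thin CLI mirrors the experiments:

```
bgsim run --mode phasic --duration 3000 --seed 1 --out spikes.csv
bgsim sweep --fmin 1 --fmax 100 --step 5 --out sweep.csv
bgsim pd --mode rate_up_20 --out pd.csv
```

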