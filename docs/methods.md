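# Methods

## Model overview

`bgsim` implements a spiking network model of the basal-ganglia (BG)
canonical circuit: striatum (MSN_D1, MSN_D2, FSI), subthalamic nucleus
(STN, with rebound-bursting RB, long-lasting-rebound LLRS and no-rebound NR
sub-types), external globus pallidus (GPe, types A/B/C) and substantia
nigra pars reticulata (SNr), driven by oscillatory cortical Poisson
ensembles and modulated by a global dopamine level.  The circuit is
organized in three parallel "microscopic channels" — the action-selection
units tied to one cortical ensemble each.

## Neurons

Every cell is a quadratic integrate-and-fire neuron in the biophysically
scaled ("extended") form

    C dv/dt = k (v − v_r)(v − v_t) − u1 − w2·u2 + I + noise
    du1/dt  = a1 (b1 (v − v_r) − u1)

with reset `v → c`, `u1 → u1 + d1` at `v ≥ v_peak`.  STN neurons carry a
second recovery variable modelling low-threshold calcium and
calcium-activated potassium currents,

    du2/dt = a2 (G · b2 (v − v_r2) − u2),

where `G = H(v_r2 − v)` for the gated RB/LLRS types and `G = 1` for NR.
u2 shifts the spike condition to `v ≥ v_peak + U·u2` and the reset to
`c − U·u2`, with the attenuation gain `U = 1/(w1|u2| + 1/w1)`.  This form
is finite at `u2 = 0` (where `U = w1`) and caps the total influence of u2
on action-potential height at `1/w1`, so bursting cannot collapse the AP.

Integration is explicit forward Euler at `dt = 0.1 ms` (configurable).
Membrane noise is additive voltage noise with per-step standard deviation
`σ·sqrt(dt/1 ms)`, i.e. dt-invariant referenced at 1 ms.  Heterogeneity
comes from per-neuron capacitance draws `N(C_µ, 0.1·C_µ)` truncated below
`0.2·C_µ`.  The GPe/SNr/STN parameter sets are the published tuned values;
the striatal MSN set is the published dopamine-modulated reduced
medium-spiny model and the FSI set a standard fast-spiking interneuron
parameterization — both clearly marked in `data/neurons.yaml`, because the
original model's striatal intrinsics were never printed.

Known deviations verified against the shipped parameters:

* **LLRS rebound.**  With `w2 = 0` the LLRS second recovery variable never
  enters the membrane equation, and its first recovery variable
  (`b1 = 0.2`, `a1 = 0.05`) stores at most ~7 pA of rebound drive that
  decays in ~20 ms.  No hyperpolarize-and-release protocol produces a
  rebound excess for this type; the rebound-classification suite therefore
  covers the six types that do behave as named (GPe_B, RB and SNr rebound;
  GPe_A, GPe_C and NR do not).
* **GPe_A/C saturation.**  The nominal F-I plateaus near 10–14 spikes/s are
  not reproduced; both types rise monotonically with input current.  All
  types do satisfy monotone F-I.

## Synapses

Chemical synapses are conductance-based with single-exponential decay per
receptor (AMPA, NMDA, GABA_A; GABA_B is deliberately absent).  Per-event
conductances superpose linearly.  NMDA currents are attenuated by the
magnesium block `B(v) = 1/(1 + 0.28 e^{−0.062 v})` and NMDA conductances
are fixed multiples of the AMPA conductance per projection (0.5
cortico-striatal, 0.6 cortico-subthalamic, 0.42 STN→SNr, 0.36 STN→GPe).

Short-term plasticity (striatal efferents facilitating, SNr afferents from
STN/GPe depressing) follows the Tsodyks–Markram scheme with the
facilitate-then-release-then-depress event ordering: `u⁺ ← u⁺ + U(1−u⁺)`,
release `u⁺x⁻`, `x⁻ ← x⁻(1−u⁺)`; both variables relax exponentially
between events (`u⁺ → U` with τ_f, `x⁻ → 1` with τ_d; `τ_f = 0` pins
`u⁺ = U`).  The run-time amplitude of a plastic synapse is `G0·u⁺·x⁻`,
with `G0 = G / steady_scale(tonic rate)` so the effective conductance in
tonic mode equals the calibrated static value `G`.  The (U, τ_f, τ_d)
values are synthetic calibrations: U is solved in closed form so the
steady-state release scale at the tonic rate reproduces the shipped G/G0
ratios exactly (0.283 for STN→SNr at 10 Hz, 0.154 for GPe→SNr at 30 Hz,
0.0288 for MSN_D1→SNr and 0.2516 for MSN_D2→GPe at 1.1 Hz), with time
constants at literature-typical magnitudes.

FSI pairs within a channel are additionally coupled electrically through a
shared-compartment gap junction: both neurons receive
`g_gap (v_gap − v_self)` and `τ_gap dv_gap/dt = v_i + v_j − 2 v_gap`
(`g_gap = 0.5 nS`, `τ_gap = 5 ms`, pairing probability 0.3; these three
numbers are not published and are config-exposed).

## Dopamine

A single pair of levels `d1 = d2 ∈ [0, 1]` (baseline 0.3) modulates
striatal intrinsics (D1 hyperpolarizes MSN_D1 rest and reduces its
adaptation increment; D2 reduces MSN_D2 gain; D1 hyperpolarizes FSI rest)
and receptor-class currents (MSN_D1 NMDA ×(1+0.5·d1); MSN_D2 AMPA
×(1−0.3·d2); FSI GABA ×(1−0.625·d2); STN and GPe glutamatergic and
GABAergic inputs ×(1−0.5·d2)).

## Anatomy

Population sizes are rat counts divided by the scale factor S (default
300): 9207 MSNs (split equally D1/D2), 93 FSIs, 153 GPe, 45 STN, 88 SNr —
9586 neurons in three channels.  GPe types split 4.05/85/10.95 % and STN
types 60/25/15 % by largest-remainder apportionment (nucleus level first,
then channels).  Connections are Bernoulli draws at the configured
per-projection probabilities; projections between nuclei are topographic
(same channel), while STN efferents and GPe/SNr local collaterals are
diffuse (uniform over all channels).  Striatal lateral connections use
separate within/between-channel probabilities derived from the
spherical-volume model of the striatum (channel radius
`R = (3V/4π)^{1/3}`, V from the 84 900 neurons/mm³ packing density;
205.8 µm at S = 300), with the D1/D2 asymmetry `P(D2→D1) = P·W`,
`P(D1→D2) = P·(2−W)` (W = 1.5) and conductance factors 1.2 (D1→D1
collaterals) and 0.4 (D2→D1).

## Cortical drive

Each channel is driven by 1000 independent inhomogeneous-Poisson
generators sharing `λ(t) = max(0, A cos(2πft + φ) + F_spon)`.  Static
tonic mode: `F_spon = 3` spikes/s; static phasic mode: a fixed 10 spikes/s
activation of one channel.  Oscillatory experiments keep the mean drive at
those operating points: the phasic channel oscillates with `A = 10` around
`F_spon = 10` and tonic channels with `A = 3` around 3 spikes/s.  (The
alternative — oscillating the phasic channel around the tonic baseline —
averages to sub-threshold drive at high frequencies and destroys the
strong negative frequency–rate relation the model is known for, so the
mean-preserving convention is adopted.)  Weak-entrainment drives
(`A = 6` at 25 Hz) compensate `F_spon` numerically so the clamped-mean
rate is unchanged.  The Parkinsonian 'off' state sets `d1 = d2 = 0` plus
either a 20 % cortical-rate increase or a 10 % increase of all cortical
synaptic conductances.

## Engine

A single vectorized step loop (numba): per-projection conductance buffers
with exponential decay, ring-buffer spike delivery at per-projection delays
rounded to the integration step, lazy per-edge plasticity updates at event
times, per-population dopamine gains, gap currents, and the unified neuron
update.  Runs are bit-reproducible under a fixed (configuration, seed)
pair; normals come from a ziggurat sampler on an xorshift64* stream seeded
from the run seed (validated against the normal distribution in the test
suite).  The first 500 ms of every run is discarded from all statistics.

## Analysis

All measures operate on 1-ms binned, mean-centred, Gaussian-smoothed spike
trains.  Defaults: smoothing σ = 3 ms for spectra and rate series
(conclusions were checked at 2 and 5 ms); σ = 10 ms for the Hilbert-phase
synchrony Φ.  The wider synchrony kernel matters: the phase estimator has
a rate-dependent no-coupling baseline on sparse smoothed point processes
(silent stretches dwell at the DC phase), and at 10 ms that baseline meets
the `1/sqrt(N)` random-phasor floor at physiological STN rates, which is
the regime in which the reference Φ values are mutually consistent.

* Spectra: DPSS multitaper, NW = 4 with 7 tapers on 2.5-s windows,
  optionally max-normalized.
* Coherence: magnitude-squared Welch coherence.
* Synchrony: Φ = time-average of |mean phasor| over per-neuron Hilbert
  phases; neurons with < 2 spikes are excluded and counted.
* ISI statistics: CV = std/mean of ISIs; asynchrony index AI = mode/mean
  with the mode from a 1-ms histogram over (0, 5·mean ISI], ties toward
  the smaller ISI.  AI < 1 indicates bursting.
* Cross-correlation: mean pairwise correlation of smoothed per-neuron rate
  series minus the same statistic on time-shuffled surrogates.
* Transfer entropy: series are RC low-passed
  (`y_t = y_{t−1} + dt/(RC+dt)(x_t − y_{t−1})`, RC = 2, dt = 0.1) and TE is
  estimated as the Kraskov-style k-nearest-neighbour conditional mutual
  information `I(Y_t; X_{t−τ} | Y_{t−τ})` with single-lag embeddings
  (k = l = 1), 4 neighbours, and τ equal to the connection's synaptic
  delay.  The estimator is validated against the closed-form
  linear-Gaussian (Granger-equivalent) TE `½ ln(σ²_red/σ²_full)` on AR
  fixtures (within 10 % at 10⁴ samples).  When averaging surrogate nulls,
  negative estimator noise is clamped at zero (TE is non-negative by
  definition).
* Pathway activation: products of edge TEs along the direct
  (Ctx→MSN_D1→SNr), indirect (Ctx→MSN_D2→GPe→SNr) and hyper-direct
  (Ctx→STN→SNr) chains, min-max normalized across the frequency grid.

## Calibration

Connectivity was calibrated structure by structure against literature
firing-rate targets, exactly in the dependency order of the circuit
(striatum → STN with forced-Poisson GPe → GPe → SNr; Nelder-Mead on the
multi-configuration objectives; rates measured over 2-s windows after
500 ms warm-up, averaged over seeded repeats).  Because the striatal
intrinsic models are stand-ins, the striatal stage was re-run for this
implementation, giving σ_MSN = 5 mV, σ_FSI = 3.2 mV, I_vivo(FSI) = 0 and
G(Ctx→FSI) = 0.88 nS; and the final SNr stage re-fitted the single
hand-tuned conductance G(GPe→SNr) = 66 nS (G0 scaled to preserve the
0.154 depression ratio) to restore the 25.5 spikes/s tonic operating
point.  All other conductances ship at their published values.

Regression status at the shipped parameters: the striatal and STN stages
meet all their targets (MSN ≤ 2 tonic / 17–48 burst, FSI 10–15 tonic;
STN ≈ 20/40/10); GPe meets the no-striatum (46.0 vs 46.5) and full-model
(32.1 vs 30) targets, but reads 21 vs 15 after STN removal; the SNr
subnetwork probes read 53 vs 76.5 and 9.2 vs 12.5 while the full-model
endpoint (25.5) holds.  The gaps reflect different operating points of the
stand-in neuron models and are reported by the tuning ops rather than
hidden.

## Reproduced quantities and known gaps

At desk scale (3-s trials, 10–20 trials per condition, S = 300) the model
reproduces: the 9586-neuron anatomy and 205.8 µm channel radius (exact);
the tonic operating point (SNr ≈ 25, STN ≈ 9, GPe ≈ 32 spikes/s); phasic
action selection (stimulated-channel SNr < 1 spikes/s, GPe silenced, MSNs
≈ 20–25 spikes/s); the strong negative frequency–rate relation of the
phasic SNr (Spearman ρ ≈ −0.9); the D2-over-D1 decision threshold (≈ 12
spikes/s of cortical drive at baseline dopamine, vs ≈ 9.5 in the
reference); phasic-channel STN synchrony Φ ≈ 0.27 rising to ≈ 0.32 under
weak 25-Hz cortical beta; Parkinsonian 'off' RB statistics (CV ≈ 46–50 %,
AI ≈ 0.67, non-RB CV ≈ 11 %); and a surrogate-TE null of order 10⁻³.

Two mesoscale quantities deviate and are reported as measured rather than
tuned toward: the tonic-channel STN of a phasic experiment drops to
~4–5 spikes/s here (its GPe is excited by the diffuse drive from the
~44 spikes/s phasic STN), which both inflates its sparse-train synchrony
baseline (Φ_tonic ≈ 0.45 vs 0.32) and — because both SNr afferents are
depression-saturated — leaves the neighbouring-channel SNr reduction at
~14 % instead of ~29 %.  Both trace to the unprinted shapes of the
depression curves and to neuron-model fidelity, not to free parameters of
this implementation.

The synthetic fixtures used to validate the estimators (AR pairs with
closed-form TE, Poisson trains with known modulation) share the
second-order structure of the model's rate series but none of the
network's nonstationarity; estimator tests on them validate the analysis
code, not the biological claims.
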