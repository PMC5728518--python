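# Anatomy of the three-channel canonical circuit: absolute population sizes
# (rat counts divided by the scale factor S), cell-type ratios, and pairwise
# Bernoulli connection probabilities.
schema_version: 1
scale: 300
n_channels: 3
counts:                       # absolute rat counts; divide by scale
  MSN: {total: 2790000, fraction: 0.99}
  FSI: {total: 2790000, fraction: 0.01}
  GPe: {total: 46000}
  STN: {total: 13600}
  SNr: {total: 26300}
generators_per_channel: 1000
ratios:
  GPe: {GPe_A: 0.0405, GPe_B: 0.85, GPe_C: 0.1095}
  STN: {STN_RB: 0.6, STN_LLRS: 0.25, STN_NR: 0.15}
striatal_density_per_mm3: 84900
probabilities:
  Ctx-MSN: 0.084
  Ctx-FSI: 0.084
  Ctx-STN: 0.03
  SD1-SNr: 0.033
  SD2-GPe: 0.033
  STN-SNr: 0.3
  STN-GPe: 0.3
  GPe-STN: 0.1
  GPe-SNr: 0.1066
  GPe-GPe: 0.1
  SNr-SNr: 0.1           # assumed collateral probability (kept as given)
  MSN-MSN: {int: 0.0718, ext: 0.0082}
  FSI-MSN: {int: 0.2925, ext: 0.0314}
  FSI-FSI: {int: 0.5864, ext: 0.0092}
asymmetry:
  W: 1.5                 # D2->D1 inhibition trade-off
  G_D1_D1_mult: 1.2      # recurrent D1 collaterals vs base MSN->MSN G
  G_D2_D1_mult: 0.4
diffuse:                 # projections spanning all channels
  - STN-GPe
  - STN-SNr
  - GPe-GPe
  - SNr-SNr
gap_junctions:           # FSI-FSI electrical coupling (within channel)
  probability: 0.3
  g_gap: 0.5             # nS
  tau_gap: 5.0           # ms
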