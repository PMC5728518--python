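# Chemical projections of the circuit: receptor kinetics, delays, maximum
# conductances, NMDA:AMPA multipliers and short-term-plasticity parameters.
#
# G is the tonic-steady-state (calibrated) conductance; for plastic synapses
# G0 is the un-depressed/un-facilitated initial conductance used at run time
# (amplitude G0*u*x), with G0 = G / steady_scale(tonic rate).
#
# Plasticity (U, tau_f, tau_d) values are synthetic calibrations: the cited
# source tables were not reproducible here, so U was solved in closed form so
# that the steady-state release scale at the tonic presynaptic rate equals
# the shipped G/G0 ratio, with literature-magnitude time constants.  tau_f: 0
# means the running utilization relaxes to U instantly (pure depression).
schema_version: 1
projections:
  Ctx-MSN_D1: {receptor: glut, G: 0.6, nmda_ratio: 0.5, delay: 10, tau_ampa: 6, tau_nmda: 160, E: 0.0, prob: Ctx-MSN, topology: topographic}
  Ctx-MSN_D2: {receptor: glut, G: 0.6, nmda_ratio: 0.5, delay: 10, tau_ampa: 6, tau_nmda: 160, E: 0.0, prob: Ctx-MSN, topology: topographic}
  # Ctx-FSI G calibrated (tune_striatum)
  Ctx-FSI: {receptor: glut, G: 0.88, nmda_ratio: 0.0, delay: 10, tau_ampa: 6, tau_nmda: 160, E: 0.0, prob: Ctx-FSI, topology: topographic}
  Ctx-STN: {receptor: glut, G: 0.388, nmda_ratio: 0.6, delay: 2.5, tau_ampa: 2, tau_nmda: 100, E: 0.0, prob: Ctx-STN, topology: topographic}
  STN-SNr:
    receptor: glut
    G: 14.0
    G0: 49.5
    nmda_ratio: 0.42
    delay: 1.5
    tau_ampa: 2
    tau_nmda: 100
    E: 0.0
    prob: STN-SNr
    topology: diffuse
    plasticity: {mode: depressing, U: 0.350637, tau_f: 0.0, tau_d: 227.0, tonic_rate: 10.0}
  STN-GPe: {receptor: glut, G: 1.447, nmda_ratio: 0.36, delay: 2, tau_ampa: 2, tau_nmda: 100, E: 0.0, prob: STN-GPe, topology: diffuse}
  SD1-SNr:
    receptor: gaba
    G: 4.5
    G0: 156.3
    delay: 4
    tau: 5.2
    E: -80.0
    prob: SD1-SNr
    topology: topographic
    plasticity: {mode: facilitating, U: 0.012710, tau_f: 623.0, tau_d: 559.0, tonic_rate: 1.1}
  SD2-GPe:
    receptor: gaba
    G: 5.435
    G0: 21.6
    delay: 5
    tau: 6
    E: -65.0
    prob: SD2-GPe
    topology: topographic
    plasticity: {mode: facilitating, U: 0.134775, tau_f: 150.0, tau_d: 77.0, tonic_rate: 1.1}
  GPe-STN: {receptor: gaba, G: 0.518, delay: 4, tau: 8, E: -84.0, prob: GPe-STN, topology: topographic}
  GPe-SNr:
    receptor: gaba
    G: 66.0          # calibrated (tune_snr final stage; G/G0 ratio preserved)
    G0: 428.57
    delay: 3
    tau: 2.1
    E: -80.0
    prob: GPe-SNr
    topology: topographic
    plasticity: {mode: depressing, U: 0.195592, tau_f: 0.0, tau_d: 138.0, tonic_rate: 30.0}
  GPe-GPe: {receptor: gaba, G: 0.765, delay: 1, tau: 5, E: -65.0, prob: GPe-GPe, topology: diffuse}
  SNr-SNr: {receptor: gaba, G: 0.2, delay: 1, tau: 3, E: -80.0, prob: SNr-SNr, topology: diffuse}
  MSN-MSN: {receptor: gaba, G: 0.75, delay: 1, tau: 4, E: -60.0, prob: MSN-MSN, topology: striatal}
  FSI-MSN: {receptor: gaba, G: 3.75, delay: 1, tau: 4, E: -60.0, prob: FSI-MSN, topology: striatal}
  FSI-FSI: {receptor: gaba, G: 1.1, delay: 1, tau: 4, E: -60.0, prob: FSI-FSI, topology: striatal}
nmda_block: {scale: 0.28, slope: 0.062}   # B(v) = 1/(1 + 0.28*exp(-0.062 v))
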