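# Intrinsic parameters of the eight basal-ganglia cell models.
#
# GPe (types A/B/C), SNr and STN (RB/LLRS/NR) values are the published tuned
# parameter sets of the circuit model this package implements.  The striatal
# MSN and FSI sets are NOT part of that publication: the MSN parameters are
# the published dopamine-modulated reduced (Izhikevich-form) medium-spiny
# model of Humphries et al. (2009) and the FSI set is the standard
# fast-spiking-interneuron parameterization of the same model family.  Their
# noise sigma, spontaneous currents and cortical conductances are set by the
# staged firing-rate calibration shipped with this package (see
# bgsim.calibration and docs/methods.md).
#
# Units: C pF, potentials mV, a 1/ms, b nS, d pA, k pA/mV^2, sigma mV,
# currents pA.
schema_version: 1
standard:
  MSN_D1: &msn
    C_mu: 15.2
    k: 1.0
    v_r: -80.0
    v_t: -29.7
    v_peak: 40.0
    a: 0.01
    b: -20.0
    c: -55.0
    d: 91.0
    sigma: 5.0       # calibrated (tune_striatum)
    I_vitro: 0.0
    I_vivo: 0.0
  MSN_D2: *msn
  FSI:
    C_mu: 80.0
    k: 1.0
    v_r: -70.0
    v_t: -50.0
    v_peak: 25.0
    a: 0.2
    b: 0.025
    c: -60.0
    d: 0.0
    sigma: 3.2       # calibrated (tune_striatum)
    I_vitro: 0.0
    I_vivo: 0.0
  GPe_A:
    C_mu: 70.0
    k: 0.06
    v_r: -50.7
    v_t: -42.0
    v_peak: 38.0
    a: 0.29
    b: 4.26
    c: -57.4
    d: 110.0
    sigma: 3.0
    I_vitro: 107.0
    I_vivo: 167.0
  GPe_B:
    C_mu: 68.0
    k: 0.943
    v_r: -53.0
    v_t: -44.0
    v_peak: 25.0
    a: 0.0045
    b: 3.895
    c: -58.36
    d: 0.353
    sigma: 3.0
    I_vitro: 52.0
    I_vivo: 64.0
  GPe_C:
    C_mu: 65.0
    k: 0.099
    v_r: -54.0
    v_t: -43.0
    v_peak: 34.5
    a: 0.42
    b: 7.0
    c: -52.0
    d: 166.0
    sigma: 3.0
    I_vitro: 187.5
    I_vivo: 237.5
  SNr:
    C_mu: 200.0
    k: 0.7836
    v_r: -64.58
    v_t: -51.8
    v_peak: 9.8
    a: 0.113
    b: 11.057
    c: -62.7
    d: 138.4
    sigma: 5.0
    I_vitro: 150.0
    I_vivo: 235.0
stn:
  STN_RB:
    C_mu: 23.0
    k: 0.439
    v_r: -56.2
    v_t: -41.4
    v_peak: 15.4
    c: -47.7
    a1: 0.021
    b1: 4.0
    d1: 17.1
    a2: 0.123
    b2: 0.015
    d2: -68.4
    v_r2: -60.0
    w1: 0.1
    w2: 0.0
    gating: heaviside
    sigma: 0.5
    I_vitro: 56.1
    I_vivo: 56.1
  STN_LLRS:
    C_mu: 40.0
    k: 0.3
    v_r: -56.2
    v_t: -50.0
    v_peak: 15.4
    c: -60.0
    a1: 0.05
    b1: 0.2
    d1: 1.0
    a2: 0.001
    b2: 0.3
    d2: 10.0
    v_r2: -60.0
    w1: 0.01
    w2: 0.0
    gating: heaviside
    sigma: 0.5
    I_vitro: 25.0
    I_vivo: 8.0
  STN_NR:
    C_mu: 30.0
    k: 0.105
    v_r: -58.5
    v_t: -43.75
    v_peak: 15.4
    c: -52.34
    a1: 0.44
    b1: -1.35
    d1: 17.65
    a2: 0.32
    b2: 3.13
    d2: 92.0
    v_r2: -43.2
    w1: 0.001
    w2: 1.0
    gating: always_on
    sigma: 0.5
    I_vitro: -1.0
    I_vivo: -18.0
capacitance:
  rel_std: 0.1        # per-neuron C ~ N(C_mu, rel_std*C_mu)
  trunc_rel: 0.2      # redraw below trunc_rel*C_mu (strictly positive draw)
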