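# Dopaminergic modulation coefficients.
# Two receptor-family levels d1, d2 in [0,1] (equal in all shipped
# experiments; baseline 0.3).  Intrinsic-parameter effects apply to striatal
# cells only; receptor-current scalings apply per target population.
schema_version: 1
baseline: {d1: 0.3, d2: 0.3}
intrinsic:
  MSN_D1: {v_r_beta1: 0.0289, d_beta2: 0.331}
  MSN_D2: {k_beta1: 0.032}
  FSI: {v_r_beta1: 0.1}
currents:
  MSN_D1: {nmda_gain_beta3: 0.5}          # I_nmda * (1 + 0.5*d1)
  MSN_D2: {ampa_loss_beta2: 0.3}          # I_ampa * (1 - 0.3*d2)
  FSI: {gaba_loss_beta2: 0.625}           # I_gaba * (1 - 0.625*d2)
  STN: {glut_loss_beta1: 0.5, gaba_loss_beta2: 0.5}
  GPe: {glut_loss_beta1: 0.5, gaba_loss_beta2: 0.5}
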