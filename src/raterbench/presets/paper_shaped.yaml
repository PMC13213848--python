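# Study-shaped preset: a 38-subject (18 AD / 20 CN) reader study with one
# automated observer and two human readers.
#
# The latent separation d = 1.8125 puts a perfectly loaded observer at a
# population AUC of Phi(d/sqrt(2)) ~= 0.90; the radiologist loadings are
# chosen so their expected AUCs are ~= 0.71 and ~= 0.62.  The automated
# observer spreads its residual (non-AD) mass across the full differential
# with the largest share leaking to DLB and records no exact ties; the human
# readers concentrate nearly all mass on CN/AD, are overconfident on the
# logit scale, and record occasional exact top-two ties.
n_pos: 18
n_neg: 20
separation: 1.8125
seed: 0
observers:
  model:
    loading: 1.0
    link_intercept: -2.2
    link_slope: 1.0
    tie_propensity: 0.0
    rounding_decimals: 3
    leakage: {DLB: 0.21, BVFTD: 0.06, SD: 0.06, PNFA: 0.06, PSP: 0.06}
  radiologist1:
    loading: 0.431782
    link_intercept: -0.9
    link_slope: 2.4
    tie_propensity: 0.20
    rounding_decimals: 3
    leakage: {DLB: 0.005, BVFTD: 0.01, SD: 0.005, PNFA: 0.005, PSP: 0.005}
  radiologist2:
    loading: 0.238353
    link_intercept: -0.7
    link_slope: 2.8
    tie_propensity: 0.25
    rounding_decimals: 3
    leakage: {DLB: 0.005, BVFTD: 0.01, SD: 0.005, PNFA: 0.005, PSP: 0.005}
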