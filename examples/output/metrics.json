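{
  "burden_at_fold_age": 412.352,
  "c_exp": 1.04197,
  "c_part": 0.000100727,
  "converged": {
    "patch": false,
    "ppc": false,
    "ta": false,
    "wpc": false
  },
  "delta_c_fix": 5.33902e-06,
  "lam": 1.3595,
  "mu_alpha": 3.9272e-06,
  "n_stem": 7.67964,
  "ratio": 0.0530047,
  "rho": 0.00808983,
  "seed": 7,
  "truth": {
    "alpha": 4.44e-06,
    "lam": 1.3,
    "n_stem": 7,
    "rho": 0.007
  },
  "version": "0.1.0"
}
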