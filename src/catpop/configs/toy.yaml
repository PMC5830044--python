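# Small synthetic city used for smoke tests: all defaults, fast solve.
latitude: 45.0
dwellings: 2000
area_ha: 300
density_dependence:
  variant: calibrated
  juvenile_rule: sqrt_adult
solver:
  max_iter: 1200
  tol: 1.0e-9
seed: 0
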