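# Guelph, Ontario (2011 census inputs) with the case-study-adjusted
# carrying-capacity densities for unowned cats.
latitude: 43.55
dwellings: 52620
area_ha: 7885
freeroaming_density: 0.787
feral_density: 0.246
density_dependence:
  variant: calibrated
  juvenile_rule: sqrt_adult
sterilization_set: table1
solver:
  max_iter: 1200
  tol: 1.0e-9
sensitivity:
  method: finite-difference
  delta: 1.0e-3
seed: 0
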