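# Near-equatorial failure-mode demo (Honolulu-scale inputs): with an
# almost year-round breeding season the verbatim demography form has
# unbounded growth, so the run terminates with an explicit
# non-convergence diagnostic instead of an equilibrium.
latitude: 21.3
dwellings: 336000
area_ha: 15600
offspring_sterilization: false
solver:
  max_iter: 1200
  tol: 1.0e-9
seed: 0
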