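# Typical (median) population parameter values for the two apomorphine
# formulations, as reported by the source population-model publications.
#
# Units: clearance_apparent L/h, volume_apparent L, all rate constants h^-1,
# ec50 ng/mL, baseline_b0 and mcic UPDRS Part III points, bioavailability and
# emax dimensionless fractions.
pk:
  sc:
    clearance_apparent: 191.0
    volume_apparent: 153.0
    ka: 14.9
    bioavailability: 1.0
  sl:
    clearance_apparent: 80.7
    volume_apparent: 438.0
    ka: 6.58
    k12: 0.613
    k21: 0.0048
    bioavailability: 0.206
pd:
  ke0: 5.36
  ec50: 10.7
  baseline_b0: 24.3
  emax: 1.0
  hill_g: 3.0
  mcic: 3.25
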