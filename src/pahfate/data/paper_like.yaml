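# Shipped reference scenario for the simulators.
#
# Incubation: Antarctic-style SML/SSL bottle experiment — 13 PAHs
# spiked at 200 ng/L, duplicate bottles per condition, sampled at 0 and
# 24 h, lognormal measurement noise with CV 10 %.  Biodegradation
# constants are derived internally from the target rate pattern (fast
# HMW removal in the SML, LMW comparable between layers, HMW unchanged
# in the SSL).
#
# Community: 16 samples (2 layers x PA/FL fractions x PAH/control x 2
# replicates) at depth 30,000; Pseudoalteromonas enriched 8x (SML-PA)
# and 7x (SML-FL) in exposed arms, Colwellia 2.5x in SML-PA.
#
# Any key below overrides the shipped default.
incubation:
  noise_cv: 0.10
  replicates: 2
  spike_ng_L: 200.0
  k_wall_per_h: 0.0
community:
  depth: 30000
  replicates: 2
  dirichlet_concentration: 500.0
  n_taxa: 150
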