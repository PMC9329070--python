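# Default property table for the 13 quantified PAHs.
# n_rings counts fused rings (including the cyclopenta ring of fluorene
# and fluoranthene, as in the usual EPA nomenclature).  log_kow values
# are configurable literature defaults (Mackay, Shiu & Ma, Handbook of
# Physical-Chemical Properties and Environmental Fate for Organic
# Chemicals); every analysis accepts a user-supplied table overriding
# them.  Molecular weights in g/mol.
name,n_rings,log_kow,mw
fluorene,3,4.18,166.22
anthracene,3,4.54,178.23
phenanthrene,3,4.57,178.23
pyrene,4,5.18,202.25
fluoranthene,4,5.22,202.25
chrysene,4,5.86,228.29
benzo(a)anthracene,4,5.91,228.29
benzo(b)fluoranthene,5,5.80,252.31
benzo(k)fluoranthene,5,6.00,252.31
benzo(a)pyrene,5,6.04,252.31
"dibenzo(a,h)anthracene",5,6.75,278.35
"indeno(1,2,3-cd)pyrene",6,6.58,276.33
benzo(ghi)perylene,6,6.63,276.33
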