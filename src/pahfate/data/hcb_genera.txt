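# Curated list of hydrocarbonoclastic bacteria (HCB) genera.
# One genus per line; '#' starts a comment.  Matching against taxonomy
# is done at genus rank, case-insensitively, assuming that ASVs within
# a genus share hydrocarbon-degrading metabolism.
#
# Seed entries: cold-water marine genera repeatedly reported to grow on
# or degrade hydrocarbons (isolates, MAGs and enrichment cultures).
# Extend freely below the marker to match your own curation.
Sulfitobacter
Pseudoalteromonas
Psychrobacter
Colwellia
Glaciecola
Alteromonas
Thalassospira
# -- user extensions below this line --
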