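# Published partition of the 1,819 TE families by presence in the two
# Arabidopsis genomes (thaliana = "A", lyrata = "B" in pipeline terms).
status	n_families
shared	1447
unique_thaliana	26
unique_lyrata	345
absent	1
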