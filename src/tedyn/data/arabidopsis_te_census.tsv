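# Published genome-wide TE copy census for Arabidopsis thaliana (selfing)
# vs Arabidopsis lyrata (outcrossing), per TE class: copy number, copies
# per Mbp, and percent of genome sequence.  Regression fixture for the
# aggregation/normalization operations.
te_class	copies_thaliana	per_mbp_thaliana	pct_genome_thaliana	copies_lyrata	per_mbp_lyrata	pct_genome_lyrata
LTR	6784	56.9	6.9	18558	89.8	12.9
non-LTR	2243	18.8	1.2	6844	33.1	2.6
DNA	12631	106.0	6.7	40118	194.1	9.0
unknown	1198	10.1	0.2	4422	21.4	0.7
Total	22856	200.6	15.0	69942	343.4	25.2
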