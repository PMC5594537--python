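# Published census of homology-predicted miRNA gene families, genes, hits and
# TE-derived families across ten diploid Oryza species.
species	te_families	families	genes	hits	genes_per_family	paralogues_per_gene
O_barthii	58	157	375	643	2.38	1.71
O_brachyantha	7	28	94	161	3.35	1.71
O_glaberrima	52	143	339	682	2.37	2.01
O_glumaepatula	58	168	375	666	2.23	1.77
O_longistaminata	38	132	407	605	3.08	1.48
O_meridionalis	44	120	303	491	2.52	1.62
O_nivara	64	176	388	676	2.20	1.74
O_punctata	20	68	201	311	2.95	1.54
O_rufipogon	64	184	385	694	2.09	1.80
O_sativa_indica	56	173	394	784	2.27	1.98
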