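sample_id	mtdna_cn	heteroplasmy_count	contamination_flag	haplogroup_discordant_variants	numt_predicted_variants	min_base_coverage	mean_base_coverage
CLEAN1	80	5	False	0	0	400	1100
CLEAN2	120	0	False	1	1	350	900
CLEAN3	41	2	False	0	0	500	1200
LOWCN	35	1	False	0	0	400	1000
HIGHCOUNT	90	6	False	0	0	400	1000
CONTAM	90	2	True	0	0	400	1000
HAPLO	90	1	False	2	0	400	1000
NUMT	90	1	False	0	3	400	1000
LOWMIN	90	1	False	0	0	50	1000
LOWMEAN	90	1	False	0	0	400	450
MISSCN		1	False	0	0	400	1000
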