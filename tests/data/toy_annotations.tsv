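chrom	pos	nonunique_map_frac	multimap_cluster	excessive_depth	dust_score
1	100	1.0	False	False	0
1	200	1.0	False	False	0
1	300	1.0	False	False	0
1	400	1.0	False	False	0
1	500	1.0	False	False	0
1	600	1.0	False	False	65
1	700	0.5	False	False	65
1	800	0.5	True	True	65
1	900	1.0	False	False	0
1	1000	1.0	False	False	0
2	150	1.0	True	True	0
2	250	1.0	False	False	0
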