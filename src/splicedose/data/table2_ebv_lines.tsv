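line_id	band_present	gt_2304256	gt_12720270
50044	+	CC	GG
GM07056	+	CC	GG
GM10854	+	CC	GG
GM10846	+	CC	GG
GM10857	+	CC	GG
GM10851	+	CC	GG
GM11830	+	CC	GG
GM12004	+	CC	GG
GM12282	+	CC	GG
GM10836	+	CA	GG
GM10859	+	CA	GG
GM10864	+	CA	GG
51814	+	CA	GG
GM12145	+	CA	GG
GM11918	+	CA	GA
GM10835	+	CA	GA
GM12144	+	CA	GA
52173	+	CA	GA
GM12249	-	CA	AA
34702	-	AA	GG
GM12275	-	AA	GG
50772	-	AA	GG
51464	-	AA	GG
GM11882	-	AA	GG
52279	-	AA	GA
49888	-	AA	GA
GM07037	-	AA	GA
GM12154	-	AA	GA
GM12342	-	AA	AA
GM12234	-	AA	AA
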