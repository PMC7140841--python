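# Published per-gene carrier counts of potentially damaging mutations by tier,
# for the lethal cases, unselected cases, and the Finnish and Swedish
# population controls. Control counts are allele-count carrier estimates;
# the ALL row is the per-gene sum for controls and the distinct-individual
# count for cases.
cohort	gene	tier	carriers	n_total
lethal	ERCC3	TIER1	1	122
unselected	ERCC3	TIER1	0	60
finnish	ERCC3	TIER1	0	3307
swedish	ERCC3	TIER1	3	6192
lethal	RAD18	TIER1	1	122
unselected	RAD18	TIER1	0	60
finnish	RAD18	TIER1	0	3307
swedish	RAD18	TIER1	0	6192
lethal	ATM	TIER1	4	122
unselected	ATM	TIER1	0	60
finnish	ATM	TIER1	4	3307
swedish	ATM	TIER1	10	6192
lethal	FANCM	TIER1	2	122
unselected	FANCM	TIER1	0	60
finnish	FANCM	TIER1	89	3307
swedish	FANCM	TIER1	44	6192
lethal	NTHL1	TIER1	2	122
unselected	NTHL1	TIER1	0	60
finnish	NTHL1	TIER1	24	3307
swedish	NTHL1	TIER1	39	6192
lethal	CHEK2	TIER1	5	122
unselected	CHEK2	TIER1	0	60
finnish	CHEK2	TIER1	60	3307
swedish	CHEK2	TIER1	5	6192
lethal	ALL	TIER1	15	122
unselected	ALL	TIER1	0	60
finnish	ALL	TIER1	177	3307
swedish	ALL	TIER1	101	6192
lethal	MUTYH	TIER2	0	122
unselected	MUTYH	TIER2	1	60
finnish	MUTYH	TIER2	34	3307
swedish	MUTYH	TIER2	75	6192
lethal	ERCC3	TIER2	1	122
unselected	ERCC3	TIER2	1	60
finnish	ERCC3	TIER2	5	3307
swedish	ERCC3	TIER2	4	6192
lethal	HLTF	TIER2	1	122
unselected	HLTF	TIER2	0	60
finnish	HLTF	TIER2	20	3307
swedish	HLTF	TIER2	9	6192
lethal	POLL	TIER2	1	122
unselected	POLL	TIER2	0	60
finnish	POLL	TIER2	15	3307
swedish	POLL	TIER2	28	6192
lethal	MRE11A	TIER2	1	122
unselected	MRE11A	TIER2	0	60
finnish	MRE11A	TIER2	0	3307
swedish	MRE11A	TIER2	0	6192
lethal	ATM	TIER2	2	122
unselected	ATM	TIER2	0	60
finnish	ATM	TIER2	13	3307
swedish	ATM	TIER2	28	6192
lethal	RECQL	TIER2	1	122
unselected	RECQL	TIER2	0	60
finnish	RECQL	TIER2	0	3307
swedish	RECQL	TIER2	13	6192
lethal	FAN1	TIER2	1	122
unselected	FAN1	TIER2	0	60
finnish	FAN1	TIER2	2	3307
swedish	FAN1	TIER2	16	6192
lethal	NEIL1	TIER2	1	122
unselected	NEIL1	TIER2	0	60
finnish	NEIL1	TIER2	3	3307
swedish	NEIL1	TIER2	16	6192
lethal	POLG	TIER2	5	122
unselected	POLG	TIER2	0	60
finnish	POLG	TIER2	197	3307
swedish	POLG	TIER2	190	6192
lethal	TP53	TIER2	2	122
unselected	TP53	TIER2	0	60
finnish	TP53	TIER2	3	3307
swedish	TP53	TIER2	7	6192
lethal	BRCA1	TIER2	1	122
unselected	BRCA1	TIER2	0	60
finnish	BRCA1	TIER2	2	3307
swedish	BRCA1	TIER2	5	6192
lethal	RECQL5	TIER2	1	122
unselected	RECQL5	TIER2	0	60
finnish	RECQL5	TIER2	3	3307
swedish	RECQL5	TIER2	1	6192
lethal	CHEK2	TIER2	1	122
unselected	CHEK2	TIER2	1	60
finnish	CHEK2	TIER2	2	3307
swedish	CHEK2	TIER2	28	6192
lethal	ALL	TIER2	16	122
unselected	ALL	TIER2	3	60
finnish	ALL	TIER2	299	3307
swedish	ALL	TIER2	420	6192
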