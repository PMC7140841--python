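# Potentially damaging germline variants observed in the lethal prostate-cancer
# case cohort (n = 122), with their published annotations. Genomic coordinates
# are not part of the published record; variant identifiers are derived from
# gene / rsID / protein change. MAF values are kept in their typeset
# scientific-notation form. The domain column flags truncations disrupting a
# UniProt-reported protein domain (supplied for rows lacking ClinVar support).
# reported_tier is the published classification, kept for regression checks.
gene	rsid	type	ref	alt	protein_change	clinvar	cadd	revel	maf	domain	reported_tier
ATM	rs758081262	stopgain	C	T	Q852X	5	35	-	2.5 × 10−5	-	1
ATM	rs761486324	frameshift ins	-	TG	H1082fs	-	-	-	-	true	1
ATM	rs767099464	frameshift del	C	-	H1083fs	-	-	-	-	true	1
ATM	rs769142993	missense	G	C	A2524P	4	31	0.89	2.5 × 10−5	-	2
ATM	-	frameshift del	AGTAG	-	S2611fs	-	-	-	-	true	1
ATM	rs753961188	frameshift ins	-	T	L2885fs	5,4	-	-	4.2 × 10−5	-	1
ATM	rs376676328	missense	A	G	R2912G	3	29	0.88	3.0 × 10−4	-	2
BRCA1	rs41293459	missense	C	T	R1699Q	5,4,3	35	0.79	2.5 × 10−5	-	2
CHEK2	rs555607708	frameshift del	G	-	T367fs	5	-	-	1.8 × 10−3	-	1
CHEK2	rs137853007	missense	G	A	R145W	5,4	33	0.81	3.3 × 10−5	-	2
CHEK2	rs730881700	frameshift ins	-	T	E457fs	5,4	-	-	5.0 × 10−5	-	1
CHEK2	rs28909982	missense	T	C	R117G	5,4	27	0.93	1.0 × 10−4	-	2
ERCC3	rs753182861	frameshift del	T	-	Q586fs	-	-	-	2.0 × 10−4	true	1
ERCC3	rs145267069	missense	A	G	F297S	-	30	0.82	2.5 × 10−5	-	2
FAN1	rs778927800	missense	G	A	R749Q	-	34	0.89	8.3 × 10−6	-	2
FANCM	rs147021911	stopgain	C	T	Q1701X	4	35	0.12	1.3 × 10−3	-	1
HLTF	rs184046773	missense	C	T	G1886A	-	33	0.81	2.0 × 10−4	-	2
MRE11A	rs372000848	missense	G	A	R305W	4,3	33	0.85	5.0 × 10−5	-	2
MUTYH	rs34126013	missense	G	A	R238W	5,4	33	0.79	9.2 × 10−5	-	2
NEIL1	rs5745906	missense	G	A	G169D	-	27	0.86	1.3 × 10−3	-	2
NTHL1	rs150766139	stopgain	G	A	Q90X	5,3	35	-	1.5 × 10−3	-	1
POLG	rs761584617	missense	G	A	A1115V	-	23	0.80	2.5 × 10−5	-	2
POLG	rs113994097	missense	C	G	W748S	5,3	33	0.91	8.0 × 10−4	-	2
POLG	rs113994096	missense	G	A	P587L	5,3	28	0.80	1.7 × 10−3	-	2
POLG	rs121918052	missense	C	G	Q497H	5,3	26	0.71	2.0 × 10−4	-	2
POLL	rs139871590	missense	C	T	G356S	-	34	0.83	1.0 × 10−3	-	2
RAD18	rs138830303	stopgain	T	A	K197X	-	36	-	1.0 × 10−4	true	1
RECQL	rs149937760	missense	C	T	C414Y	-	33	0.84	2.0 × 10−4	-	2
RECQL5	rs768705080	missense	T	G	Y362S	-	32	0.76	8.2 × 10−6	-	2
TP53	rs876660754	missense	C	T	V173M	5,4	28	0.89	-	-	2
TP53	rs779000871	missense	G	A	T170M	3	24	0.87	8.2 × 10−5	-	2
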