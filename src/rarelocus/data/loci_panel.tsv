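locus	chrom	roi_kb	n_variants
CELSR2	1	36.464	254
GALNT2	1	4.530	67
GCKR	2	2.189	12
ABCG8	2	38.183	231
G6PC2	2	17.240	97
LPL	8	3.747	43
ABCA1	9	11.176	73
PANK1	10	3.684	12
CRY2	11	10.997	60
MADD	11	47.317	325
FADS1	11	9.273	43
MTNR1B	11	1.662	15
APOA1	11	5.057	55
MVK	12	6.093	54
LIPC	15	2.175	27
CETP	16	16.686	148
NCAN	19	55.570	336
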