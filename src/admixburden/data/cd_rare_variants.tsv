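# Allele frequencies and effects of 25 rare coding variants affecting Crohn's disease susceptibility,
# as printed in the source summary table (2 d.p. except where more digits were printed).
# aa_maf / eu_maf: gnomAD African / Non-Finnish European frequencies of the ascertained allele.
# ratio: aa_maf / eu_maf as printed. aa_or: odds ratio in the African American WGS cohort
# (not computed if MAF < 0.001); eu_or: odds ratio from the European discovery meta-analysis.
# *_ve_pct: percent variance explained 2p(1-p)(lnOR)^2 x 100; *_xs: excess cases per 100,000 at 1% prevalence.
# printed_rarity from the table footnotes: rare (0.01 < EU MAF < 0.05), very_rare (0.001 < EU MAF <= 0.01),
# ultra_rare (EU MAF <= 0.001); unannotated rows with EU MAF >= 0.05 are common.
gene	rsid	variant	direction	aa_maf	eu_maf	ratio	aa_or	eu_or	aa_ve_pct	eu_ve_pct	aa_xs	eu_xs	printed_rarity
HGFAC	rs16844401	R516H	risk	0.028	0.070	0.40	1.25	1.17	0.27	0.32	13	19	common
SLC39A8	rs13107325	A391T	risk	0.013	0.070	0.19	1.36	1.21	0.24	0.47	9	29	common
CCR7	rs2228015	M7V	risk	0.007	0.038	0.18	1.17	1.15	0.03	0.14	2	10	rare
DOK2	rs34215892	P274L	risk	0.005	0.032	0.16	1.18	1.25	0.03	0.31	2	14	rare
SDF2L1	rs73166641	R161H	risk	0.006	0.013	0.46	2.30	1.24	0.83	0.12	15	7	rare
NOD2	rs2066844	R702W	risk	0.009	0.045	0.20	1.36	2.07	0.17	4.55	6	77	rare
NOD2	rs2066845	G908R	risk	0.003	0.015	0.20	1.96	2.34	0.27	2.14	6	36	rare
NOD2	rs2066847	fs1007	risk	0.003	0.023	0.13	2.03	3.00	0.30	5.42	6	79	rare
NOD2	rs104895431	S431L	risk	0.0004	0.0019	0.21	0.46	1.74	0.05	0.12	0	3	very_rare
NOD2	rs104895438	A612T	risk	0.0000	0.0002	NA	NA	3.12	NA	0.05	0	1	ultra_rare
NOD2	rs5743277	R703C	risk	0.0008	0.0051	0.16	0.93	1.88	0.0008	0.40	1	9	very_rare
NOD2	rs61747625	A755V	risk	0.0007	0.0053	0.13	0.77	2.34	0.01	0.76	2	14	very_rare
NOD2	rs104895443	E778K	risk	0.0000	0.0004	NA	NA	3.03	NA	0.10	0	2	ultra_rare
NOD2	rs373550987	splice	risk	0.0000	0.00006	NA	NA	4.97	NA	0.03	0	1	ultra_rare
NOD2	rs104895467	N852S	risk	0.0001	0.0007	0.14	1.85	2.31	0.008	0.10	0	1	ultra_rare
RELA	rs61759893	D291N	risk	0.0011	0.006	0.18	0.69	1.46	0.03	0.17	1	5	very_rare
PTAFR	rs138629813	N114S	risk	0.0005	0.0038	0.13	0.93	1.70	0.0005	0.21	1	5	very_rare
PDLIM5	rs182339387	splice	risk	0.0007	0.004	0.18	0.93	1.61	0.0007	0.18	1	5	very_rare
IL10RA	rs56143179	P295L	risk	0.0001	0.0013	0.08	0.31	2.11	0.03	0.14	0	3	very_rare
IL23R	rs41313262	V362I	protective	0.003	0.015	0.20	0.54	0.70	0.23	0.38	3	8	rare
IL23R	rs11209026	R381Q	protective	0.013	0.07	0.19	0.64	0.49	0.51	6.63	9	61	common
TYK2	rs35018800	A928V	protective	0.001	0.008	0.13	2.32	0.60	0.14	0.41	1	6	very_rare
TYK2	rs34536443	P1104A	protective	0.009	0.044	0.21	1.22	0.72	0.07	0.91	0	21	rare
TAGAP	rs41267765	E147K	protective	0.006	0.022	0.27	0.81	0.79	0.05	0.24	2	9	rare
CARD9	rs141992399	splice	protective	0.001	0.006	0.17	NA	0.47	NA	0.68	0	6	very_rare
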