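# Variants at the Crohn's disease risk loci that are present in African Americans with
# evolutionary-probability (EP) scores in the range of known pathogenic mutations but nearly
# absent in Europeans. af_case / af_control: ascertained-allele frequency in African American
# WGS cases / controls; af_gnomad_afr: gnomAD African frequency.
gene	var_id	rsid	variant	ep_score	af_case	af_control	af_gnomad_afr
SDF2L1	22-21643930-G-A	rs61739341	D141N	0.001	0.018	0.016	0.017
PTAFR	1-28150202-C-T	rs140866472	A274T	0.002	0.012	0.011	0.013
PTAFR	1-28150940-G-A	rs116552042	L28F	0.004	0.0093	0.0061	0.007
PTGER4	5-40692215-G-A	rs138674524	R435Q	0.002	0.00057	0.0003	0.0008
SLC39A8	4-102263082-G-A	rs112519623	L449F	0.0008	0.0051	0.0015	0.003
IL10RA	11-117988495-C-G	rs4252250	L61V	0.005	0.041	0.044	0.045
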