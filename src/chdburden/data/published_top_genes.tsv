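gene	chrom	stratum	min_category	carriers_sCHD	carriers_nsCHD	carriers_control	p_min	p_bh_published	p_bonferroni_published	known_chd
KMT2A	11	sCHD	hcLOF	8	0	0	9.76E-13	3.19E-08	3.19E-08	yes
SMAD4	18	sCHD	missC	11	3	16	2.47E-10	4.04E-06	8.09E-06	yes
NOTCH1	9	nsCHD	hcLOF	2	7	0	8.48E-10	2.77E-05	2.77E-05	yes
PTPN11	12	sCHD	missC	11	5	25	8.78E-09	9.57E-05	2.87E-04	yes
TAB2	6	sCHD	hcLOF	5	1	0	3.13E-08	2.56E-04	1.02E-03	yes
NSD1	5	sCHD	hcLOF	5	1	1	1.83E-07	1.20E-03	5.98E-03	yes
BCOR	X	sCHD	hcLOF	4	0	0	9.93E-07	4.06E-03	3.25E-02	yes
KAT6A	8	sCHD	hcLOF	4	1	0	9.93E-07	4.06E-03	3.25E-02	yes
PBX1	1	sCHD	missC	6	3	6	7.73E-07	4.06E-03	2.53E-02	no
FLT4	5	nsCHD	hcLOF	0	5	0	3.32E-07	5.43E-03	1.09E-02	yes
CTCF	16	sCHD	missC	4	1	1	4.84E-06	1.58E-02	1.58E-01	yes
KAT6B	10	sCHD	hcLOF	4	1	1	4.84E-06	1.58E-02	1.58E-01	no
SHOX2	3	nsCHD	missC	1	10	21	1.81E-06	1.98E-02	5.93E-02	no
HCAR1	12	nsCHD	missC	2	9	18	4.40E-06	3.60E-02	1.44E-01	no
ADNP	20	sCHD	hcLOF	3	0	0	3.15E-05	6.44E-02	1.00E+00	yes
CHD7	8	sCHD	hcLOF	3	0	0	3.15E-05	6.44E-02	1.00E+00	yes
EP300	22	sCHD	hcLOF	3	1	0	3.15E-05	6.44E-02	1.00E+00	yes
KMT2D	12	sCHD	hcLOF	3	0	0	3.15E-05	6.44E-02	1.00E+00	yes
KRT25	17	sCHD	missC	8	3	31	2.51E-05	6.44E-02	8.19E-01	no
QRICH1	3	sCHD	hcLOF	3	0	0	3.15E-05	6.44E-02	1.00E+00	no
SLC38A9	5	nsCHD	missC	0	6	6	1.19E-05	7.78E-02	3.89E-01	no
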