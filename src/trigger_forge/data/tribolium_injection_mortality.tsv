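# Published injection-screen mortality for the 50 candidate lethal RNAi
# targets in Tribolium castaneum (150 nl of 250 ng/ul dsRNA, scored 14 days
# post injection; mean and SEM of three replicates), with the paired
# Diabrotica virgifera virgifera diet-overlay outcomes (500 ng/cm2, 9 days).
# dvv_selected marks dsRNAs with significant D. v. virgifera mortality.
gene	ncbi_id	beetlebase_id	tc_mortality_pct	tc_sem	dvv_dsrna	dvv_mortality_pct	dvv_sem	dvv_selected
Arp1	XM_964734.2	TC030579	100	0	Arp1-1	40.01	4.96	1
l(3)72Ab	XM_965461.1	TC031972	97.22	0	Brr2-1	54.90	9.81	1
cas	XM_962930.1	TC015935	88.89	0.8	Cas-1	27.06	3.36	0
Cchl	XM_961483.2	TC011725	100	0	CchI-1	9.22	1.47	0
Cdc27	XM_964716.1	TC006902	100	0	CchI-3	41.57	6.12	1
Cdc6	XM_001813172.1	TC013003	100	0	Cdc6-2	29.41	3.39	0
CG12104	XM_969426.1	TC012723	63.89	2.12	CG12104-1	29.41	11.00	0
CG1703	XM_966469.1	TC004420	77.78	1.6	CG1703-1	7.63	2.90	0
CG2063	XM_961444.1	TC003747	97.44	0.76	CG2063-1	22.16	4.51	0
CG2909	XM_965359.1	TC014931	100	0	CG2909-1	15.10	4.87	0
CG34184	XM_015981502.1	TC004760	100	0	CG34184-2	82.68	9.73	1
CG6843	XM_966328.2	TC012381	100	0	CG6843-1	52.08	1.70	1
Chc	XM_962736.1	TC015014	69.44	2.12	Chc-1	30.88	14.48	0
DCTN1-p150	XM_967301.2	TC012455	86.11	0.8	GI-1	29.69	5.17	0
dre4	XM_967384.1	TC014294	100	0	dre4-1	87.49	30.9	1
dUTPase	XM_968608.1	TC008662	100	0	dUTPase-1	53.99	10.97	1
fkh	NM_001039414.2	TC013245	100	0	fsh-1	49.17	6.45	1
gcm2	XM_970010.2	TC014730	100	0	gcm-1	19.12	4.41	0
Hsc70-3	XM_965476.2	TC004425	100	0	Hsc70-3-1	47.06	6.62	1
Keap1	XM_961255.1	TC016270	97.22	0	Kaep1-1	22.29	8.96	0
Klp61F	XM_965759.2	TC008263	94.44	0.8	Klp61F-1	51.89	6.09	1
mam	.	TC030619	94.44	0.8	mam-1	10.48	3.73	0
MED17	XM_964448.1	TC007640	93.33	0	iB-01233-363-53	48.82	2.94	0
mtRNApol	XM_962507.1	TC006188	52.78	1.6	mtRNApol-1	8.50	2.62	0
NAA15-16	XM_970509.1	TC008190	100	0	NAT1_1-1	47.06	5.88	1
ncm	XM_001811253.1	TC014785	100	0	ncm-1	83.45	5.62	1
Past1	XM_970194.1	TC033251	47.22	8.0	Past1-1	12.13	0.37	0
Picot	XM_961223.2	TC003405	77.78	12.73	Picot-1	14.71	2.94	0
Pka-R1-PP	XM_967511.2	TC000040	100	0	iB-00004-193-274	23.53	5.88	0
Prosalpha1-PA	XM_961880.2	TC000258	100	0	iB-00141-266-641	41.67	8.78	1
Prosalpha6-PA	XM_963762.1	TC000069	100	0	iB-00053-911-273	35.10	11.57	0
Prosbeta5	XM_965101.1	TC030625	100	0	Prosbeta5-1	44.12	14.71	0
Rab6	XM_967360.2	TC001600	83.33	3.21	Rab6-1	20.59	2.94	0
Rop	NM_001170684.1	TC011120	100	0	Rop-1	82.80	1.78	1
Rpb7	XM_965220.1	TC014109	100	0	Rpb7-1	76.72	3.07	1
RpII140	XM_969560	TC011771	88.89	0	RpII140-1	97.06	1.70	1
RpL6	XM_968022.2	TC030666	100	0	RpL6-1	29.41	5.88	0
Rpn11	XM_961333.2	TC005869	100	0	iB-00950-010-291	23.11	5.46	0
Rpn12	XM_966866.2	TC007891	100	0	iB-01280-690-586	38.24	7.78	1
Rpn7	XM_968550.1	TC006375	97.22	0	Rpn7-1	59.20	4.97	1
Rpt3	XM_962883.2	TC007999	100	0	Rpt3-1	46.11	3.49	1
Sam-S	XM_961585.2	TC011082	100	0	iB-01800-344-368	18.38	6.62	0
Sec.6	XM_965057.2	TC010557	100	0	sec.6-1	47.06	5.88	1
Sec.61alpha	XM_965057.2	TC010557	100	0	iB-07109-147-640	43.77	3.09	1
sif	XM_001815311.1	TC031145	100	0	sif-2	11.77	3.4	0
snRNP-U1-70K	XM_962210.2	TC002933	97.78	0	iB-00472-005-561	29.41	0.00	0
Spx	XM_963027.1	TC003731	83.33	0.8	Spx_NEW	20.59	8.83	0
su(f)	XM_967794.1	TC015727	91.67	1.6	su-f-1	17.65	5.89	0
Surf4-PA	XM_964082.2	TC000161	92.59	2.27	iB-000029-022-670	25.10	1.57	0
Tango6	XM_001814799.1	TC014300	88.89	1.6	Tango6-2	18.38	6.62	0
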