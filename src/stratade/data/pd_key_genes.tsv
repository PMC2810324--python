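gene	genbank_id	group	all_p01	male_p01	male_p05	female_p01	female_p05
TNFRSF1A	NM_001065	PCD_mitochondrial	0	0	0	1.25	1.26
PINK1	NM_032409	PCD_mitochondrial	-2.08	-1.85	-1.82	0	-2.55
SOD1	NM_000454	PCD_mitochondrial	-3.44	-3.44	-3.44	0	0
PARK7	NM_007262	PCD_mitochondrial	-7.14	-9.09	-8.37	0	0
NDUFA6	NM_002490	PCD_mitochondrial	-1.80	0	-2.19	-1.56	-2.07
NDUFB8	NM_005004	PCD_mitochondrial	-7.14	-5.55	-3.00	0	-10.96
CYP1A1	NM_000499	PCD_mitochondrial	1.2	0	0	1.36	1.36
CYP2C9	NM_000771	PCD_mitochondrial	0	1.23	1.23	0	0
APAF1	NM_181869	PCD_mitochondrial	1.35	1.41	1.40	0	0
GSTA4	NM_001512	PCD_mitochondrial	-1.38	-1.38	-1.38	0	0
SNCA	NM_007308	protein_degradation	-1.88	-2.12	-1.12	0	-1.84
PSMA7	NM_002792	protein_degradation	-1.72	0	0	-1.78	-1.77
HSP90AA1	NM_005348	protein_degradation	-2.70	-3.33	-3.46	0	0
HSPA8	NM_153201	protein_degradation	-2.77	-3.70	-1.35	0	0
LAMP1	NM_005561	protein_degradation	0	0	0	-12.50	-11.50
PPARD	NM_006238	protein_degradation	0	1.20	1.20	0	0
DRD1	NM_000794	receptors_channels	0	0	0	1.37	1.37
DRD2	NM_016574	receptors_channels	1.26	1.32	1.32	1.32	1.32
CHRNA4	NM_000744	receptors_channels	1.25	1.22	1.22	1.4	1.40
GABARAPL2	NM_007285	receptors_channels	-1.53	-1.51	-1.50	0	-1.54
GRIN2B	NM_000834	receptors_channels	1.27	1.27	1.27	0	1.25
TGFB2	NM_003238	receptors_channels	1.24	0	1.24	1.33	1.33
KCNN3	NM_170782	receptors_channels	0	0	0	-1.92	-1.91
SLC24A3	NM_020689	receptors_channels	0	-1.56	-1.55	0	0
SLC6A4	NM_001045	receptors_channels	0	0	0	1.33	1.33
CCK	NM_000729	receptors_channels	-1.23	-1.31	-1.30	0	0
CCKAR	NM_000730	receptors_channels	1.31	1.31	1.31	0	0
VDR	NM_001017535	receptors_channels	1.39	1.39	1.39	0	1.31
FYN	NM_153048	receptors_channels	-1.19	-1.19	-1.19	0	-1.92
RIPK2	NM_003821	receptors_channels	1.29	0	0	1.29	1.29
MAPT	NM_016841	other	-5	0	0	-5	-4.9
FTH1	NM_002032	other	-2.81	-2.77	-2.74	0	0
FTL	NM_000146	other	-1.88	-1.81	-1.80	0	0
PPP1R3A	NM_002711	other	1.25	1.24	1.24	0	0
PPP3CA	NM_000944	other	-2.56	-3.03	-2.94	0	0
ST13	NM_003932	other	-1.67	0	0	-1.64	-1.67
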