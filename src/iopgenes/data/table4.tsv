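gene	context	plier	dabg_avg	dabg_range
AFAP1	TM	33.64	0.08	0-0.58
AFAP1	CB	31.53	0.07	0-0.49
AFAP1	Cornea	30.54	0.14	0-0.77
ANGPTL2	TM	45.11	0.16	0-0.71
ANGPTL2	CB	30.32	0.19	0-0.8
ANGPTL2	Cornea	74.34	0.07	0-0.42
ANKH	TM	112.61	0.05	0-0.76
ANKH	CB	70.15	0.05	0-0.51
ANKH	Cornea	88.56	0.07	0-0.51
ANTXR1	TM	145.19	0.06	0-0.89
ANTXR1	CB	90.84	0.10	0-0.77
ANTXR1	Cornea	58.56	0.09	0-0.84
COL4A1	TM	46.71	0.08	0-0.92
COL4A1	CB	42.61	0.16	0-0.97
COL4A1	Cornea	24.59	0.24	0-0.98
COL8A2	TM	99.82	0.12	0-0.56
COL8A2	CB	86.39	0.14	0-0.52
COL8A2	Cornea	81.40	0.11	0-0.57
CPXM1	TM	26.48	0.11	0-0.58
CPXM1	CB	24.60	0.17	0-0.85
CPXM1	Cornea	26.29	0.10	0-0.32
EFEMP1	TM	214.28	0.01	0-0.11
EFEMP1	CB	667.78	0.03	0-0.35
EFEMP1	Cornea	165.29	0.04	0-0.52
ETS1	TM	86.82	0.07	0-0.76
ETS1	CB	41.16	0.08	0-0.51
ETS1	Cornea	27.07	0.05	0-0.35
GMDS	TM	76.23	0.06	0-0.20
GMDS	CB	88.91	0.19	0-0.78
GMDS	Cornea	93.19	0.06	0-0.16
HHEX	TM	92.41	0.14	0-0.64
HHEX	CB	63.12	0.20	0-0.54
HHEX	Cornea	95.97	0.23	0-0.95
HLA-DQA1	TM	NA	NA	NA
HLA-DQA1	CB	NA	NA	NA
HLA-DQA1	Cornea	NA	NA	NA
LTBP2	TM	79.44	0.06	0-0.66
LTBP2	CB	69.94	0.08	0-0.77
LTBP2	Cornea	62.10	0.08	0-0.53
MAFB	TM	54.38	0.19	0-0.93
MAFB	CB	62.34	0.17	0-0.82
MAFB	Cornea	77.52	0.09	0-0.50
ME3	TM	29.17	0.13	0-0.86
ME3	CB	36.24	0.17	0-0.52
ME3	Cornea	34.63	0.11	0-0.52
NR1H3	TM	32.84	0.18	0-0.72
NR1H3	CB	32.88	0.23	0-1.00
NR1H3	Cornea	33.11	0.16	0-0.57
PCSK5	TM	37.87	0.07	0-0.33
PCSK5	CB	31.31	0.17	0-0.81
PCSK5	Cornea	234.57	0.01	0-0.18
PRKAG2	TM	65.93	0.08	0-0.68
PRKAG2	CB	57.75	0.14	0-0.78
PRKAG2	Cornea	51.41	0.13	0-0.72
PRSS23	TM	76.78	0.06	0-0.34
PRSS23	CB	155.24	0.02	0-0.15
PRSS23	Cornea	121.46	0.04	0-0.28
PTPN1	TM	84.10	0.02	0-0.22
PTPN1	CB	61.15	0.06	0-0.62
PTPN1	Cornea	78.01	0.07	0-0.37
RPLP2P1	TM	NA	NA	NA
RPLP2P1	CB	NA	NA	NA
RPLP2P1	Cornea	NA	NA	NA
SEMA3E	TM	130.67	0.01	0-0.20
SEMA3E	CB	28.40	0.10	0-0.82
SEMA3E	Cornea	35.46	0.07	0-0.83
SH2B3	TM	40.00	0.15	0-0.99
SH2B3	CB	29.77	0.15	0-0.68
SH2B3	Cornea	37.72	0.12	0-0.5
TES	TM	290.39	0.01	0-0.11
TES	CB	67.06	0.07	0-0.27
TES	Cornea	193.21	0.01	0-0.08
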