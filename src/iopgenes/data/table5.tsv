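gene	context	fpkm
AFAP1	TM	3.10
AFAP1	CB	4.71
AFAP1	Cornea	2.46
ANGPTL2	TM	18.84
ANGPTL2	CB	15.75
ANGPTL2	Cornea	8.69
ANKH	TM	50.88
ANKH	CB	32.83
ANKH	Cornea	21.43
ANTXR1	TM	67.92
ANTXR1	CB	5.40
ANTXR1	Cornea	10.42
COL4A1	TM	9.15
COL4A1	CB	8.06
COL4A1	Cornea	0.73
COL8A2	TM	118.54
COL8A2	CB	33.40
COL8A2	Cornea	28.26
CPXM1	TM	6.63
CPXM1	CB	9.52
CPXM1	Cornea	0.22
EFEMP1	TM	142.27
EFEMP1	CB	153.01
EFEMP1	Cornea	77.16
ETS1	TM	16.18
ETS1	CB	1.85
ETS1	Cornea	3.56
GMDS	TM	81.59
GMDS	CB	55.42
GMDS	Cornea	89.55
HHEX	TM	2.25
HHEX	CB	0.53
HHEX	Cornea	0.48
HLA-DQA1	TM	31.13
HLA-DQA1	CB	4.11
HLA-DQA1	Cornea	9.36
LTBP2	TM	54.69
LTBP2	CB	142.61
LTBP2	Cornea	3.93
MAFB	TM	13.35
MAFB	CB	1.45
MAFB	Cornea	8.08
ME3	TM	7.26
ME3	CB	15.74
ME3	Cornea	5.42
NR1H3	TM	8.60
NR1H3	CB	19.88
NR1H3	Cornea	7.02
PCSK5	TM	5.04
PCSK5	CB	2.71
PCSK5	Cornea	21.57
PRKAG2	TM	16.79
PRKAG2	CB	2.30
PRKAG2	Cornea	16.08
PRSS23	TM	23.22
PRSS23	CB	8.20
PRSS23	Cornea	16.50
PTPN1	TM	16.16
PTPN1	CB	34.22
PTPN1	Cornea	17.24
RPLP2P1	TM	0.00
RPLP2P1	CB	0.00
RPLP2P1	Cornea	0.00
SEMA3E	TM	8.27
SEMA3E	CB	0.16
SEMA3E	Cornea	1.93
SH2B3	TM	4.54
SH2B3	CB	2.79
SH2B3	Cornea	1.28
TES	TM	56.81
TES	CB	0.81
TES	Cornea	30.17
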