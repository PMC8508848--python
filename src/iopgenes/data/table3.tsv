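gene	context	fpkm
AFAP1	SC	46.64
ANGPTL2	SC	30.90
ANKH	TM	64.41
ANTXR1	TM, SC	32.78, 47.13
COL4A1	SC	17.92
COL8A2	TM	34.44
CPXM1	SC	0.49
EFEMP1	TM	89.70
ETS1	SC	15.70
GMDS	TM	29.40
HHEX	SC	2.60
HLA-DQA1	TM	0.00
LTBP2	TM, SC	104.70, 171.74
MAFB	TM, SC	1.37, 1.79
ME3	SC	11.09
NR1H3	SC	4.45
PCSK5	SC	1.97
PRKAG2	SC	6.49
PRSS23	SC	184.92
PTPN1	SC	12.46
RPLP2P1	TM	0.00
SEMA3E	TM	1.51
SH2B3	SC	13.63
TES	SC	64.48
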