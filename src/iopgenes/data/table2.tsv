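gene	fold_change	p_value
AFAP1	1.56	1.35e-1
ANGPTL2	-3.33	6.73e-2
ANTXR1	-1.67	4.77e-2
COL4A1	2.84	1.43e-1
CPXM1	1.57	2.18e-2
ETS1	1.61	1.28e-1
HHEX	-1.62	1.81e-2
LTBP2	-1.63	1.56e-1
MAFB	-1.79	2.82e-1
ME3	-1.59	3.23e-3
NR1H3	-1.59	5.54e-2
PCSK5	-2.04	3.93e-2
PRKAG2	1.63	1.70e-2
PRSS23	-1.65	1.60e-1
PTPN1	1.63	1.63e-2
SH2B3	1.58	7.07e-3
TES	1.54	4.75e-2
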