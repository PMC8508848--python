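gene	fold_change	p_value
ANKH	2.69	3.16e-7
ANTXR1	1.79	6.46e-3
COL8A2	2.66	1.32e-4
EFEMP1	1.82	4.43e-3
GMDS	1.93	3.14e-3
HLA-DQA1	2.13	3.10e-3
LTBP2	2.25	1.65e-3
MAFB	1.54	1.22e-2
RPLP2	1.58	1.32e-1
SEMA3E	1.94	1.26e-5
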