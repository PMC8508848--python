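gene	fold_change	p_value
MCPH1	2.18	2.4e-2
MAFB	-2.12	1.9e-2
HGF	-2.52	3.1e-2
PCSK5	-2.75	3.2e-2
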