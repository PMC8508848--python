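label	nm	nm_sd	pg_per_ml	pg_per_ml_sd	n
Non-glaucomatous	0.14	0.05	37.90	14.80	4
Glaucomatous	0.13	0.03	34.46	7.08	4
Bovine	0.22	0.03	59.70	8.58	5
Porcine	0.55	0.62	149.44	168.21	4
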