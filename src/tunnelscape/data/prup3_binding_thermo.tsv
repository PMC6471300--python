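ligand	orientation	dG_kcal	dG_err	dH_kcal	dH_err	TdS_kcal	TdS_err
natural_ligand	A	-7.27	0.59	-18.63	0.68	-11.36	0.23
natural_ligand	B	-11.15	0.58	-23.03	0.49	-11.88	0.26
phytosphingosine	A	-10.20	0.41	-21.73	0.38	11.53	0.19
phytosphingosine	B	-3.33	0.49	-16.07	0.47	-12.75	0.18
sphingosine	A	-6.09	0.59	-19.02	0.59	-12.93	0.20
sphingosine	B	-9.36	0.33	-22.48	0.27	-13.12	0.23
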