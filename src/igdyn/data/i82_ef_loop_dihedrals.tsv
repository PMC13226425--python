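# Backbone phi/psi angles (degrees) of the I82 EF-loop in the two deposited
# conformers (IN = 9IBI, OUT = 9IBK) and the chemical-shift based prediction.
residue_id	residue_name	phi_in	psi_in	phi_out	psi_out	phi_pred	psi_pred
73	GLU	-83	-18	-81	-21	-63	-44
74	ALA	-78	4	-99	20	-70	-35
75	GLN	-84	-178	-110	166	-85	-7
76	GLY	121	84	132	-70	94	-41
77	GLN	-9	109	-163	137	-69	138
78	TYR	-83	138	-118	139	-119	126
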