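# Conformer-specific NOE distance restraints of the I82 EF-loop (residues 73-77)
# with the effective distances in the best deposited IN (9IBI) and OUT (9IBK)
# structures.  tag = conformer the restraint is compatible with; upper_A = upper
# bound (A); d_in/d_out = distance in the best model of each conformer (A).
tag	atom1	res1	atom2	res2	upper_A	d_in	d_out
OUT	HB1	74	HH	78	2.0	2.9	2.3
OUT	HB1	75	HA	72	2.5	3.7	2.7
OUT	HA2	76	HG1	90	3.0	5.1	3.3
OUT	HA2	76	HG2	90	4.5	6.2	4.6
OUT	HN	76	HA	92	3.5	5.2	3.6
OUT	HD2	43	HA	74	2.0	3.2	2.1
IN	HB3	74	HG2#	67	3.5	3.6	4.1
IN	HA	75	HG	91	2.5	2.7	3.5
IN	HG1	43	HA3	76	2.5	2.6	5.8
IN	HG2	43	HA3	76	2.0	2.3	5.3
IN	HD2	43	HA3	76	3.0	3.3	6.1
IN	HD1	43	HA3	76	4.0	4.3	7.1
IN	HA	43	HA2	76	4.0	4.1	6.6
IN	HD21	44	HA2	76	2.0	2.3	3.6
IN	HD21	44	HA3	76	3.5	3.7	5.1
IN	HN	44	HA2	76	4.0	4.1	7.0
IN	HN	44	HA3	76	3.5	3.6	5.6
IN	HE21	77	HA	89	3.5	3.6	7.6
IN	HA3	76	HE#	78	4.0	4.3	7.3
IN	HB3	74	HG1#	70	4.0	4.1	6.3
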