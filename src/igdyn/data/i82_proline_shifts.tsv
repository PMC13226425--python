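# Proline Cbeta/Cgamma chemical shifts of murine titin I82 (BMRB 34980/34981)
residue_number	residue_name	CB	CG
4	PRO	31.8	26.5
9	PRO	31.9	27.4
35	PRO	32.1	26.8
50	PRO	31.2	27.8
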