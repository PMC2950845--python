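protein_number	group	description	accession
23	1	Possible ligand gated channel (GIC family	NP_896860.1
25	1	extracellular solute-binding protein, family	ZP_00674117.1
33	1	extracellular solute-binding protein, family 3	YP_378562.1
37	1	Ionoropic glutamate receptor	YP_376778.1
40	1	extracellular solute-binding protein, family 3	ABB23418.1
41	1	extracellular solute-binding protein, family	ZP_00517290.1
43	1	conserved protein of unknown function_ putative	YP_339120.1
46	1	extracellular solute-binding protein, family 3	ZP_00660701.1
56	1	hypothetical protein	NP_441171.1
62	1	Possible ligand gated channel (GIC family)	NP_894348.1
65	1	extracellular solute-binding protein, family	ZP_00530895.1
94	1	K channel, pore region	ZP_00533070.1
1	2	ABC transport system glutamine-binding protein	NP_486951.1
2	2	COG0834: ABC-type amino acid transport/signal	ZP_00157839.2
3	2	Q3MEH3) Ionotropic glutamate receptor precursor	ABA20613.1
4	2	COG0834: ABC-type amino acid transport/signal	ZP_00108493.1
5	2	glutamine ABC transporter, periplasmic	YP_168531.1
6	2	COG0834: ABC-type amino acid transport/signal	ZP_00053934.2
9	2	extracellular solute-binding protein, family 3	ZP_00622239.1
42	2	glutamate-gated potassium channel	YP_204476.1
50	2	hypothetical protein	YP_132561.1
63	2	extracellular solute-binding protein, family 3	ZP_00629025.1
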