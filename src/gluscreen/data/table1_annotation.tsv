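annotation_category	protein_numbers	count
ABC transport system glutamine-binding protein	1,5,7,15,18,31,36,39,53,58,59,61	12
ABC-type amino acid transport/signal	2,4,6,8,10,12,13,17,24,26,27,28,29,35,38,45,47,48,49,54,55,64,69,71,77,78,81,82,83,85,88,90,91,95,96,97,98,99,52	39
transporter	19,21	2
binding protein	66,80	2
extracellular solute-binding protein	9,25,33,40,41,46,63,65,70,73,89	11
hypothetical protein	16,20,22,43,50,56,57,60,67,72,75,76,79,100	14
iGluR	3,23,37,62	4
K channel	42,94	2
sensory transduction protein kinase	34	1
sensory box protein	87	1
IMP dehydrogenase/GMP reductase	84	1
Unknown function	30,32,44,51,68,74,86,92,93	9
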