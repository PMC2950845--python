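subtype	name	accession	length_aa
AMPA	AMPA 1	NP_000818.1	906
AMPA	AMPA 2 isoform 1	NP_000817.2	883
AMPA	AMPA 2 isoform 2	NP_001077088.1	883
AMPA	AMPA 2 isoform 3	NP_001077089.1	836
AMPA	glutamate receptor 3 isoform flip	NP_015564.4	894
AMPA	glutamate receptor 3 isoform flop	NP_000819.3	894
AMPA	AMPA 4 isoform 1	NP_000820.3	902
AMPA	AMPA 4 isoform 2	NP_001070711.2	884
Kainate	kainate 1 isoform 1	NP_000821.1	918
Kainate	kainate 1 isoform 2	NP_783300.1	905
Kainate	kainate 2 isoform 1	NP_068775.1	908
Kainate	kainate 2 isoform 2	NP_786944.1	869
Kainate	kainite 3	NP_000822.2	919
Kainate	glutamate receptor KA1	NP_055434.2	956
Kainate	glutamate receptor KA2	NP_002079.3	980
NMDA	NMDA receptor 1 isoform NR1-1	NP_000823.4	885
NMDA	NMDA receptor 1 isoform NR1-2	NP_067544.1	901
NMDA	NMDA receptor 1 isoform NR1-3	NP_015566.1	938
NMDA	N-methyl-D-aspartate receptor subunit 2A	NP_000824.1	1464
NMDA	N-methyl-D-aspartate receptor subunit 2D	NP_000825.2	1336
NMDA	N-methyl-D-aspartate receptor subunit 2C	NP_000826.2	1233
NMDA	N-methyl-D-aspartate receptor subunit 2B	NP_000827.2	1484
NMDA	N-methyl-D-aspartate 3A	NP_597702.1	1115
NMDA	N-methyl-D-aspartate 3B	NP_619635.1	1043
Delta	delta 1	NP_060021.1	1009
Delta	delta 2	NP_001501.2	1007
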