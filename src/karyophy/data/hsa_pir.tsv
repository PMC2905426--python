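# Homology map: human (HSA) whole-chromosome probes on Pithecia irrorata (PIR)
# probe_species: HSA
# target_species: PIR
# diploid_female: 48
# diploid_male: 48
# sex_system: XY
# probe_chroms: 1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22,X,Y
probe_chrom	targets
HSA1	10;9:q;23
HSA2	2:q;4:q
HSA3	15;16;19:distal q
HSA4	5
HSA5	1:proximal q + p
HSA6	3
HSA7	1:distal p;11
HSA8	7:p;12
HSA9	17
HSA10	6:proximal p-distal q;2:p
HSA11	18
HSA12	14
HSA13	8:proximal q + p
HSA14	13:distal q
HSA15	9:p;13:proximal q
HSA16	6:distal p-proximal q;4:p
HSA17	21
HSA18	7:q
HSA19	22
HSA20	20
HSA21	19:proximal q
HSA22	8:distal p
HSAX	X
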