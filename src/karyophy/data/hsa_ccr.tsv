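# Homology map: human (HSA) whole-chromosome probes on Cacajao calvus rubicundus (CCR)
# The Y entry is the Y-autosome composite: the HSA11 homologue is
# translocated to the Y, giving the X1X2Y multiple sex-chromosome system
# (male 2n = 45, female 2n = 46).  X2, the free homologue of the
# translocated autosome, carries no entry of its own in the source table.
# probe_species: HSA
# target_species: CCR
# diploid_female: 46
# diploid_male: 45
# sex_system: X1X2Y
# probe_chroms: 1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22,X,Y
# extra_chromosomes: X2
probe_chrom	targets
HSA1	11;17;6:p
HSA2	5:q;7:q
HSA3	19:proximal q;2:p;1:distal p
HSA4	9
HSA5	21:proximal q;2:q
HSA6	8
HSA7	21:distal q;10
HSA8	3:p;12
HSA9	14
HSA10	4:proximal p-distal q;7:p
HSA11	Y
HSA12	6:q
HSA13	13
HSA14	1:distal q
HSA15	1:proximal q;18
HSA16	4:distal p-proximal q;5:p
HSA17	16
HSA18	3:q
HSA19	15
HSA20	1:proximal p
HSA21	19:distal q
HSA22	20
HSAX	X
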