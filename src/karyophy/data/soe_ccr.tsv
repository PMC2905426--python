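# Homology map: Saguinus oedipus (SOE) whole-chromosome probes on
# Cacajao calvus rubicundus (CCR).  The Y-autosome translocation involves
# the SOE14 homologue.
# probe_species: SOE
# target_species: CCR
# diploid_female: 46
# diploid_male: 45
# sex_system: X1X2Y
# probe_chroms: 1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22,X,Y
# extra_chromosomes: X2
probe_chrom	targets
SOE1	13:distal q;14;20
SOE2	1:proximal p;13:proximal q;16
SOE3	3
SOE4	19
SOE5	15
SOE6	2:q;21
SOE7	9
SOE8	8
SOE9	7:q;18
SOE10	5
SOE11	1:q
SOE12	6:q
SOE13	10
SOE14	Y
SOE15	4
SOE16	11
SOE17	2:p
SOE18	12
SOE19	1:distal p
SOE20	17
SOE21	6:p
SOE22	7:p
SOEX	X
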