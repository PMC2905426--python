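# SYNTHETIC reconstruction: human (HSA) probes on Chiropotes utahicki (CUT).
# The published CUT painting map is not shipped with this package; this
# file is a reconstruction assembled from the cross-taxon rearrangement
# correspondences (which CUT chromosome carries which human homologous
# form) and the CUT karyotype description (2n = 54: 26 autosome pairs,
# XX/XY).  It preserves the documented content of each CUT chromosome -
# in particular the retained ancestral Platyrrhini associations 3a/21,
# 5/7a, 2b/16b, 8a/18, 14/15a (within 20/15/14) and the inverted
# 10a/16a - and is intended for association-level analysis only; arm
# assignments of minor segments are conventional, not observed.
# probe_species: HSA
# target_species: CUT
# diploid_female: 54
# diploid_male: 54
# sex_system: XY
# probe_chroms: 1,2,3,4,5,6,7,8,9,10,11,12,13,14,15,16,17,18,19,20,21,22,X,Y
probe_chrom	targets
HSA1	3;17:q;24
HSA2	2:q;8:q;23
HSA3	15;22:proximal q;26
HSA4	4
HSA5	10:proximal q;18
HSA6	5
HSA7	6;10:distal q
HSA8	9:p;21
HSA9	11
HSA10	2:p;7:proximal p-distal q
HSA11	12
HSA12	20
HSA13	13
HSA14	1:distal q
HSA15	1:proximal q;25
HSA16	7:distal p-proximal q;8:p
HSA17	14
HSA18	9:q
HSA19	16
HSA20	1:proximal p
HSA21	22:distal q
HSA22	19
HSAX	X
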