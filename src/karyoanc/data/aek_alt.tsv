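# taxon: AEK_alt
# 2n: 46
# sex_chromosomes: 2
# probes_failed:
# unpainted_pairs:
# layout_inferred: false
# conserved: 1,3,4,5,6,9,11,13,14,15,17,18,20,21,X
# two_blocks: 2,7,8,10,12,16,19,22
# three_blocks:
# note: Alternative ancestral Eutherian karyotype (2n=46), differing from the 2n=48 version only by the additional association HSA 10p/12/22.
taxon	chrom_id	segments	flags
AEK_alt	AEKALT.01	3,21	-
AEK_alt	AEKALT.02	4,8p	-
AEK_alt	AEKALT.03	7b,16p	-
AEK_alt	AEKALT.04	10p,12a,22a	-
AEK_alt	AEKALT.05	12b,22b	-
AEK_alt	AEKALT.06	14,15	-
AEK_alt	AEKALT.07	16q,19q	-
AEK_alt	AEKALT.08	1	-
AEK_alt	AEKALT.09	2p	-
AEK_alt	AEKALT.10	2q	-
AEK_alt	AEKALT.11	5	-
AEK_alt	AEKALT.12	6	-
AEK_alt	AEKALT.13	7a	-
AEK_alt	AEKALT.14	8q	-
AEK_alt	AEKALT.15	9	-
AEK_alt	AEKALT.16	10q	-
AEK_alt	AEKALT.17	11	-
AEK_alt	AEKALT.18	13	-
AEK_alt	AEKALT.19	17	-
AEK_alt	AEKALT.20	18	-
AEK_alt	AEKALT.21	19p	-
AEK_alt	AEKALT.22	20	-
AEK_alt	AEKALT.X	X	sex
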