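# taxon: Choloepus_hoffmanni
# 2n: 50
# sex_chromosomes: 2
# probes_failed:
# unpainted_pairs:
# layout_inferred: true
# conserved: 1,3,4,5,6,9,10,11,13,14,15,17,18,20,21,X
# two_blocks: 2,7,12,19,22
# three_blocks: 8?,16
# note: A small distal segment of the chromosome painted by HSA 7 was unlabeled; it may correspond to an undetected HSA 10 segment (a possible cryptic 7/10 association).
# note: The third HSA 8 block is uncertain in the source (count range 2-3) and is stored as an uncertain chromosome.
taxon	chrom_id	segments	flags
Choloepus_hoffmanni	CHO.01	3,21	-
Choloepus_hoffmanni	CHO.02	4,8a	-
Choloepus_hoffmanni	CHO.03	7b,16a	-
Choloepus_hoffmanni	CHO.04	12a,22a	-
Choloepus_hoffmanni	CHO.05	12b,22b	-
Choloepus_hoffmanni	CHO.06	14,15	-
Choloepus_hoffmanni	CHO.07	16b,19a	-
Choloepus_hoffmanni	CHO.08	1	-
Choloepus_hoffmanni	CHO.09	2a	-
Choloepus_hoffmanni	CHO.10	2b	-
Choloepus_hoffmanni	CHO.11	5	-
Choloepus_hoffmanni	CHO.12	6	-
Choloepus_hoffmanni	CHO.13	7a	-
Choloepus_hoffmanni	CHO.14	8b	-
Choloepus_hoffmanni	CHO.15	9	-
Choloepus_hoffmanni	CHO.16	10	-
Choloepus_hoffmanni	CHO.17	11	-
Choloepus_hoffmanni	CHO.18	13	-
Choloepus_hoffmanni	CHO.19	16c	-
Choloepus_hoffmanni	CHO.20	17	-
Choloepus_hoffmanni	CHO.21	18	-
Choloepus_hoffmanni	CHO.22	19b	-
Choloepus_hoffmanni	CHO.23	20	-
Choloepus_hoffmanni	CHO.24	8c	uncertain
Choloepus_hoffmanni	CHO.X	X	sex
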