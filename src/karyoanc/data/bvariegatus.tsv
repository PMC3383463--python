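# taxon: Bradypus_variegatus
# 2n: 54
# sex_chromosomes: 2
# probes_failed: 21
# unpainted_pairs: BVA25
# layout_inferred: false
# conserved: 5,6,9,11,13,14,15,17,18,20,21?,X
# two_blocks: 1,2,3,4,7,10,12,19,22
# three_blocks: 8,16
# note: 35 conserved segments (36 counting the inferred HSA 21 block on BVA1, whose distal non-heterochromatic region was unlabeled because the HSA 21 probe gave no hybridization).
# note: HSA 16 labels three segments, two of them on the same chromosome carrying the 12/22/16 association; segment order on that chromosome is not resolved.
taxon	chrom_id	segments	flags
Bradypus_variegatus	BVA1	3,21?	-
Bradypus_variegatus	BVA.02	4,8a	-
Bradypus_variegatus	BVA.03	7a,10a	-
Bradypus_variegatus	BVA.04	7b,16a	-
Bradypus_variegatus	BVA.05	12a,22a	-
Bradypus_variegatus	BVA.06	16b,12b,22b,16c	unordered
Bradypus_variegatus	BVA.07	14,15	-
Bradypus_variegatus	BVA.08	17,19a	-
Bradypus_variegatus	BVA.09	1a	-
Bradypus_variegatus	BVA.10	1b	-
Bradypus_variegatus	BVA.11	2a	-
Bradypus_variegatus	BVA.12	2b	-
Bradypus_variegatus	BVA.13	3b	-
Bradypus_variegatus	BVA.14	4b	-
Bradypus_variegatus	BVA.15	5	-
Bradypus_variegatus	BVA.16	6	-
Bradypus_variegatus	BVA.17	8b	-
Bradypus_variegatus	BVA.18	8c	-
Bradypus_variegatus	BVA.19	9	-
Bradypus_variegatus	BVA.20	10b	-
Bradypus_variegatus	BVA.21	11	-
Bradypus_variegatus	BVA.22	13	-
Bradypus_variegatus	BVA.23	18	-
Bradypus_variegatus	BVA.24	19b	-
Bradypus_variegatus	BVA.26	20	-
Bradypus_variegatus	BVA.X	X	sex
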