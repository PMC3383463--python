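# taxon: Bradypus_tridactylus
# 2n: 52
# sex_chromosomes: 2
# probes_failed:
# unpainted_pairs: BTR.u1
# layout_inferred: true
# conserved: 1,5,9,11,13,14,15,17,18,20,21,X
# two_blocks: 2,3,4,7,10,12,16,19,22
# three_blocks: 6,8?
# note: Correspondence inferred from Choloepus didactylus paints hybridized to B. tridactylus plus human paints on CDI; at least 35 segments.
# note: The CDI probe corresponding to HSA 2/8 gave no signal, so the third HSA 8 block is inferred but unconfirmed (count range 2-3); it is stored as an uncertain chromosome.
# note: 14/15 and 17/19, omitted from the truncated association cell of the source table, are included: the source text states both associations are present in all three Bradypus species.
# note: One hypothesised unpainted pair balances the layout against the reported 2n=52.
taxon	chrom_id	segments	flags
Bradypus_tridactylus	BTR.01	2a,6a	-
Bradypus_tridactylus	BTR.02	3,21	-
Bradypus_tridactylus	BTR.03	4,8a	-
Bradypus_tridactylus	BTR.04	7a,10a	-
Bradypus_tridactylus	BTR.05	7b,16a	-
Bradypus_tridactylus	BTR.06	11,19a	-
Bradypus_tridactylus	BTR.07	12a,22a	-
Bradypus_tridactylus	BTR.08	12b,22b,16b	unordered
Bradypus_tridactylus	BTR.09	14,15	-
Bradypus_tridactylus	BTR.10	17,19b	-
Bradypus_tridactylus	BTR.11	1	-
Bradypus_tridactylus	BTR.12	2b	-
Bradypus_tridactylus	BTR.13	3b	-
Bradypus_tridactylus	BTR.14	4b	-
Bradypus_tridactylus	BTR.15	5	-
Bradypus_tridactylus	BTR.16	6b	-
Bradypus_tridactylus	BTR.17	6c	-
Bradypus_tridactylus	BTR.18	8b	-
Bradypus_tridactylus	BTR.19	9	-
Bradypus_tridactylus	BTR.20	10b	-
Bradypus_tridactylus	BTR.21	13	-
Bradypus_tridactylus	BTR.22	18	-
Bradypus_tridactylus	BTR.23	20	-
Bradypus_tridactylus	BTR.24	8c	uncertain
Bradypus_tridactylus	BTR.X	X	sex
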