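# taxon: Dasypus_novemcinctus
# 2n: 64
# sex_chromosomes: 2
# probes_failed:
# unpainted_pairs:
# layout_inferred: true
# conserved: 5,9,13,14,15,17,18,20,X
# two_blocks: 1,4,6,7,10,11,16,19?,21,22
# three_blocks: 2?,3,8,12
# note: The second HSA 19 block and the third HSA 2 block are uncertain in the source table; both are stored as uncertain chromosomes (count ranges 1-2 and 2-3).
# note: HSA 21 appears under two blocks and both blocks sit in the doubled 3/21 association.
taxon	chrom_id	segments	flags
Dasypus_novemcinctus	DNO.01	3a,21a	-
Dasypus_novemcinctus	DNO.02	3b,21b	-
Dasypus_novemcinctus	DNO.03	4a,8a	-
Dasypus_novemcinctus	DNO.04	7a,16a	-
Dasypus_novemcinctus	DNO.05	10a,12a	-
Dasypus_novemcinctus	DNO.06	12b,22a	-
Dasypus_novemcinctus	DNO.07	12c,22b	-
Dasypus_novemcinctus	DNO.08	14,15	-
Dasypus_novemcinctus	DNO.09	16b,19a	-
Dasypus_novemcinctus	DNO.10	1a	-
Dasypus_novemcinctus	DNO.11	1b	-
Dasypus_novemcinctus	DNO.12	2a	-
Dasypus_novemcinctus	DNO.13	2b	-
Dasypus_novemcinctus	DNO.14	3c	-
Dasypus_novemcinctus	DNO.15	4b	-
Dasypus_novemcinctus	DNO.16	5	-
Dasypus_novemcinctus	DNO.17	6a	-
Dasypus_novemcinctus	DNO.18	6b	-
Dasypus_novemcinctus	DNO.19	7b	-
Dasypus_novemcinctus	DNO.20	8b	-
Dasypus_novemcinctus	DNO.21	8c	-
Dasypus_novemcinctus	DNO.22	9	-
Dasypus_novemcinctus	DNO.23	10b	-
Dasypus_novemcinctus	DNO.24	11a	-
Dasypus_novemcinctus	DNO.25	11b	-
Dasypus_novemcinctus	DNO.26	13	-
Dasypus_novemcinctus	DNO.27	17	-
Dasypus_novemcinctus	DNO.28	18	-
Dasypus_novemcinctus	DNO.29	20	-
Dasypus_novemcinctus	DNO.30	2c	uncertain
Dasypus_novemcinctus	DNO.31	19b	uncertain
Dasypus_novemcinctus	DNO.X	X	sex
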