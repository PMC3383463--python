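# taxon: Euphractus_sexcinctus
# 2n: 58
# sex_chromosomes: 2
# probes_failed:
# unpainted_pairs:
# layout_inferred: true
# conserved: 5,9,13,14,15,17,18,20,21,X
# two_blocks: 1,6,7,10,11,16,19,22
# three_blocks: 2,3,4,8,12
# note: The printed row is internally inconsistent with the reported 2n=58: 41 segments with 10 association junctions imply 31 chromosomes (2n=62). The one-chromosome-per-association layout below preserves the printed cells; validate_map flags the diploid mismatch as an advisory.
# note: The 11/19 association, absent from the printed row, is included: the source text twice states it is present in E. sexcinctus (and B. tridactylus) and excludes it from the ancestral complement on that distribution.
taxon	chrom_id	segments	flags
Euphractus_sexcinctus	ESE.01	2a,8a	-
Euphractus_sexcinctus	ESE.02	3a,21	-
Euphractus_sexcinctus	ESE.03	4a,8b	-
Euphractus_sexcinctus	ESE.04	7a,10a	-
Euphractus_sexcinctus	ESE.05	7b,16a	-
Euphractus_sexcinctus	ESE.06	12a,22a	-
Euphractus_sexcinctus	ESE.07	12b,22b	-
Euphractus_sexcinctus	ESE.08	14,15	-
Euphractus_sexcinctus	ESE.09	16b,19a	-
Euphractus_sexcinctus	ESE.10	1a	-
Euphractus_sexcinctus	ESE.11	1b	-
Euphractus_sexcinctus	ESE.12	2b	-
Euphractus_sexcinctus	ESE.13	2c	-
Euphractus_sexcinctus	ESE.14	3b	-
Euphractus_sexcinctus	ESE.15	3c	-
Euphractus_sexcinctus	ESE.16	4b	-
Euphractus_sexcinctus	ESE.17	4c	-
Euphractus_sexcinctus	ESE.18	5	-
Euphractus_sexcinctus	ESE.19	6a	-
Euphractus_sexcinctus	ESE.20	6b	-
Euphractus_sexcinctus	ESE.21	8c	-
Euphractus_sexcinctus	ESE.22	9	-
Euphractus_sexcinctus	ESE.23	10b	-
Euphractus_sexcinctus	ESE.24	11a,19b	-
Euphractus_sexcinctus	ESE.25	11b	-
Euphractus_sexcinctus	ESE.26	12c	-
Euphractus_sexcinctus	ESE.27	13	-
Euphractus_sexcinctus	ESE.28	17	-
Euphractus_sexcinctus	ESE.29	18	-
Euphractus_sexcinctus	ESE.31	20	-
Euphractus_sexcinctus	ESE.X	X	sex
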