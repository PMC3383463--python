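# taxon: Choloepus_didactylus
# 2n: 65
# sex_chromosomes: 1
# probes_failed:
# unpainted_pairs:
# layout_inferred: true
# conserved: 9,13,15,17,18,20,21,X
# two_blocks: 1,3,4,5,6,10,11,12,14,16,19,22
# three_blocks: 2,7,8
# note: 2n=65 reflects the reported Y/autosome translocation; the free sex chromosome count is 1 (X), the translocated Y riding on an autosome.
taxon	chrom_id	segments	flags
Choloepus_didactylus	CDI.01	2a,8a	-
Choloepus_didactylus	CDI.02	3a,21	-
Choloepus_didactylus	CDI.03	4a,8b	-
Choloepus_didactylus	CDI.04	7a,10a	-
Choloepus_didactylus	CDI.05	7b,16a	-
Choloepus_didactylus	CDI.06	12a,22a	-
Choloepus_didactylus	CDI.07	12b,22b	-
Choloepus_didactylus	CDI.08	14a,15	-
Choloepus_didactylus	CDI.09	1a	-
Choloepus_didactylus	CDI.10	1b	-
Choloepus_didactylus	CDI.11	2b	-
Choloepus_didactylus	CDI.12	2c	-
Choloepus_didactylus	CDI.13	3b	-
Choloepus_didactylus	CDI.14	4b	-
Choloepus_didactylus	CDI.15	5a	-
Choloepus_didactylus	CDI.16	5b	-
Choloepus_didactylus	CDI.17	6a	-
Choloepus_didactylus	CDI.18	6b	-
Choloepus_didactylus	CDI.19	7c	-
Choloepus_didactylus	CDI.20	8c	-
Choloepus_didactylus	CDI.21	9	-
Choloepus_didactylus	CDI.22	10b	-
Choloepus_didactylus	CDI.23	11a	-
Choloepus_didactylus	CDI.24	11b	-
Choloepus_didactylus	CDI.25	13	-
Choloepus_didactylus	CDI.26	14b	-
Choloepus_didactylus	CDI.27	16b	-
Choloepus_didactylus	CDI.28	17	-
Choloepus_didactylus	CDI.29	18	-
Choloepus_didactylus	CDI.30	19a	-
Choloepus_didactylus	CDI.31	19b	-
Choloepus_didactylus	CDI.32	20	-
Choloepus_didactylus	CDI.X	X	sex
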