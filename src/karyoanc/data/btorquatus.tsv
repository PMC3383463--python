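# taxon: Bradypus_torquatus
# 2n: 50
# sex_chromosomes: 2
# probes_failed:
# unpainted_pairs: BTO23
# layout_inferred: false
# conserved: 1,3,4,5,6,9,11,13,14,15,17,18,20,21,X
# two_blocks: 2,7,10,12,16,19,22
# three_blocks: 8
# note: 32 conserved segments; BTO23 is wholly unpainted and non-heterochromatic; other unlabeled regions are C-band-positive heterochromatin and are not recorded as segments.
# note: Painted chromosome ids are transcription ids, not the published G-band numbering.
taxon	chrom_id	segments	flags
Bradypus_torquatus	BTO.01	3,21	-
Bradypus_torquatus	BTO.02	4,8a	-
Bradypus_torquatus	BTO.03	7a,10a	-
Bradypus_torquatus	BTO.04	7b,16a	-
Bradypus_torquatus	BTO.05	12a,22a	-
Bradypus_torquatus	BTO.06	12b,22b	-
Bradypus_torquatus	BTO.07	14,15	-
Bradypus_torquatus	BTO.08	17,19a	-
Bradypus_torquatus	BTO.09	1	-
Bradypus_torquatus	BTO.10	2a	-
Bradypus_torquatus	BTO.11	2b	-
Bradypus_torquatus	BTO.12	5	-
Bradypus_torquatus	BTO.13	6	-
Bradypus_torquatus	BTO.14	8b	-
Bradypus_torquatus	BTO.15	8c	-
Bradypus_torquatus	BTO.16	9	-
Bradypus_torquatus	BTO.17	10b	-
Bradypus_torquatus	BTO.18	11	-
Bradypus_torquatus	BTO.19	13	-
Bradypus_torquatus	BTO.20	16b	-
Bradypus_torquatus	BTO.21	18	-
Bradypus_torquatus	BTO.22	19b	-
Bradypus_torquatus	BTO.24	20	-
Bradypus_torquatus	BTO.X	X	sex
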