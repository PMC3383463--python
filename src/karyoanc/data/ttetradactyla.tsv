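# taxon: Tamandua_tetradactyla
# 2n: 54
# sex_chromosomes: 2
# probes_failed:
# unpainted_pairs:
# layout_inferred: true
# conserved: 9,10,13,17,18,20,21,X
# two_blocks: 2,6,7,11,12,14,15,16,19,22
# three_blocks: 1,3,4,5,8
# note: The printed association cell lists 7/20 and 20/7/10 separately and a third HSA 22 association (3/22); the stored layout follows the printed associations, so layout-derived block counts for HSA 7, 20 and 22 exceed the printed count columns (advisories, printed counts authoritative).
taxon	chrom_id	segments	flags
Tamandua_tetradactyla	TTE.01	1a,9	-
Tamandua_tetradactyla	TTE.02	1b,13	-
Tamandua_tetradactyla	TTE.03	1c,19a	-
Tamandua_tetradactyla	TTE.04	2a,8a	-
Tamandua_tetradactyla	TTE.05	3a,6a	-
Tamandua_tetradactyla	TTE.06	3b,21	-
Tamandua_tetradactyla	TTE.07	4a,8b	-
Tamandua_tetradactyla	TTE.08	7a,16a	-
Tamandua_tetradactyla	TTE.09	8c,17	-
Tamandua_tetradactyla	TTE.10	12a,22a	-
Tamandua_tetradactyla	TTE.11	12b,22b	-
Tamandua_tetradactyla	TTE.12	14a,15a	-
Tamandua_tetradactyla	TTE.13	14b,15b	-
Tamandua_tetradactyla	TTE.14	16b,19b	-
Tamandua_tetradactyla	TTE.15	3c,22c	-
Tamandua_tetradactyla	TTE.16	5a,11a	-
Tamandua_tetradactyla	TTE.17	7b,20a	-
Tamandua_tetradactyla	TTE.18	20b,7c,10	unordered
Tamandua_tetradactyla	TTE.19	2b	-
Tamandua_tetradactyla	TTE.20	4b	-
Tamandua_tetradactyla	TTE.21	4c	-
Tamandua_tetradactyla	TTE.22	5b	-
Tamandua_tetradactyla	TTE.23	5c	-
Tamandua_tetradactyla	TTE.24	6b	-
Tamandua_tetradactyla	TTE.25	11b	-
Tamandua_tetradactyla	TTE.26	18	-
Tamandua_tetradactyla	TTE.X	X	sex
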