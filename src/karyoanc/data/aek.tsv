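# taxon: AEK
# 2n: 48
# sex_chromosomes: 2
# probes_failed:
# unpainted_pairs:
# layout_inferred: false
# conserved: 1,3,4,5,6,9,11,13,14,15,17,18,20,21,X
# two_blocks: 2,7,8,10,12,16,19,22
# three_blocks:
# note: Hypothetical ancestral Eutherian karyotype (2n=48) expressed as human-chromosome blocks: 1, 2p, 2q, 3/21, 4/8p, 5, 6, 7a, 7b/16p, 8q, 9, 10p, 10q, 11, 12/22 twice, 13, 14/15, 16q/19q, 17, 18, 19p, 20, X.
taxon	chrom_id	segments	flags
AEK	AEK.01	3,21	-
AEK	AEK.02	4,8p	-
AEK	AEK.03	7b,16p	-
AEK	AEK.04	12a,22a	-
AEK	AEK.05	12b,22b	-
AEK	AEK.06	14,15	-
AEK	AEK.07	16q,19q	-
AEK	AEK.08	1	-
AEK	AEK.09	2p	-
AEK	AEK.10	2q	-
AEK	AEK.11	5	-
AEK	AEK.12	6	-
AEK	AEK.13	7a	-
AEK	AEK.14	8q	-
AEK	AEK.15	9	-
AEK	AEK.16	10p	-
AEK	AEK.17	10q	-
AEK	AEK.18	11	-
AEK	AEK.19	13	-
AEK	AEK.20	17	-
AEK	AEK.21	18	-
AEK	AEK.22	19p	-
AEK	AEK.23	20	-
AEK	AEK.X	X	sex
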