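# Replication run configuration: every choice used to derive the ancestral
# Xenarthran karyotype (AXK, 2n=48) and the clade signature tables.
engine: fitch
tie_break: outgroup
outgroup: AEK
uncertainty_policy: missing
target_node: Xenarthra

# Fragment-count characters only: the highly rearranged lesser-anteater
# karyotype is treated as missing data when polarising block counts, the
# same discounting the source analysis applies to it.
downweight_taxa:
  - Tamandua_tetradactyla

# A printed multi-way association credited as evidence for a contained pair.
association_credits:
  "20/7/10":
    - "7/10"

# Labeled alternative ancestral states emitted alongside the main karyotype.
count_variants:
  "6": [2]

# Sub-block assignment for assembling ancestral adjacencies: which block of
# a multi-block chromosome joins which partner.  Derived from the ancestral
# Eutherian composition (4/8p, 7a, 7b/16p, 8q, 16q/19q, 12/22 twice) and the
# proposed AXK block lists; the assembler never guesses these.
adjacencies:
  "3/21": [["3", "21"]]
  "4/8": [["4", "8a"]]
  "7/10": [["7a", "10a"]]
  "7/16": [["7b", "16a"]]
  "12/22": [["12a", "22a"], ["12b", "22b"]]
  "14/15": [["14", "15"]]
  "16/19": [["16b", "19b"]]
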