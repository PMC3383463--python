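# Deep-outgroup state overrides, applied only where configured.
# Each entry asserts the state of one character in outgroups deeper than the
# ancestral Eutherian pseudo-taxon, with its provenance.
"7/10":
  state: 1
  provenance: >-
    HSA 7q and 10p are associated on opossum (Monodelphis domestica)
    chromosome 8 and chicken (Gallus gallus) chromosome 1 in Ensembl-based
    genome comparisons, supporting 7/10 as ancestral at the Xenarthra node.
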