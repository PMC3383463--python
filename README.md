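# karyoanc

Ancestral karyotype reconstruction from comparative chromosome-painting
(Zoo-FISH) homology maps.

## The problem

Hybridizing whole-chromosome human probes onto the metaphases of another
mammal reveals which human chromosome (HSA 1–22, X) each segment of the
target karyotype is homologous to.  Two kinds of phylogenetic character
fall out of such a map:

* **syntenic associations** — two or more human chromosomes painting one
  target chromosome (e.g. HSA 7/10), the trace of a fusion;
* **fragment counts** — how many blocks a human chromosome is split into
  (1 = conserved intact), the trace of fissions.

Comparative cytogeneticists score these characters across species, polarize
them against a hypothetical ancestral Eutherian karyotype (AEK, 2n = 48),
and argue block by block about which states are ancestral
(symplesiomorphies), which are clade-defining fusions/fissions
(synapomorphies, "chromosome signatures"), and which are convergent
(homoplasy).  `karyoanc` turns that argument into a reproducible pipeline
for the xenarthrans (sloths, anteaters and armadillos), whose painted
karyotypes — eight species across all four painted families — support an
ancestral Xenarthran karyotype (AXK) with 2n = 48.

The package ships the published painting maps of *Bradypus torquatus*,
*B. variegatus*, *B. tridactylus* (inferred), *Choloepus hoffmanni*,
*C. didactylus*, *Dasypus novemcinctus*, *Euphractus sexcinctus* and
*Tamandua tetradactyla*, the two AEK variants (2n = 48 and 2n = 46), the
genus-level topology, and the deep-outgroup evidence table (the opossum /
chicken 7q–10p association).

## Methods in brief

Characters are extracted per map (association multiplicities; per-HSA block
counts with ranges for uncertain "?" entries and missing states for failed
probes) and reconstructed on the fixed rooted tree by small parsimony:
unordered (Fitch) logic for presence/absence, ordered (Wagner,
cost `|Δstate|`) for counts and multiplicities, optional Dollo
(single-origin) reconstruction, all with exhaustive enumeration of the
most-parsimonious reconstructions (MPRs) and a brute-force oracle backing
them in the tests.  Ambiguity at a node is resolved by outgroup
tie-breaking (the AEK pseudo-taxon) after consulting an explicit
deep-outgroup override table.  Resolved blocks and adjacencies are
assembled into chromosomes as connected components of the block-adjacency
graph (paths only; the sub-block assignment — which of HSA 8's three blocks
joins 4 — comes from a configured table, never a guess), giving the diploid
number as `2 × autosomal components + sex chromosomes`.  A fusion/fission
simulator with per-branch Poisson events, probe-failure masking and a
ground-truth event log exercises every stage.

## Worked example

```python
>>> from karyoanc.model import AncestralKaryotypeModel
>>> results = AncestralKaryotypeModel.from_fixtures().fit("Xenarthra")
>>> print(results.summary())
Ancestral karyotype at node Xenarthra
==============================================
diploid number (2n)      48
conserved segments       32
junctions (associations) 8

associations: 12/22 (x2), 14/15, 16/19, 3/21, 4/8, 7/10, 7/16
block counts: X:1, 1:1, 2:2, 3:1, 4:1, 5:1, 6:1, 7:2, 8:3, 9:1, 10:2, ...
...
labeled variants: HSA6=2 (2n=50)
```

Reading: the inferred ancestral Xenarthran complement has 48 chromosomes,
carrying the ancestral Eutherian associations 3/21, 4/8, 7/16, 12/22
(twice), 14/15 and 16/19 plus the Xenarthra-specific 7/10 fusion, with
HSA 8 in three blocks (the Xenarthra-specific fission) — it differs from
the AEK only by those two features:

```python
>>> from karyoanc import karyotype_from_map, load_fixtures
>>> aek = karyotype_from_map(load_fixtures().maps["AEK"])
>>> d = results.compare(aek)
>>> d.adjacencies_only_a, d.count_differences, d.diploid_delta
({'7/10': 1}, {'8': (3, 2)}, 0)
```

Signature queries (`results.signatures()` or the CLI) report 17/19 as the
*Bradypus* signature, 12/22/16 as the (*B. variegatus*, *B. tridactylus*)
signature, 7/10 + the HSA 8 three-block state as the Xenarthra signatures
(with caveats for the two species where 7/10 was not detected), and no
signatures for Pilosa or Folivora.

The same is available from a shell:

```
karyoanc infer --node Xenarthra
karyoanc signatures --clade Bradypus
karyoanc run --out out/            # full report bundle
karyoanc simulate --seed 42 --out sim/
```

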