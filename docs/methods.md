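# Methods

## Data model

A painting map records one species' karyotype as seen through human
whole-chromosome probes: per chromosome, the ordered (or flagged-unordered)
list of homology blocks; wholly unpainted non-heterochromatic pairs;
probes that yielded no hybridization; and "?" flags on inferred but
unconfirmed entries.  Heterochromatic unlabeled regions are recorded as
counts but excluded from all segment arithmetic, matching how painted
complements are reported.  All counts are per haploid complement except the
diploid number, `2n = 2 × (painted + unpainted autosome pairs) + sex
chromosomes`.  The Y is metadata only: human Y probes give no
cross-species signal.

Two transcription conventions matter for the shipped literature maps:

* For rows where only the correspondence table was published (not a full
  chromosome-level layout), chromosomes are stored one-per-printed-
  association with leftover blocks as singletons, and the printed
  conserved/two-block/three-block columns are stored alongside and treated
  as authoritative for fragment counts.  Where the printed cells are
  internally inconsistent (the *E. sexcinctus* row cannot reach its
  reported 2n under any per-association layout; the *T. tetradactyla* row
  lists more 7, 20 and 22 junctions than its count columns allow), the
  tension is preserved and surfaced as validation advisories rather than
  silently repaired.
* Segments of the same human chromosome separated by another segment on
  one chromosome (the *B. variegatus* 16/12/22/16 case) count as two
  blocks and three junctions — the only reading consistent with that
  species' 36 segments and 2n = 54 simultaneously.

## Characters

Association characters are unordered, orientation-free co-occurrence sets
(painting resolves neither orientation nor breakpoint identity).  Multi-way
associations are characters of their own and are *not* decomposed into
contained pairs; a single configured "containment credit" scores the lesser
anteater's printed 20/7/10 chromosome as carrying the 7/10 adjacency, the
one case where the source analysis counts a triple as evidence for a pair.
Multiplicities (12/22 twice) are integer states compared by ordered
parsimony, since the ancestral complement itself carries a doubled
association.  Fragment counts are integers, ranges for "?" entries, missing
for failed probes.

Uncertainty policy (`missing` default, `optimistic`, `pessimistic`) decides
what "?" becomes; an observation that would have required a failed probe is
always missing regardless of policy, but a printed "?" inference takes the
policy route.

## Reconstruction

All engines run a generalized Sankoff dynamic programme over small integer
state domains with an up pass (subtree costs) and a down pass
(out-of-subtree costs), so per-node MPR state sets are exact; full MPR
enumeration uses the edgewise decomposition of joint optima and is capped
(20 000 assignments) far above anything these data produce.  Missing tips
constrain nothing; range tips are free within bounds; polytomies are
handled natively.  A brute-force enumerator over all internal assignments
(refusing > 12 internal nodes) is the oracle in the test-suite: Fitch and
Wagner agree with it on cost, node sets and (for Fitch) the complete MPR
list over hundreds of random characters.

Dollo reconstruction (single origin, unlimited losses) places the gain on
the stem of the minimal clade spanning all present tips; it is opt-in,
because the study's own logic is Fitch-like (it rejects 11/19 as
convergent — exactly what Dollo would ancestralize) while its acceptance of
7/10 rests on *deeper-outgroup evidence*, which is encoded as an explicit
override table (opossum chromosome 8 and chicken chromosome 1 carry
7q/10p), not as a silent engine switch.

Ambiguity resolution: policy `report` keeps MPR sets; policy `outgroup`
picks, per ambiguous node, the state nearest the override (if one is
configured for the character) or the outgroup tip's state.  The outgroup
enters as an ordinary basal tip — that is how the source argument works —
so no root prior is needed.  Every resolution carries its justification in
the provenance record.

For signature classification the rules differ deliberately: the root is
pinned by the outgroup tip and other ambiguous nodes only by configured
overrides.  Blanket outgroup tie-breaking inside the in-group would
manufacture certainty the data do not contain — it would, for instance,
collapse the two genuinely indistinguishable 16/19 loss scenarios in the
sloths (loss on the *Bradypus* stem plus loss in *C. didactylus*, versus
loss on the Folivora stem plus regain in *C. hoffmanni*) and promote a
loss to a spurious *Bradypus* signature.  A synapomorphy requires the
derived *gain* (new association, or +k blocks) on the clade's stem in
every retained MPR and absence outside the clade among scored taxa; in-
clade taxa lacking the state become caveats (7/10 in *C. hoffmanni* and
*D. novemcinctus*), missing data are listed but never disqualify.

### Down-weighting the lesser anteater for counts

Plain Wagner parsimony with outgroup tie-breaking reconstructs HSA 3 and
HSA 4 as two blocks at the Xenarthra node; the source analysis instead
treats those fissions as convergent, explicitly discounting the highly
rearranged *T. tetradactyla* karyotype when polarizing block counts
("leaving *E. sexcinctus* as the sole species to be considered").  The
packaged replication config encodes exactly that: fragment-count characters
treat *T. tetradactyla* as missing (`downweight_taxa`), while association
characters keep it (its 7/10 and HSA 8 evidence counts).  With this one
documented choice every ancestral block count, the association set, and
2n = 48 reproduce; without it the pipeline yields 2n = 52 with HSA 3/4
split, which is the honest plain-parsimony answer.  HSA 6 remains
ambiguous (1 or 2 blocks) under the full taxon set and resolves to 1 by
outgroup preference; the alternative (two blocks) is emitted as a labeled
variant karyotype (2n = 50).

## Assembly

Blocks (per-HSA counts) plus adjacencies form a graph whose connected
components are chromosomes; components must be simple paths (an adjacency
referencing an absent block, a block with three junction partners, or a
circular chromosome is a reported conflict).  Which sub-block carries which
junction is read from a configured assignment table derived from the
ancestral Eutherian composition (4/8p, 7a, 7b/16p, 8q, 16q/19q, 12/22
twice); the assembler never invents sub-block pairings.  Whether the
ancestral HSA 2 blocks correspond to 2p/2q is not asserted; they are
labeled 2a/2b with no arm hint.

## Simulator

The generator evolves a karyotype along the fixed tree by per-branch
Poisson fusions and fissions — the only two event classes this character
system can observe.  Fusions end-join two whole chromosomes (centric-
fusion-like, random orientation); fissions split a uniformly chosen block
in two.  The X is held immune (it is conserved across the study group);
branch lengths default to 1.  Default rates of 0.1 events per branch per
event type give tips within the empirically observed distance of the
ancestral complement (a few events per lineage).  Probe-failure masking
drops each human probe independently per taxon, converting its segments to
unpainted regions (a fully erased chromosome becomes an unpainted pair);
planted stem fusions support signature-recovery experiments.  The event
log stores the true karyotype at every node and replays exactly.

What the simulator does *not* emulate: translocations and inversions
(invisible to the characters), heterochromatin growth, band-level
coordinates, correlated probe failures, or transcription noise in
published tables.  Passing recovery tests therefore show the inference is
sound under the model's own event vocabulary, not that real karyotype
evolution lacks the excluded processes.

Calibration: with 200 replicates on the study tree at 0.1 events/branch
per type, root co-occurrence recovery (F1 against the true ancestor,
conservative minimum-state resolution at the root) averaged 0.994
(0.977 at rate 0.2); the frozen test threshold is a mean of 0.95 over 60
replicates at rate 0.1.  Recovery degrades monotonically with rate, and is
exact at rate 0.

## Numerical and degenerate-input choices

Costs are unit/absolute-difference integers held as floats; no tolerances
are involved.  State domains span the observed tip range (plus {0, 1} for
binary characters), which is sufficient for ordered optima.  Ties between
event placements along a branch (accelerated vs delayed transformation)
are never auto-chosen: outputs carry MPR sets and name the policy used.
Empty present-tip sets under Dollo cost zero; single-tip trees cost zero;
maps whose reported 2n disagrees with their layout are flagged, not
rejected; fusion proposals with no legal partner are logged as refused.

## Known limitations

* Fragment-count layouts for the five literature species are
  reconstructed from printed count columns, not published ideograms; their
  chromosome-level adjacency detail beyond the printed associations is not
  claimed.
* The acceptance of 7/10 versus the rejection of 11/19 is reproduced via
  the override table — the cited evidence, not a unified formal criterion,
  because no such criterion exists in the source argument.
* Segment-level homology (whether 7/10 in Xenarthra equals 7q/10p in the
  outgroups, or 1/19 across supraorders) is outside what painting data can
  establish; the tool reports character distributions only.
* No statistical support values are attached to signatures; the character
  counts are far too small for resampling to be meaningful.
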