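"""Classify character histories and report clade-specific chromosome
signatures.

A character is a *synapomorphy* of a clade when, in every retained
most-parsimonious reconstruction, the derived state arises exactly once, on
that clade's stem branch, and no scored taxon outside the clade carries it.
For associations the derived state is presence (a fusion product); for
fragment counts, an increase on the stem (a fission).  *Homoplasy* means
two or more independent origins — or a loss-and-regain — in every MPR;
*symplesiomorphy* an ancestral state shared by descent; reconstructions
whose MPRs disagree on the class are *ambiguous*.

Deep-outgroup overrides and the outgroup tip are used to pin down ambiguous
nodes before classification (the evidence route by which the 7/10
association is accepted as a Xenarthra signature); generic outgroup
tie-breaking is otherwise not applied here, so genuinely unresolved
histories (the 16/19 loss scenarios in sloths) stay unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .character_extraction import Character, CharacterMatrix
from .karyotype_assembly import InferenceConfig, reconstruct_character
from .parsimony import PhyloTree, Reconstruction, resolve_ambiguity

__all__ = [
    "Classification",
    "SignatureReport",
    "classify_character",
    "clade_signatures",
    "build_signature_report",
]


@dataclass(frozen=True)
class Classification:
    kind: str                      # synapomorphy | autapomorphy | symplesiomorphy
    #                              # | homoplasy | ambiguous | absent
    clade: Optional[str] = None    # for synapomorphy/autapomorphy
    detail: str = ""
    caveats: tuple[str, ...] = ()


def _retained_mprs(rec: Reconstruction, config: Optional[InferenceConfig]):
    """Filter MPRs to those consistent with override/outgroup-pinned nodes.

    Only nodes that an override or the (unambiguous) outgroup state can fix
    are pinned; everything else keeps its full MPR variation.
    """
    if config is None:
        return list(zip(rec.mprs, rec.mpr_events))
    pinned: dict[str, int] = {}
    ov = config.overrides.get(rec.character)
    root_label = rec.tree.labels[rec.tree.root]
    for lab in rec.ambiguous_nodes:
        if rec.tree.is_tip[rec.tree.index_of(lab)]:
            continue
        if lab == root_label and config.outgroup in rec.node_states:
            # the root follows the outgroup tip, not the override: the
            # override is evidence about the in-group node it supports
            og = rec.node_states[config.outgroup]
            if len(og) == 1 and next(iter(og)) in rec.node_states[lab]:
                pinned[lab] = next(iter(og))
                continue
        if ov is not None and ov.state in rec.node_states[lab]:
            pinned[lab] = ov.state
    out = [(m, e) for m, e in zip(rec.mprs, rec.mpr_events)
           if all(m[lab] == s for lab, s in pinned.items())]
    return out or list(zip(rec.mprs, rec.mpr_events))


def classify_character(rec: Reconstruction, tree: Optional[PhyloTree] = None,
                       config: Optional[InferenceConfig] = None,
                       derived_direction: int = +1) -> Classification:
    """Classify one reconstruction.

    ``derived_direction`` fixes what counts as the derived change: +1 for
    gains/fissions (the default: new associations and extra blocks are the
    derived states painting can date), -1 to hunt stem losses instead.
    """
    t = tree or rec.tree
    retained = _retained_mprs(rec, config)

    per_mpr: list[Classification] = []
    for mpr, events in retained:
        derived = [e for e in events
                   if (e[2] - e[1] > 0) == (derived_direction > 0)]
        reversals = [e for e in events
                     if (e[2] - e[1] > 0) != (derived_direction > 0)]
        if not events:
            per_mpr.append(Classification("symplesiomorphy",
                                          detail="no changes in this MPR"))
            continue
        if not derived:
            # only losses of an ancestrally present state
            if len(reversals) >= 2:
                per_mpr.append(Classification(
                    "homoplasy", detail=f"{len(reversals)} independent losses"))
            else:
                node = reversals[0][0]
                idx = t.index_of(node)
                kind = "autapomorphy" if t.is_tip[idx] else "synapomorphy"
                per_mpr.append(Classification(
                    f"loss-{kind}", clade=node,
                    detail="derived state is a loss"))
            continue
        if len(derived) >= 2 or (derived and reversals and
                                 _regain(derived, reversals, t)):
            per_mpr.append(Classification(
                "homoplasy",
                detail=f"{len(derived)} gains, {len(reversals)} losses"))
            continue
        node = derived[0][0]
        idx = t.index_of(node)
        if t.is_tip[idx]:
            per_mpr.append(Classification("autapomorphy", clade=node,
                                          detail="single terminal gain"))
        else:
            per_mpr.append(Classification("synapomorphy", clade=node,
                                          detail="single stem gain"))

    kinds = {(c.kind, c.clade) for c in per_mpr}
    if len(kinds) == 1:
        return per_mpr[0]
    return Classification("ambiguous",
                          detail="MPRs disagree: " +
                                 "; ".join(sorted(f"{k}({c})" if c else k
                                                  for k, c in kinds)))


def _regain(gains, losses, tree: PhyloTree) -> bool:
    """True when some gain sits below a loss of the same state (regain)."""
    loss_nodes = {tree.index_of(e[0]) for e in losses}
    # a gain is a regain when a loss edge lies on its path to the root
    for g in gains:
        i = tree.parent[tree.index_of(g[0])]
        while i != -1:
            if i in loss_nodes:
                return True
            i = tree.parent[i]
    return False


@dataclass
class Signature:
    character: str
    kind: str                # "association" | "fragment_count"
    detail: str
    caveats: list[str] = field(default_factory=list)
    missing_taxa: list[str] = field(default_factory=list)


def clade_signatures(matrix: CharacterMatrix, tree, clade: str,
                     config: InferenceConfig) -> list[Signature]:
    """All characters whose derived state arises on ``clade``'s stem in
    every retained MPR and is absent outside the clade among scored taxa.

    Association signatures are presence gains; count characters qualify via
    a +k step on the stem branch (e.g. HSA 8 going from two to three
    blocks).  Signatures are reported with caveats naming in-clade taxa
    that lack the state and taxa missing data for it.
    """
    t = tree if isinstance(tree, PhyloTree) else PhyloTree.from_dendropy(tree)
    clade_idx = t.index_of(clade)
    if t.is_tip[clade_idx]:
        raise KeyError(f"{clade!r} is a tip, not a clade")
    inside = set(t.clade_tips(clade_idx))

    out: list[Signature] = []
    for ch in matrix.characters:
        rec = reconstruct_character(matrix, t, ch, config)
        retained = _retained_mprs(rec, config)
        stem_steps = []
        for mpr, events in retained:
            stem = [e for e in events if e[0] == clade and e[2] > e[1]]
            other_gains = [e for e in events if e[0] != clade and e[2] > e[1]]
            stem_steps.append(bool(stem) and not other_gains)
        if not (stem_steps and all(stem_steps)):
            continue
        # outside-clade absence among scored taxa (association characters)
        caveats, missing = [], []
        ok = True
        for taxon in matrix.taxa:
            s = matrix.state(ch, taxon)
            if taxon in config.downweight_taxa and ch.kind == "fragment_count":
                s = None
            if s is None:
                missing.append(taxon)
                continue
            hi = s[1] if isinstance(s, tuple) else s
            lo = s[0] if isinstance(s, tuple) else s
            derived_state = min(m[clade] for m, _ in retained)
            if taxon in inside:
                if hi < derived_state:
                    caveats.append(f"{taxon} lacks the derived state")
            else:
                if ch.kind == "association" and lo >= 1:
                    ok = False
        if not ok:
            continue
        anc = sorted({m[clade] for m, _ in retained})
        if ch.kind == "fragment_count":
            parent_states = sorted({m[t.labels[t.parent[clade_idx]]]
                                    for m, _ in retained})
            detail = f"count {parent_states} -> {anc} on the {clade} stem"
        else:
            detail = f"gained on the {clade} stem (state {anc})"
        out.append(Signature(ch.label, ch.kind, detail, caveats, missing))
    return out


@dataclass
class SignatureReport:
    """Per-character classifications plus per-clade signature lists."""

    classifications: dict[str, Classification]
    clades: dict[str, list[Signature]]

    def to_dict(self) -> dict:
        return {
            "characters": {
                lab: {"class": c.kind, "clade": c.clade, "detail": c.detail}
                for lab, c in self.classifications.items()},
            "clades": {
                clade: [{"character": s.character, "kind": s.kind,
                         "detail": s.detail, "caveats": s.caveats,
                         "missing_data": s.missing_taxa} for s in sigs]
                for clade, sigs in self.clades.items()},
        }


def build_signature_report(matrix: CharacterMatrix, tree,
                           config: InferenceConfig,
                           clades: Optional[list[str]] = None) -> SignatureReport:
    t = tree if isinstance(tree, PhyloTree) else PhyloTree.from_dendropy(tree)
    classifications = {}
    for ch in matrix.characters:
        rec = reconstruct_character(matrix, t, ch, config)
        classifications[ch.label] = classify_character(rec, t, config)
    if clades is None:
        clades = [t.labels[i] for i in t.internal_indices]
    clade_map = {c: clade_signatures(matrix, t, c, config) for c in clades}
    return SignatureReport(classifications, clade_map)
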