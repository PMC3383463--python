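"""Assemble ancestral blocks and adjacencies into chromosomes, and the
end-to-end ancestral-karyotype inference pipeline.

A karyotype is a set of human-chromosome blocks (with per-chromosome
counts) plus block-level adjacencies; chromosomes are the connected
components of the block-adjacency graph, which must be a disjoint union of
paths (linear chromosomes).  The diploid number follows as twice the
autosomal component count plus the sex chromosomes.

Which sub-block joins which partner (that 7a joins 10 while 7b joins 16,
that the 4/8 junction uses one of HSA 8's blocks) is read from an explicit
assignment table in the run configuration — the assembler never guesses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import networkx as nx

from .character_extraction import Character, CharacterMatrix
from .karyo_model import HUMAN_CHROMOSOMES, PaintingMap
from .parsimony import (
    OutgroupOverride,
    PhyloTree,
    Reconstruction,
    resolve_ambiguity,
    wagner_counts,
)

__all__ = [
    "AssemblyConflictError",
    "AncestralKaryotype",
    "InferenceConfig",
    "assemble_karyotype",
    "karyotype_from_map",
    "infer_ancestral_states",
    "infer_ancestral_karyotype",
    "compare_karyotypes",
]

_HSA_ORDER = {h: i for i, h in enumerate(HUMAN_CHROMOSOMES)}


class AssemblyConflictError(ValueError):
    """Adjacency set inconsistent with the block set (e.g. an association
    inferred present while the fragment it needs is inferred absent)."""


def _block_ids(hsa: str, count: int) -> list[str]:
    if count <= 0:
        return []
    if count == 1:
        return [hsa]
    return [f"{hsa}{chr(ord('a') + i)}" for i in range(count)]


@dataclass
class AncestralKaryotype:
    """An inferred (or given) karyotype: blocks, adjacencies, chromosomes."""

    blocks: dict[str, int]                      # human chromosome -> block count
    adjacencies: list[tuple[str, str]]          # block-id pairs, e.g. ("7a","10a")
    chromosomes: list[tuple[str, ...]] = field(default_factory=list)
    sex_chromosomes: int = 2
    provenance: dict[str, dict] = field(default_factory=dict)
    variants: dict[str, "AncestralKaryotype"] = field(default_factory=dict)

    @property
    def diploid_number(self) -> int:
        autosomal = sum(1 for c in self.chromosomes if "X" not in {b.rstrip("abcdef") for b in c})
        return 2 * autosomal + self.sex_chromosomes

    @property
    def segment_count(self) -> int:
        return sum(self.blocks.values())

    @property
    def junction_count(self) -> int:
        return len(self.adjacencies)

    def association_multiset(self) -> dict[str, int]:
        """Adjacencies at the human-chromosome level, e.g. {"7/10": 1,
        "12/22": 2}, keyed by canonically sorted labels."""
        out: dict[str, int] = {}
        for a, b in self.adjacencies:
            ha, hb = a.rstrip("abcdef"), b.rstrip("abcdef")
            key = "/".join(sorted((ha, hb), key=lambda h: _HSA_ORDER[h]))
            out[key] = out.get(key, 0) + 1
        return out

    def cooccurrence_multiset(self) -> dict[str, int]:
        """Distinct-human-chromosome co-occurrences per chromosome, keyed
        like extracted association characters (so recovery metrics compare
        like with like: extraction sees co-occurrence, not segment order)."""
        from .karyo_model import AssociationType

        out: dict[str, int] = {}
        for chrom in self.chromosomes:
            hsas = {b.rstrip("abcdef") for b in chrom}
            if len(hsas) >= 2:
                key = str(AssociationType(tuple(hsas)))
                out[key] = out.get(key, 0) + 1
        return out

    def describe(self) -> str:
        parts = []
        for chrom in self.chromosomes:
            parts.append("/".join(chrom))
        return "; ".join(parts)


def assemble_karyotype(blocks: dict[str, int],
                       adjacencies: list[tuple[str, str]],
                       sex_chromosomes: int = 2,
                       provenance: Optional[dict] = None) -> AncestralKaryotype:
    """Build chromosomes as connected components of the adjacency graph.

    Deterministic and order-independent: components are paths read from
    their lexicographically smaller end, sorted by their lowest block.
    Raises :class:`AssemblyConflictError` on adjacencies to nonexistent
    blocks, on blocks with more than two junction partners, and on circular
    chromosomes.
    """
    ids: set[str] = set()
    for hsa, count in blocks.items():
        if hsa not in _HSA_ORDER:
            raise AssemblyConflictError(f"unknown human chromosome {hsa!r}")
        ids.update(_block_ids(hsa, count))

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for a, b in adjacencies:
        for end in (a, b):
            if end not in ids:
                raise AssemblyConflictError(
                    f"adjacency {a}-{b} references block {end!r} not present "
                    f"in the block set")
        if graph.has_edge(a, b):
            raise AssemblyConflictError(f"duplicate adjacency {a}-{b}")
        graph.add_edge(a, b)

    for node, deg in graph.degree():
        if deg > 2:
            raise AssemblyConflictError(
                f"block {node} would join {deg} partners (branching chromosome)")

    def _key(bid: str) -> tuple:
        hsa = bid.rstrip("abcdef")
        return (_HSA_ORDER[hsa], bid)

    chromosomes: list[tuple[str, ...]] = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            chromosomes.append((next(iter(comp)),))
            continue
        if any(True for _ in nx.cycle_basis(sub.copy())):
            raise AssemblyConflictError(
                f"circular chromosome among blocks {sorted(comp)}")
        ends = sorted((n for n, d in sub.degree() if d == 1), key=_key)
        path = [ends[0]]
        prev = None
        while True:
            nxts = [n for n in sub.neighbors(path[-1]) if n != prev]
            if not nxts:
                break
            prev = path[-1]
            path.append(nxts[0])
        chromosomes.append(tuple(path))
    chromosomes.sort(key=lambda c: _key(c[0]))

    return AncestralKaryotype(blocks=dict(blocks), adjacencies=list(adjacencies),
                              chromosomes=chromosomes,
                              sex_chromosomes=sex_chromosomes,
                              provenance=provenance or {})


def karyotype_from_map(pmap: PaintingMap) -> AncestralKaryotype:
    """A tip's own karyotype in assembled form (layout-derived blocks and
    adjacencies; uncertain segments included)."""
    blocks: dict[str, int] = {}
    seen: dict[str, dict[str, str]] = {}
    for chrom in pmap.chromosomes:
        for seg in chrom.segments:
            blocks[seg.human_chromosome] = blocks.get(seg.human_chromosome, 0) + 1
    idmap: dict[tuple, str] = {}
    counters: dict[str, int] = {}
    for chrom in pmap.chromosomes:
        for seg in chrom.segments:
            hsa = seg.human_chromosome
            i = counters.get(hsa, 0)
            counters[hsa] = i + 1
            idmap[(chrom.chrom_id, id(seg))] = _block_ids(hsa, blocks[hsa])[i]
    adjacencies = []
    for chrom in pmap.chromosomes:
        labs = [idmap[(chrom.chrom_id, id(seg))] for seg in chrom.segments]
        adjacencies.extend(zip(labs, labs[1:]))
    return assemble_karyotype(blocks, adjacencies,
                              sex_chromosomes=pmap.sex_chromosome_count)


@dataclass
class InferenceConfig:
    """Everything the ancestral inference depends on, in one place."""

    engine: str = "fitch"
    tie_break: str = "outgroup"           # or "report"
    outgroup: str = "AEK"
    uncertainty_policy: str = "missing"
    overrides: dict[str, OutgroupOverride] = field(default_factory=dict)
    downweight_taxa: list[str] = field(default_factory=list)
    adjacencies: dict[str, list[list[str]]] = field(default_factory=dict)
    count_variants: dict[str, list[int]] = field(default_factory=dict)
    sex_chromosomes: int = 2

    @classmethod
    def from_dict(cls, raw: dict, overrides_raw: Optional[dict] = None) -> "InferenceConfig":
        ov = {}
        for label, spec in (overrides_raw or {}).items():
            ov[label] = OutgroupOverride(label, int(spec["state"]),
                                         spec.get("provenance", ""))
        return cls(
            engine=raw.get("engine", "fitch"),
            tie_break=raw.get("tie_break", "outgroup"),
            outgroup=raw.get("outgroup", "AEK"),
            uncertainty_policy=raw.get("uncertainty_policy", "missing"),
            overrides=ov,
            downweight_taxa=list(raw.get("downweight_taxa", []) or []),
            adjacencies={k: [list(p) for p in v]
                         for k, v in (raw.get("adjacencies", {}) or {}).items()},
            count_variants={str(k): [int(x) for x in v]
                            for k, v in (raw.get("count_variants", {}) or {}).items()},
        )


def _binary(state) -> Optional[int]:
    if state is None:
        return None
    if isinstance(state, tuple):
        return 1 if state[1] >= 1 else 0
    return 1 if state >= 1 else 0


def reconstruct_character(matrix: CharacterMatrix, tree, character: Character,
                          config: InferenceConfig) -> Reconstruction:
    """Run the configured engine for one character.

    Associations are reconstructed as ordered multiplicities (0/1/2 ...;
    identical to binary Fitch where multiplicities never exceed 1);
    fragment counts by ordered (Wagner) parsimony with the configured taxa
    down-weighted to missing.
    """
    t = tree if isinstance(tree, PhyloTree) else PhyloTree.from_dendropy(tree)
    states = dict(matrix.column(character))
    if character.kind == "fragment_count":
        for taxon in config.downweight_taxa:
            if taxon in states:
                states[taxon] = None
    return wagner_counts(t, states, character.label)


def infer_ancestral_states(matrix: CharacterMatrix, tree, node: str,
                           config: InferenceConfig):
    """Per-character reconstruction + resolution at ``node``.

    Returns ``(blocks, present_associations, provenance, unresolved)``:
    block counts per human chromosome, association label -> multiplicity
    for associations resolved present, a provenance record per character,
    and the labels left ambiguous (empty under outgroup tie-breaking with
    a resolvable outgroup).
    """
    t = tree if isinstance(tree, PhyloTree) else PhyloTree.from_dendropy(tree)
    t.index_of(node)  # raises KeyError for unknown nodes

    blocks: dict[str, int] = {}
    provenance: dict[str, dict] = {}
    present_assoc: dict[str, int] = {}
    unresolved: list[str] = []

    for ch in matrix.characters:
        rec = reconstruct_character(matrix, t, ch, config)
        res = resolve_ambiguity(
            rec, policy="outgroup" if config.tie_break == "outgroup" else "report",
            outgroup=config.outgroup, overrides=config.overrides, nodes=[node])[node]
        record = {
            "kind": ch.kind,
            "cost": rec.cost,
            "mpr_states": sorted(rec.node_states[node]),
            "state": res.state,
            "justification": res.justification,
        }
        provenance[ch.label] = record
        if res.state is None:
            unresolved.append(ch.label)
            continue
        if ch.kind == "fragment_count":
            blocks[ch.identity] = res.state
        elif res.state >= 1:
            present_assoc[ch.label] = res.state
    return blocks, present_assoc, provenance, unresolved


def infer_ancestral_karyotype(matrix: CharacterMatrix, tree, node: str,
                              config: InferenceConfig) -> AncestralKaryotype:
    """Reconstruct every character at ``node`` and assemble the karyotype.

    ``node`` may be an internal label (ancestral inference) or a tip (the
    result is that taxon's own scored state).  Every block count and
    adjacency carries a provenance record: parsimony cost, MPR state set at
    the node, and the tie-break or override used.
    """
    blocks, present_assoc, provenance, unresolved = infer_ancestral_states(
        matrix, tree, node, config)

    if unresolved and config.tie_break != "outgroup":
        raise AssemblyConflictError(
            "ambiguous characters under policy 'report': " + ", ".join(unresolved))

    adjacencies: list[tuple[str, str]] = []
    for label, mult in sorted(present_assoc.items()):
        table = config.adjacencies.get(label)
        if table is None:
            raise AssemblyConflictError(
                f"association {label} inferred present at {node} but no "
                f"sub-block assignment is configured for it")
        if len(table) < mult:
            raise AssemblyConflictError(
                f"association {label} inferred with multiplicity {mult} but "
                f"only {len(table)} junction assignments configured")
        for pair in table[:mult]:
            adjacencies.append((pair[0], pair[1]))

    karyotype = assemble_karyotype(blocks, adjacencies,
                                   sex_chromosomes=config.sex_chromosomes,
                                   provenance=provenance)

    for hsa, alt_counts in config.count_variants.items():
        for alt in alt_counts:
            alt_blocks = dict(blocks)
            alt_blocks[hsa] = alt
            try:
                variant = assemble_karyotype(alt_blocks, adjacencies,
                                             sex_chromosomes=config.sex_chromosomes)
            except AssemblyConflictError:
                continue
            karyotype.variants[f"HSA{hsa}={alt}"] = variant
    return karyotype


@dataclass
class KaryotypeDifference:
    """Symmetric difference between two assembled karyotypes."""

    adjacencies_only_a: dict[str, int]
    adjacencies_only_b: dict[str, int]
    count_differences: dict[str, tuple[int, int]]
    diploid_delta: int

    @property
    def empty(self) -> bool:
        return not (self.adjacencies_only_a or self.adjacencies_only_b
                    or self.count_differences or self.diploid_delta)


def compare_karyotypes(a: AncestralKaryotype, b: AncestralKaryotype) -> KaryotypeDifference:
    am, bm = a.association_multiset(), b.association_multiset()
    only_a = {k: am[k] - bm.get(k, 0) for k in am if am[k] > bm.get(k, 0)}
    only_b = {k: bm[k] - am.get(k, 0) for k in bm if bm[k] > am.get(k, 0)}
    counts = {}
    for hsa in set(a.blocks) | set(b.blocks):
        ca, cb = a.blocks.get(hsa, 0), b.blocks.get(hsa, 0)
        if ca != cb:
            counts[hsa] = (ca, cb)
    return KaryotypeDifference(only_a, only_b, counts,
                               a.diploid_number - b.diploid_number)
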