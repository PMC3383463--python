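"""Simulate karyotype evolution by chromosome fusions and fissions along a
tree, emitting painting maps with full ground truth.

The process mirrors what comparative painting can actually observe: whole
chromosomes end-join (centric-fusion-like, creating associations) and
blocks split (fissions, raising a human chromosome's fragment count).  No
translocations or inversions are generated — the character system is blind
to them.  Events arrive as a Poisson process per branch (branch length
defaults to 1); the X is held immune, matching its conservation across the
study group.  Probe-failure masking and extra unpainted heterochromatic
pairs emulate the missing-data structure of real experiments.

Event algebra, checked per tip by the test-suite:

    segments(tip)    = segments(ancestor)    + fissions on the root path
    chromosomes(tip) = chromosomes(ancestor) + fissions - fusions

Every run is reproducible from its seed, and the event log replays from the
ancestor to the exact tip karyotypes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .karyo_model import BlockLabel, PaintedChromosome, PaintingMap
from .karyotype_assembly import AncestralKaryotype
from .parsimony import PhyloTree

__all__ = [
    "SimulationConfig",
    "Event",
    "EventLog",
    "SimulationResult",
    "simulate",
    "mask_probes",
    "recovered_root_summary",
    "adjacency_f1",
]

# internal karyotype state: list of chromosomes, chromosome = list of block
# ids; registry maps block id -> human chromosome
_Karyotype = list


@dataclass
class SimulationConfig:
    tree: Union[str, PhyloTree]
    ancestor: AncestralKaryotype
    fusion_rate: float = 0.1            # expected fusions per unit branch length
    fission_rate: float = 0.1
    probe_failure_prob: float = 0.0
    unpainted_pair_prob: float = 0.0
    seed: int = 0
    #: planted events: (branch label, ancestral block id, ancestral block id)
    #: fused head-to-head on that branch before any random events
    forced_fusions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fusion_rate < 0 or self.fission_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass(frozen=True)
class Event:
    branch: str                 # label of the child node of the branch
    kind: str                   # "fusion" | "fission" | "fusion-refused"
    operands: tuple


@dataclass
class EventLog:
    events: list[Event]
    node_karyotypes: dict[str, list[tuple[int, ...]]]
    registry: dict[int, str]    # block id -> human chromosome

    def events_on_path(self, tree: PhyloTree, tip: str) -> list[Event]:
        path = set()
        i = tree.index_of(tip)
        while i != -1:
            path.add(tree.labels[i])
            i = tree.parent[i]
        return [e for e in self.events if e.branch in path]

    def count_on_path(self, tree: PhyloTree, tip: str, kind: str) -> int:
        return sum(1 for e in self.events_on_path(tree, tip) if e.kind == kind)

    def replay(self, tree: PhyloTree) -> dict[str, list[tuple[int, ...]]]:
        """Re-apply the logged events from the ancestral karyotype; returns
        the karyotype at every node (the log is self-sufficient)."""
        root = tree.labels[tree.root]
        state = {root: [list(c) for c in self.node_karyotypes[root]]}
        by_branch: dict[str, list[Event]] = {}
        for e in self.events:
            by_branch.setdefault(e.branch, []).append(e)
        out = {root: [tuple(c) for c in state[root]]}
        order = list(reversed(range(tree.n_nodes)))  # parents before children
        for i in order:
            p = tree.parent[i]
            if p == -1:
                continue
            lab, plab = tree.labels[i], tree.labels[p]
            kar = [list(c) for c in state[plab]]
            for e in by_branch.get(lab, []):
                kar = _apply_event(kar, e)
            state[lab] = kar
            out[lab] = [tuple(c) for c in kar]
        return out


@dataclass
class SimulationResult:
    maps: dict[str, PaintingMap]
    log: EventLog
    config: SimulationConfig


def _apply_event(kar: _Karyotype, event: Event) -> _Karyotype:
    if event.kind == "fusion-refused":
        return kar
    if event.kind == "fusion":
        a, b, flip_a, flip_b = event.operands
        ca = next(c for c in kar if tuple(c) == tuple(a))
        cb = next(c for c in kar if tuple(c) == tuple(b))
        kar = [c for c in kar if c is not ca and c is not cb]
        left = list(reversed(ca)) if flip_a else list(ca)
        right = list(reversed(cb)) if flip_b else list(cb)
        kar.append(left + right)
        return kar
    if event.kind == "fission":
        block, left_id, right_id = event.operands
        for c in kar:
            if block in c:
                i = c.index(block)
                left = c[:i] + [left_id]
                right = [right_id] + c[i + 1:]
                kar = [x for x in kar if x is not c]
                kar.extend([left, right])
                return kar
        raise ValueError(f"replay: block {block} not found")
    raise ValueError(event.kind)


def _ancestor_state(ancestor: AncestralKaryotype):
    registry: dict[int, str] = {}
    kar: _Karyotype = []
    sex: _Karyotype = []
    next_id = 0
    for chrom in ancestor.chromosomes:
        ids = []
        for bid in chrom:
            hsa = bid.rstrip("abcdef")
            registry[next_id] = hsa
            ids.append(next_id)
            next_id += 1
        (sex if any(registry[i] == "X" for i in ids) else kar).append(ids)
    return kar, sex, registry, next_id


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the fusion/fission process and emit per-tip painting maps."""
    tree = config.tree if isinstance(config.tree, PhyloTree) \
        else PhyloTree.from_newick(config.tree)
    rng = np.random.default_rng(config.seed)
    kar0, sex0, registry, next_id = _ancestor_state(config.ancestor)

    events: list[Event] = []
    node_karyotypes: dict[str, list[tuple[int, ...]]] = {}
    root_lab = tree.labels[tree.root]
    node_karyotypes[root_lab] = [tuple(c) for c in kar0]
    state: dict[str, _Karyotype] = {root_lab: kar0}

    def do_fusion(kar: _Karyotype, branch: str) -> _Karyotype:
        nonlocal events
        if len(kar) < 2:
            events.append(Event(branch, "fusion-refused",
                                ("no two autosomes to fuse",)))
            return kar
        ia, ib = rng.choice(len(kar), size=2, replace=False)
        flip_a, flip_b = bool(rng.integers(2)), bool(rng.integers(2))
        a, b = kar[ia], kar[ib]
        events.append(Event(branch, "fusion",
                            (tuple(a), tuple(b), flip_a, flip_b)))
        return _apply_event(kar, events[-1])

    def do_fission(kar: _Karyotype, branch: str) -> _Karyotype:
        nonlocal events, next_id
        blocks = [b for c in kar for b in c]
        block = int(blocks[rng.integers(len(blocks))])
        left_id, right_id = next_id, next_id + 1
        next_id += 2
        registry[left_id] = registry[block]
        registry[right_id] = registry[block]
        events.append(Event(branch, "fission", (block, left_id, right_id)))
        return _apply_event(kar, events[-1])

    block_name_to_id = {}
    for chrom in config.ancestor.chromosomes:
        for bid in chrom:
            block_name_to_id.setdefault(bid, len(block_name_to_id))

    def do_forced_fusion(kar: _Karyotype, branch: str, name_a: str,
                         name_b: str) -> _Karyotype:
        ida, idb = block_name_to_id[name_a], block_name_to_id[name_b]
        ca = next((c for c in kar if ida in c), None)
        cb = next((c for c in kar if idb in c), None)
        if ca is None or cb is None or ca is cb:
            events.append(Event(branch, "fusion-refused",
                                (f"forced fusion {name_a}+{name_b} not applicable",)))
            return kar
        # orient so the named blocks meet at the junction
        left = list(reversed(ca)) if ca.index(ida) != len(ca) - 1 else list(ca)
        right = list(reversed(cb)) if cb.index(idb) != 0 else list(cb)
        events.append(Event(branch, "fusion",
                            (tuple(ca), tuple(cb),
                             ca.index(ida) != len(ca) - 1,
                             cb.index(idb) != 0)))
        kar = [c for c in kar if c is not ca and c is not cb]
        kar.append(left + right)
        return kar

    for i in reversed(range(tree.n_nodes)):  # parents before children
        p = tree.parent[i]
        if p == -1:
            continue
        lab = tree.labels[i]
        kar = [list(c) for c in state[tree.labels[p]]]
        for branch, name_a, name_b in config.forced_fusions:
            if branch == lab:
                kar = do_forced_fusion(kar, lab, name_a, name_b)
        blen = tree.edge_length[i]
        n_fus = rng.poisson(config.fusion_rate * blen)
        n_fis = rng.poisson(config.fission_rate * blen)
        order = ["fusion"] * n_fus + ["fission"] * n_fis
        rng.shuffle(order)
        for kind in order:
            kar = do_fusion(kar, lab) if kind == "fusion" else do_fission(kar, lab)
        state[lab] = kar
        node_karyotypes[lab] = [tuple(c) for c in kar]

    maps = {}
    for tip in tree.tip_labels:
        maps[tip] = _emit_map(tip, state[tip], sex0, registry, rng,
                              config.unpainted_pair_prob)
    if config.probe_failure_prob > 0:
        maps = mask_probes(maps, config.probe_failure_prob,
                           seed=int(rng.integers(2 ** 31)))
    return SimulationResult(maps=maps, log=EventLog(events, node_karyotypes,
                                                    dict(registry)),
                            config=config)


def _emit_map(taxon: str, kar: _Karyotype, sex: _Karyotype,
              registry: dict[int, str], rng, unpainted_pair_prob: float) -> PaintingMap:
    hsa_total: dict[str, int] = {}
    for c in kar + sex:
        for b in c:
            hsa_total[registry[b]] = hsa_total.get(registry[b], 0) + 1
    seen: dict[str, int] = {}
    chromosomes = []
    for n, c in enumerate(sorted(kar, key=lambda c: [registry[b] for b in c]), 1):
        segs = []
        for b in c:
            hsa = registry[b]
            k = seen.get(hsa, 0)
            seen[hsa] = k + 1
            sub = chr(ord("a") + k) if hsa_total[hsa] > 1 else None
            segs.append(BlockLabel(hsa, sub_block=sub))
        chromosomes.append(PaintedChromosome(chrom_id=f"{taxon}.{n:02d}",
                                             segments=segs))
    for c in sex:
        segs = []
        for b in c:
            hsa = registry[b]
            k = seen.get(hsa, 0)
            seen[hsa] = k + 1
            sub = chr(ord("a") + k) if hsa_total[hsa] > 1 else None
            segs.append(BlockLabel(hsa, sub_block=sub))
        chromosomes.append(PaintedChromosome(chrom_id=f"{taxon}.X",
                                             segments=segs,
                                             is_sex_chromosome=True))
    unpainted = []
    if unpainted_pair_prob > 0 and rng.random() < unpainted_pair_prob:
        unpainted.append(f"{taxon}.het1")
    n_autosomes = len(kar) + len(unpainted)
    return PaintingMap(taxon=taxon,
                       diploid_number_reported=2 * n_autosomes + 2,
                       chromosomes=chromosomes,
                       unpainted_pairs=unpainted,
                       sex_chromosome_count=2)


def recovered_root_summary(result: SimulationResult):
    """Reconstruct the root state from a simulation's tip maps alone.

    Builds the character matrix from the emitted maps, runs ordered
    parsimony per character and takes the conservative (minimum) root
    state over all MPRs — no outgroup exists in a simulated tree, so
    ambiguity is resolved downward.  Returns ``(association multiset,
    block counts)`` at the human-chromosome level, for scoring against
    ``result.config.ancestor``.
    """
    from .character_extraction import build_character_matrix
    from .parsimony import wagner_counts

    tree = result.config.tree if isinstance(result.config.tree, PhyloTree) \
        else PhyloTree.from_newick(result.config.tree)
    matrix = build_character_matrix(result.maps)
    root = tree.labels[tree.root]
    assoc: dict[str, int] = {}
    counts: dict[str, int] = {}
    for ch in matrix.characters:
        rec = wagner_counts(tree, matrix.column(ch), ch.label)
        state = min(rec.node_states[root])
        if ch.kind == "association":
            if state >= 1:
                assoc[ch.label] = state
        else:
            counts[ch.identity] = state
    return assoc, counts


def adjacency_f1(truth: dict[str, int], predicted: dict[str, int]) -> float:
    """F1 between two association multisets (human-chromosome level)."""
    tp = sum(min(truth.get(k, 0), predicted.get(k, 0))
             for k in set(truth) | set(predicted))
    n_true = sum(truth.values())
    n_pred = sum(predicted.values())
    if n_true == 0 and n_pred == 0:
        return 1.0
    if tp == 0:
        return 0.0
    precision = tp / n_pred
    recall = tp / n_true
    return 2 * precision * recall / (precision + recall)


def mask_probes(maps: dict[str, PaintingMap], probe_failure_prob: float,
                seed: int) -> dict[str, PaintingMap]:
    """Independently drop each human probe per taxon; a chromosome whose
    every segment came from failed probes becomes an unpainted pair (the
    experimentalist would see no signal on it at all)."""
    rng = np.random.default_rng(seed)
    out = {}
    for taxon in maps:
        pmap = copy.deepcopy(maps[taxon])
        probes = sorted({s.human_chromosome for c in pmap.chromosomes
                         for s in c.segments if not c.is_sex_chromosome})
        failed = {h for h in probes if rng.random() < probe_failure_prob}
        if failed:
            kept = []
            for chrom in pmap.chromosomes:
                remaining = [s for s in chrom.segments
                             if s.human_chromosome not in failed]
                dropped = len(chrom.segments) - len(remaining)
                if not remaining and not chrom.is_sex_chromosome:
                    pmap.unpainted_pairs.append(chrom.chrom_id)
                    continue
                chrom.segments = remaining
                chrom.unpainted_regions += dropped
                chrom.uncertain_segments = frozenset()
                kept.append(chrom)
            pmap.chromosomes = kept
            pmap.probes_failed |= failed
        out[taxon] = pmap
    return out
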