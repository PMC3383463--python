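"""Ancestral-state reconstruction on a fixed rooted tree.

Three small-parsimony engines over integer character states:

* :func:`fitch_reconstruct` — unweighted minimum-change (Fitch) for binary
  presence/absence characters, with full enumeration of most-parsimonious
  reconstructions (MPRs) on small trees;
* :func:`wagner_counts` — ordered (Wagner) parsimony for block counts and
  association multiplicities, cost ``|parent - child|`` per branch, with
  range and missing tip states;
* :func:`dollo_reconstruct` — single origin of the derived (present) state,
  unlimited losses.

All engines run the generalized Sankoff dynamic programme (up pass for
subtree costs, down pass for out-of-subtree costs), so per-node MPR state
sets are exact; explicit MPR enumeration uses the decomposition of joint
optima over edges.  :func:`brute_force_min_changes` enumerates every
internal assignment outright and is the test oracle.

Missing tips constrain nothing; range tips are free within their bounds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import dendropy

__all__ = [
    "PhyloTree",
    "Reconstruction",
    "OutgroupOverride",
    "fitch_reconstruct",
    "wagner_counts",
    "dollo_reconstruct",
    "brute_force_min_changes",
    "resolve_ambiguity",
]

INF = float("inf")
State = Union[int, tuple, None]  # int, (lo, hi) range, or missing


# ---------------------------------------------------------------------------
# tree adapter


@dataclass
class PhyloTree:
    """Rooted tree as parallel arrays in postorder.

    ``parent[i]`` indexes the parent of node ``i`` (root: -1); tips carry
    taxon labels, internal nodes their Newick labels (auto-named ``N<k>``
    when anonymous).  Polytomies are kept as-is.
    """

    labels: list[str]
    parent: list[int]
    children: list[list[int]]
    is_tip: list[bool]
    edge_length: list[float]

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        labels, parent, children, is_tip, elen = [], [], [], [], []
        anon = itertools.count(1)
        for n in nodes:
            if n.is_leaf():
                lab = n.taxon.label if n.taxon else (n.label or f"T{next(anon)}")
            else:
                lab = (n.taxon.label if n.taxon else None) or n.label or f"N{next(anon)}"
            labels.append(lab.replace(" ", "_"))
            parent.append(index[id(n.parent_node)] if n.parent_node else -1)
            children.append([index[id(c)] for c in n.child_nodes()])
            is_tip.append(n.is_leaf())
            elen.append(n.edge.length if n.edge.length is not None else 1.0)
        return cls(labels, parent, children, is_tip, elen)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        from .painting_io import read_tree

        return cls.from_dendropy(read_tree(newick))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.parent.index(-1)

    @property
    def tip_labels(self) -> list[str]:
        return [l for l, t in zip(self.labels, self.is_tip) if t]

    @property
    def internal_indices(self) -> list[int]:
        return [i for i, t in enumerate(self.is_tip) if not t]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def clade_tips(self, node: int) -> list[str]:
        stack, out = [node], []
        while stack:
            i = stack.pop()
            if self.is_tip[i]:
                out.append(self.labels[i])
            else:
                stack.extend(self.children[i])
        return out

    def mrca(self, tip_labels: Sequence[str]) -> int:
        want = set(tip_labels)
        below = [set() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_tip[i]:
                below[i] = {self.labels[i]}
            else:
                for c in self.children[i]:
                    below[i] |= below[c]
        candidates = [i for i in range(self.n_nodes) if want <= below[i]]
        if not candidates:
            raise KeyError(f"tips {sorted(want)} not all present in tree")
        return min(candidates, key=lambda i: len(below[i]))


def _coerce_tree(tree) -> PhyloTree:
    if isinstance(tree, PhyloTree):
        return tree
    if isinstance(tree, dendropy.Tree):
        return PhyloTree.from_dendropy(tree)
    if isinstance(tree, str):
        return PhyloTree.from_newick(tree)
    raise TypeError(f"cannot interpret {type(tree)} as a tree")


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class OutgroupOverride:
    """Asserted deep-outgroup state for one character, with provenance."""

    character: str
    state: int
    provenance: str = ""


@dataclass
class Reconstruction:
    """All most-parsimonious reconstructions of one character."""

    character: str
    tree: PhyloTree
    cost: float
    node_states: dict[str, frozenset]      # states across all MPRs, per node
    mprs: list[dict[str, int]]             # full assignments (may be capped)
    mpr_events: list[list[tuple]]          # per MPR: (child_label, from, to)
    engine: str
    method: str = "sankoff-enumeration"
    enumeration_complete: bool = True

    @property
    def ambiguous_nodes(self) -> set[str]:
        return {lab for lab, s in self.node_states.items() if len(s) > 1}

    def state_at(self, label: str) -> frozenset:
        return self.node_states[label]

    def events_on_stem(self, label: str) -> list[list[tuple]]:
        """Per MPR, the events on the branch entering ``label``."""
        return [[e for e in ev if e[0] == label] for ev in self.mpr_events]


# ---------------------------------------------------------------------------
# Sankoff engine


def _tip_cost(state: State, domain: Sequence[int]) -> list[float]:
    if state is None:
        return [0.0] * len(domain)
    if isinstance(state, tuple):
        lo, hi = state
        return [0.0 if lo <= s <= hi else INF for s in domain]
    return [0.0 if s == state else INF for s in domain]


def _domain_for(tip_states: dict[str, State]) -> list[int]:
    vals = []
    for s in tip_states.values():
        if s is None:
            continue
        vals.extend(s if isinstance(s, tuple) else (s,))
    if not vals:
        return [0]
    return list(range(min(min(vals), 0), max(vals) + 1))


def _sankoff(tree: PhyloTree, tip_states: dict[str, State],
             domain: Sequence[int], step: Callable[[int, int], float],
             character: str, engine: str,
             max_mprs: int = 20000) -> Reconstruction:
    missing_tips = set(tip_states) - set(tree.tip_labels)
    if missing_tips:
        raise KeyError(f"taxa absent from tree: {sorted(missing_tips)}")

    k = len(domain)
    up = [[0.0] * k for _ in range(tree.n_nodes)]
    for i in range(tree.n_nodes):
        if tree.is_tip[i]:
            up[i] = _tip_cost(tip_states.get(tree.labels[i]), domain)
        else:
            for si in range(k):
                up[i][si] = sum(
                    min(up[c][ti] + step(domain[si], domain[ti]) for ti in range(k))
                    for c in tree.children[i])

    root = tree.root
    cost = min(up[root])

    # down pass: cost of the rest of the tree given this node's state
    down = [[0.0] * k for _ in range(tree.n_nodes)]
    for i in reversed(range(tree.n_nodes)):  # preorder over postorder arrays
        p = tree.parent[i]
        if p == -1:
            continue
        sib_cost = [0.0] * k
        for sp in range(k):
            sib_cost[sp] = down[p][sp] + sum(
                min(up[c][tc] + step(domain[sp], domain[tc]) for tc in range(k))
                for c in tree.children[p] if c != i)
        for si in range(k):
            down[i][si] = min(sib_cost[sp] + step(domain[sp], domain[si])
                              for sp in range(k))

    node_states = {}
    for i in range(tree.n_nodes):
        opt = frozenset(domain[si] for si in range(k)
                        if up[i][si] + down[i][si] == cost)
        node_states[tree.labels[i]] = opt

    # enumerate MPRs: choose root state, then per child every cost-achieving
    # state; additive costs make every greedy-consistent assignment optimal.
    mprs: list[dict[str, int]] = []
    complete = True
    assignment: dict[int, int] = {}

    def recurse(order_pos: int, preorder: list[int]) -> None:
        nonlocal complete
        if len(mprs) >= max_mprs:
            complete = False
            return
        if order_pos == len(preorder):
            mprs.append({tree.labels[i]: domain[si] for i, si in assignment.items()})
            return
        i = preorder[order_pos]
        p = tree.parent[i]
        if p == -1:
            choices = [si for si in range(k) if up[i][si] == cost]
        else:
            sp = assignment[p]
            best = min(up[i][ti] + step(domain[sp], domain[ti]) for ti in range(k))
            choices = [si for si in range(k)
                       if up[i][si] + step(domain[sp], domain[si]) == best]
        for si in choices:
            assignment[i] = si
            recurse(order_pos + 1, preorder)
            del assignment[i]

    preorder = list(reversed(range(tree.n_nodes)))
    recurse(0, preorder)

    mpr_events = []
    for mpr in mprs:
        ev = []
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p == -1:
                continue
            a, b = mpr[tree.labels[p]], mpr[tree.labels[i]]
            if a != b:
                ev.append((tree.labels[i], a, b))
        mpr_events.append(ev)

    return Reconstruction(character=character, tree=tree, cost=cost,
                          node_states=node_states, mprs=mprs,
                          mpr_events=mpr_events, engine=engine,
                          enumeration_complete=complete)


def _unordered_step(a: int, b: int) -> float:
    return 0.0 if a == b else 1.0


def _ordered_step(a: int, b: int) -> float:
    return float(abs(a - b))


def fitch_reconstruct(tree, tip_states: dict[str, State],
                      character: str = "") -> Reconstruction:
    """Unweighted (Fitch) parsimony with full MPR enumeration.

    ``tip_states`` maps taxon -> 0/1 (or small unordered multistate);
    missing (None) tips constrain nothing.
    """
    t = _coerce_tree(tree)
    domain = sorted(set(_domain_for(tip_states)) | {0, 1})
    return _sankoff(t, tip_states, domain, _unordered_step, character, "fitch")


def wagner_counts(tree, tip_states: dict[str, State],
                  character: str = "") -> Reconstruction:
    """Ordered parsimony on integer counts: minimises total |parent-child|.
    Range tips (lo, hi) are free within their bounds."""
    t = _coerce_tree(tree)
    return _sankoff(t, tip_states, _domain_for(tip_states), _ordered_step,
                    character, "wagner")


def dollo_reconstruct(tree, tip_states: dict[str, State],
                      character: str = "") -> Reconstruction:
    """Single-origin parsimony: one gain of the present state on the stem of
    the minimal clade spanning all present tips, losses wherever a maximal
    subclade of that clade has only absent (non-missing) tips.

    The Dollo reconstruction under this rule is unique, so the result
    carries exactly one MPR.
    """
    t = _coerce_tree(tree)
    present = [lab for lab, s in tip_states.items()
               if s is not None and (s[1] if isinstance(s, tuple) else s) >= 1]
    assignment: dict[str, int] = {}
    if not present:
        for lab in t.labels:
            assignment[lab] = 0
        events: list[tuple] = []
        cost = 0.0
    else:
        gain_node = t.mrca(present)
        inside = set()
        stack = [gain_node]
        while stack:
            i = stack.pop()
            inside.add(i)
            stack.extend(t.children[i])
        # a node keeps the state while some present tip descends from it
        has_present = [False] * t.n_nodes
        for i in range(t.n_nodes):
            if t.is_tip[i]:
                s = tip_states.get(t.labels[i])
                has_present[i] = (s is not None
                                  and (s[1] if isinstance(s, tuple) else s) >= 1)
            else:
                has_present[i] = any(has_present[c] for c in t.children[i])
        events = []
        for i in reversed(range(t.n_nodes)):  # parents before children
            lab = t.labels[i]
            if i not in inside:
                assignment[lab] = 0
                continue
            if i == gain_node:
                assignment[lab] = 1
                events.append((lab, 0, 1))
                continue
            p = t.parent[i]
            parent_present = assignment[t.labels[p]] == 1
            if t.is_tip[i]:
                s = tip_states.get(lab)
                if s is None:
                    assignment[lab] = 1 if parent_present else 0
                else:
                    assignment[lab] = 1 if has_present[i] else 0
            else:
                assignment[lab] = 1 if has_present[i] else 0
            if parent_present and assignment[lab] == 0:
                events.append((lab, 1, 0))
            # no regains under Dollo: parent absent -> children stay absent
        cost = float(len(events))

    node_states = {lab: frozenset({s}) for lab, s in assignment.items()}
    return Reconstruction(character=character, tree=t, cost=cost,
                          node_states=node_states, mprs=[assignment],
                          mpr_events=[events], engine="dollo",
                          method="dollo-direct")


def brute_force_min_changes(tree, tip_states: dict[str, State],
                            ordered: bool = False,
                            character: str = "",
                            max_internal: int = 12) -> Reconstruction:
    """Exhaustive enumeration over all internal-node assignments.

    Authoritative oracle for the DP engines; refuses trees with more than
    ``max_internal`` internal nodes.
    """
    t = _coerce_tree(tree)
    internals = t.internal_indices
    if len(internals) > max_internal:
        raise ValueError(f"brute force refused: {len(internals)} internal nodes")
    step = _ordered_step if ordered else _unordered_step
    domain = _domain_for(tip_states) if ordered else \
        sorted(set(_domain_for(tip_states)) | {0, 1})

    tip_options: dict[int, list[int]] = {}
    for i in range(t.n_nodes):
        if t.is_tip[i]:
            s = tip_states.get(t.labels[i])
            if s is None:
                tip_options[i] = list(domain)
            elif isinstance(s, tuple):
                tip_options[i] = [v for v in domain if s[0] <= v <= s[1]]
            else:
                tip_options[i] = [s]

    tip_idx = [i for i in range(t.n_nodes) if t.is_tip[i]]
    free_tips = [i for i in tip_idx if len(tip_options[i]) > 1]
    fixed = {i: tip_options[i][0] for i in tip_idx if len(tip_options[i]) == 1}

    best_cost = INF
    best: list[dict[int, int]] = []
    for internal_combo in itertools.product(domain, repeat=len(internals)):
        base = dict(fixed)
        base.update(dict(zip(internals, internal_combo)))
        for tip_combo in itertools.product(*(tip_options[i] for i in free_tips)):
            assign = dict(base)
            assign.update(dict(zip(free_tips, tip_combo)))
            c = 0.0
            for i in range(t.n_nodes):
                p = t.parent[i]
                if p != -1:
                    c += step(assign[p], assign[i])
                    if c > best_cost:
                        break
            if c < best_cost:
                best_cost, best = c, [assign]
            elif c == best_cost:
                best.append(assign)

    node_states: dict[str, set] = {lab: set() for lab in t.labels}
    mprs, mpr_events = [], []
    for assign in best:
        mpr = {t.labels[i]: s for i, s in assign.items()}
        mprs.append(mpr)
        ev = []
        for i in range(t.n_nodes):
            p = t.parent[i]
            if p != -1 and assign[p] != assign[i]:
                ev.append((t.labels[i], assign[p], assign[i]))
        mpr_events.append(ev)
        for lab, s in mpr.items():
            node_states[lab].add(s)

    return Reconstruction(character=character, tree=t, cost=best_cost,
                          node_states={k: frozenset(v) for k, v in node_states.items()},
                          mprs=mprs, mpr_events=mpr_events,
                          engine="brute-force", method="exhaustive")


# ---------------------------------------------------------------------------
# ambiguity resolution


@dataclass
class Resolution:
    """Resolved state for one node plus the justification trail."""

    node: str
    state: Optional[int]
    ambiguous_set: frozenset
    justification: str


def resolve_ambiguity(rec: Reconstruction, policy: str = "outgroup",
                      outgroup: Optional[str] = None,
                      overrides: Optional[dict[str, OutgroupOverride]] = None,
                      nodes: Optional[Sequence[str]] = None) -> dict[str, Resolution]:
    """Collapse per-node MPR state sets to single states.

    ``policy="report"`` keeps ambiguity (state=None where sets have >1
    element).  ``policy="outgroup"`` consults the override table for this
    character first, then the outgroup tip's own state, picking the nearest
    member of the MPR state set; every choice is annotated.
    """
    if policy not in ("outgroup", "report"):
        raise ValueError(f"unknown policy {policy!r}")
    overrides = overrides or {}
    node_list = list(nodes) if nodes is not None else list(rec.node_states)
    out: dict[str, Resolution] = {}

    ref_state: Optional[int] = None
    ref_why = ""
    ov = overrides.get(rec.character)
    if ov is not None:
        ref_state = ov.state
        ref_why = f"deep-outgroup override ({ov.provenance or 'configured'})"
    elif outgroup is not None:
        og_set = rec.node_states.get(outgroup)
        if og_set and len(og_set) == 1:
            ref_state = next(iter(og_set))
            ref_why = f"outgroup {outgroup} state {ref_state}"

    for lab in node_list:
        sset = rec.node_states[lab]
        if len(sset) == 1:
            out[lab] = Resolution(lab, next(iter(sset)), sset, "unambiguous")
            continue
        if policy == "report":
            out[lab] = Resolution(lab, None, sset, "ambiguity retained (policy=report)")
            continue
        if ref_state is None:
            out[lab] = Resolution(lab, None, sset,
                                  "ambiguous; no outgroup/override available")
            continue
        chosen = min(sset, key=lambda s: (abs(s - ref_state), s))
        out[lab] = Resolution(lab, chosen, sset,
                              f"resolved from {sorted(sset)} by {ref_why}")
    return out
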