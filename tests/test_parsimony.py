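"""Parsimony engines versus the exhaustive oracle, plus the study's
documented reconstructions."""

import numpy as np
import pytest

from karyoanc.parsimony import (
    OutgroupOverride,
    PhyloTree,
    brute_force_min_changes,
    dollo_reconstruct,
    fitch_reconstruct,
    resolve_ambiguity,
    wagner_counts,
)

from .conftest import binary_column


def random_binary_newick(n_tips, rng):
    nodes = [f"t{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


class TestStudyReconstructions:
    def test_11_19_two_convergent_gains(self, matrix, tree):
        # present in B. tridactylus and E. sexcinctus only: two independent
        # gains, the ancestral Xenarthra state is absent in every MPR
        rec = fitch_reconstruct(tree, binary_column(matrix, "11/19"))
        assert rec.cost == 2
        assert rec.node_states["Xenarthra"] == frozenset({0})

    def test_2_8_three_convergent_gains(self, matrix, tree):
        rec = fitch_reconstruct(tree, binary_column(matrix, "2/8"))
        assert rec.cost == 3
        assert rec.node_states["Xenarthra"] == frozenset({0})

    def test_16_19_exactly_two_loss_scenarios(self, matrix, tree):
        # either lost on the Bradypus stem and again in C. didactylus, or
        # lost on the sloth (Folivora) stem and regained in C. hoffmanni
        rec = fitch_reconstruct(tree, binary_column(matrix, "16/19"))
        assert rec.cost == 2
        assert rec.node_states["Xenarthra"] == frozenset({1})
        scenarios = {(m["Folivora"], m["Bradypus"], m["Choloepus"])
                     for m in rec.mprs}
        assert scenarios == {(1, 0, 1), (0, 0, 0)}
        assert len(rec.mprs) == 2

    def test_7_10_ambiguous_resolved_by_deep_outgroup(self, matrix, tree):
        rec = fitch_reconstruct(tree, binary_column(matrix, "7/10"), "7/10")
        assert rec.cost == 3
        assert rec.node_states["Xenarthra"] == frozenset({0, 1})
        ov = {"7/10": OutgroupOverride("7/10", 1, "opossum chr 8 / chicken chr 1")}
        res = resolve_ambiguity(rec, "outgroup", outgroup="AEK", overrides=ov,
                                nodes=["Xenarthra"])["Xenarthra"]
        assert res.state == 1
        assert "override" in res.justification

    def test_constant_character_costs_nothing(self, matrix, tree):
        rec = fitch_reconstruct(tree, binary_column(matrix, "4/8"))
        assert rec.cost == 0
        assert all(s == frozenset({1}) for s in rec.node_states.values())

    def test_resolution_noop_on_unambiguous(self, matrix, tree):
        rec = fitch_reconstruct(tree, binary_column(matrix, "2/8"))
        res = resolve_ambiguity(rec, "outgroup", outgroup="AEK")
        assert res["Xenarthra"].state == 0
        assert res["Xenarthra"].justification == "unambiguous"

    def test_report_policy_preserves_ambiguity(self, matrix, tree):
        rec = fitch_reconstruct(tree, binary_column(matrix, "7/10"))
        res = resolve_ambiguity(rec, "report", nodes=["Xenarthra"])["Xenarthra"]
        assert res.state is None
        assert res.ambiguous_set == frozenset({0, 1})

    def test_hsa8_gains_a_block_on_the_xenarthra_stem(self, matrix, tree):
        rec = wagner_counts(tree, matrix.column(matrix.get("n8")))
        assert rec.node_states["Xenarthra"] == frozenset({3})
        res = resolve_ambiguity(rec, "outgroup", outgroup="AEK")
        root_steps = {(m["Eutheria"], m["Xenarthra"]) for m in rec.mprs}
        assert (2, 3) in root_steps  # a single +1 step on the stem

    def test_hsa6_ambiguous_between_one_and_two(self, matrix, tree):
        rec = wagner_counts(tree, matrix.column(matrix.get("n6")))
        assert rec.node_states["Xenarthra"] == frozenset({1, 2})
        res = resolve_ambiguity(rec, "outgroup", outgroup="AEK",
                                nodes=["Xenarthra"])["Xenarthra"]
        assert res.state == 1  # outgroup preference, as the study proposes

    def test_dollo_7_10_single_gain_two_losses(self, matrix, tree):
        rec = dollo_reconstruct(tree, binary_column(matrix, "7/10"))
        assert rec.cost == 3  # 1 gain + 2 losses
        assert rec.node_states["Xenarthra"] == frozenset({1})
        events = rec.mpr_events[0]
        assert ("Xenarthra", 0, 1) in events
        losers = {e[0] for e in events if e[2] == 0}
        assert losers == {"Choloepus_hoffmanni", "Dasypus_novemcinctus"}

    def test_dollo_single_tip_terminal_gain(self, matrix, tree):
        states = {t: 0 for t in tree.tip_labels}
        states["Bradypus_torquatus"] = 1
        rec = dollo_reconstruct(tree, states)
        assert rec.cost == 1
        assert rec.mpr_events[0] == [("Bradypus_torquatus", 0, 1)]


class TestOracleProperties:
    def test_fitch_matches_brute_force_on_random_characters(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 500:
            n_tips = int(rng.integers(4, 9))
            tree = PhyloTree.from_newick(random_binary_newick(n_tips, rng))
            states = {t: int(rng.integers(2)) for t in tree.tip_labels}
            if rng.random() < 0.25:  # sprinkle missing data
                states[tree.tip_labels[int(rng.integers(n_tips))]] = None
            rec = fitch_reconstruct(tree, states)
            oracle = brute_force_min_changes(tree, states)
            assert rec.cost == oracle.cost
            assert rec.node_states == oracle.node_states
            assert sorted(map(sorted, (m.items() for m in rec.mprs))) == \
                sorted(map(sorted, (m.items() for m in oracle.mprs)))
            checked += 1

    def test_wagner_matches_brute_force_on_random_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(120):
            n_tips = int(rng.integers(4, 8))
            tree = PhyloTree.from_newick(random_binary_newick(n_tips, rng))
            states = {}
            for t in tree.tip_labels:
                r = rng.random()
                if r < 0.1:
                    states[t] = None
                elif r < 0.25:
                    lo = int(rng.integers(0, 3))
                    states[t] = (lo, lo + int(rng.integers(1, 3)))
                else:
                    states[t] = int(rng.integers(0, 4))
            rec = wagner_counts(tree, states)
            oracle = brute_force_min_changes(tree, states, ordered=True)
            assert rec.cost == oracle.cost
            assert rec.node_states == oracle.node_states

    def test_dollo_never_beats_fitch(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            tree = PhyloTree.from_newick(
                random_binary_newick(int(rng.integers(4, 9)), rng))
            states = {t: int(rng.integers(2)) for t in tree.tip_labels}
            d = dollo_reconstruct(tree, states)
            f = fitch_reconstruct(tree, states)
            assert d.cost >= f.cost
            if d.cost == f.cost and any(states.values()):
                # equality implies some MPR is single-origin
                assert any(sum(1 for e in ev if e[2] > e[1]) <= 1
                           for ev in f.mpr_events)

    def test_masking_tips_never_raises_cost(self, matrix, tree):
        for label in ("7/10", "16/19", "2/8", "17/19"):
            states = binary_column(matrix, label)
            base = fitch_reconstruct(tree, states).cost
            for taxon in states:
                masked = dict(states)
                masked[taxon] = None
                assert fitch_reconstruct(tree, masked).cost <= base

    def test_every_enumerated_mpr_achieves_the_minimum(self, matrix, tree):
        rec = fitch_reconstruct(tree, binary_column(matrix, "7/10"))
        for events in rec.mpr_events:
            assert len(events) == rec.cost

    def test_brute_force_refuses_large_trees(self):
        rng = np.random.default_rng(0)
        tree = PhyloTree.from_newick(random_binary_newick(15, rng))
        with pytest.raises(ValueError, match="refused"):
            brute_force_min_changes(tree, {t: 0 for t in tree.tip_labels})

    def test_unknown_taxon_rejected(self, tree):
        with pytest.raises(KeyError):
            fitch_reconstruct(tree, {"not_a_taxon": 1})

    def test_single_tip_tree_costs_zero(self):
        rec = brute_force_min_changes(PhyloTree.from_newick("A;"), {"A": 1})
        assert rec.cost == 0
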