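"""Fusion/fission simulator: event algebra, reproducibility, recovery."""

import numpy as np
import pytest

from karyoanc import karyo_model as km
from karyoanc.character_extraction import build_character_matrix
from karyoanc.karyotype_assembly import compare_karyotypes, karyotype_from_map
from karyoanc.painting_io import write_painting_map
from karyoanc.synthetic_evolution import (
    SimulationConfig,
    adjacency_f1,
    mask_probes,
    recovered_root_summary,
    simulate,
)


@pytest.fixture(scope="module")
def sim_result(tree, aek_karyotype):
    return simulate(SimulationConfig(tree=tree, ancestor=aek_karyotype,
                                     fusion_rate=0.3, fission_rate=0.3, seed=17))


class TestProcess:
    def test_zero_rates_round_trip_the_ancestor(self, tree, aek_karyotype):
        res = simulate(SimulationConfig(tree=tree, ancestor=aek_karyotype,
                                        fusion_rate=0, fission_rate=0, seed=5))
        assert res.log.events == []
        for pmap in res.maps.values():
            assert compare_karyotypes(karyotype_from_map(pmap),
                                      aek_karyotype).empty
            assert km.diploid_number(pmap) == 48

    def test_event_algebra_per_tip(self, tree, aek_karyotype, sim_result):
        anc_segments = aek_karyotype.segment_count - 1     # X held immune
        anc_autosomes = sum(1 for c in aek_karyotype.chromosomes
                            if c != ("X",))
        for tip, pmap in sim_result.maps.items():
            fissions = sim_result.log.count_on_path(tree, tip, "fission")
            fusions = sim_result.log.count_on_path(tree, tip, "fusion")
            segments = km.count_segments(pmap) - 1         # minus the X
            autosomes = sum(1 for c in pmap.chromosomes
                            if not c.is_sex_chromosome)
            assert segments == anc_segments + fissions
            assert autosomes == anc_autosomes + fissions - fusions

    def test_simulated_maps_validate(self, sim_result):
        for pmap in sim_result.maps.values():
            assert [v for v in km.validate_map(pmap)
                    if v.severity == "error"] == []
            assert km.diploid_number(pmap) == pmap.diploid_number_reported

    def test_same_seed_byte_identical(self, tree, aek_karyotype, sim_result):
        again = simulate(SimulationConfig(tree=tree, ancestor=aek_karyotype,
                                          fusion_rate=0.3, fission_rate=0.3,
                                          seed=17))
        for tip in sim_result.maps:
            assert write_painting_map(again.maps[tip]) == \
                write_painting_map(sim_result.maps[tip])

    def test_event_log_replays_to_every_node(self, tree, sim_result):
        replayed = sim_result.log.replay(tree)
        for node, kar in sim_result.log.node_karyotypes.items():
            assert sorted(map(tuple, replayed[node])) == sorted(map(tuple, kar))

    def test_fusion_refused_on_single_chromosome_ancestor(self, tree,
                                                          aek_karyotype):
        from karyoanc.karyotype_assembly import AncestralKaryotype, assemble_karyotype

        one = assemble_karyotype({"1": 1, "X": 1}, [])
        res = simulate(SimulationConfig(tree=tree, ancestor=one,
                                        fusion_rate=3.0, fission_rate=0,
                                        seed=1))
        kinds = {e.kind for e in res.log.events}
        assert kinds <= {"fusion-refused"}
        assert any(e.kind == "fusion-refused" for e in res.log.events)


class TestMasking:
    def test_probability_zero_is_identity(self, sim_result):
        masked = mask_probes(sim_result.maps, 0.0, seed=1)
        for tip in sim_result.maps:
            assert write_painting_map(masked[tip]) == \
                write_painting_map(sim_result.maps[tip])

    def test_probability_one_erases_all_characters(self, tree, aek_karyotype):
        res = simulate(SimulationConfig(tree=tree, ancestor=aek_karyotype,
                                        fusion_rate=0, fission_rate=0, seed=2))
        masked = mask_probes(res.maps, 1.0, seed=3)
        mat = build_character_matrix(masked)
        assert mat.variable_characters() == []
        for ch in mat.characters:
            if ch.kind == "fragment_count" and ch.identity != "X":
                assert all(mat.state(ch, t) is None for t in mat.taxa)

    def test_single_probe_mask_turns_association_uncertain(self, tree,
                                                           aek_karyotype):
        # the B. variegatus situation: drop one probe and the association
        # that hangs on it becomes unobservable (missing), not absent
        import copy

        res = simulate(SimulationConfig(tree=tree, ancestor=aek_karyotype,
                                        fusion_rate=0, fission_rate=0, seed=4))
        m = copy.deepcopy(res.maps["Bradypus_variegatus"])
        kept = []
        for chrom in m.chromosomes:
            chrom.segments = [s for s in chrom.segments
                              if s.human_chromosome != "21"]
            if chrom.segments:
                kept.append(chrom)
            else:
                m.unpainted_pairs.append(chrom.chrom_id)
        m.chromosomes = kept
        m.probes_failed = {"21"}
        mat = build_character_matrix({"m": m, "ref": res.maps["AEK"]})
        assert mat.state(mat.get("3/21"), "m") is None
        assert mat.state(mat.get("3/21"), "ref") == 1


class TestRecovery:
    def test_root_recovery_f1_at_calibrated_rates(self, tree, aek_karyotype):
        # 60 replicates at 0.1 events/branch/event-type; threshold frozen
        # from a 200-replicate calibration (mean F1 0.994)
        truth = aek_karyotype.cooccurrence_multiset()
        f1s = []
        for seed in range(60):
            res = simulate(SimulationConfig(tree=tree, ancestor=aek_karyotype,
                                            fusion_rate=0.1, fission_rate=0.1,
                                            seed=seed))
            assoc, _ = recovered_root_summary(res)
            f1s.append(adjacency_f1(truth, assoc))
        assert float(np.mean(f1s)) >= 0.95

    def test_recovery_error_shrinks_with_rate(self, tree, aek_karyotype):
        truth = aek_karyotype.cooccurrence_multiset()
        means = []
        for rate in (0.02, 0.1, 0.4):
            f1s = []
            for seed in range(25):
                res = simulate(SimulationConfig(
                    tree=tree, ancestor=aek_karyotype, fusion_rate=rate,
                    fission_rate=rate, seed=seed))
                assoc, _ = recovered_root_summary(res)
                f1s.append(adjacency_f1(truth, assoc))
            means.append(float(np.mean(f1s)))
        assert means[0] >= means[1] >= means[2]
        assert means[0] > 0.99

    def test_zero_rate_recovery_is_exact(self, tree, aek_karyotype):
        res = simulate(SimulationConfig(tree=tree, ancestor=aek_karyotype,
                                        fusion_rate=0, fission_rate=0, seed=9))
        assoc, counts = recovered_root_summary(res)
        assert assoc == aek_karyotype.cooccurrence_multiset()
        for hsa, n in aek_karyotype.blocks.items():
            if hsa != "X":
                assert counts[hsa] == n
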