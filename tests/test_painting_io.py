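"""I/O round-trips and the fixture transcription check."""

import io

import dendropy
import pytest

from karyoanc.character_extraction import (
    build_character_matrix,
    extract_associations,
    extract_fragment_counts,
    uncertain_associations,
)
from karyoanc.painting_io import (
    FIXTURE_TAXA,
    ParseError,
    read_character_matrix_tsv,
    read_painting_map,
    read_tree,
    write_character_matrix,
    write_painting_map,
)
from karyoanc.parsimony import PhyloTree

# ---------------------------------------------------------------------------
# The correspondence table, transcribed: association cell and block-count
# columns per taxon.  Deviations from the printed row, each taken from the
# source's own text, are commented where they occur.
TABLE = {
    "Bradypus_torquatus": {
        "assoc": {"3/21": 1, "4/8": 1, "7/10": 1, "7/16": 1, "12/22": 2,
                  "14/15": 1, "17/19": 1},
        "conserved": {"1", "3", "4", "5", "6", "9", "11", "13", "14", "15",
                      "17", "18", "20", "21", "X"},
        "two": {"2", "7", "10", "12", "16", "19", "22"},
        "three": {"8"},
    },
    "Bradypus_variegatus": {
        # 3/21 is inferred (HSA 21 probe failed) -> uncertain, not certain
        "assoc": {"4/8": 1, "7/10": 1, "7/16": 1, "12/22": 1, "12/22/16": 1,
                  "14/15": 1, "17/19": 1},
        "uncertain_assoc": {"3/21": 1},
        "conserved": {"5", "6", "9", "11", "13", "14", "15", "17", "18",
                      "20", "X"},   # 21? handled via probe failure
        "two": {"1", "2", "3", "4", "7", "10", "12", "19", "22"},
        "three": {"8", "16"},
    },
    "Bradypus_tridactylus": {
        # 14/15 and 17/19 restored from the truncated printed cell: the text
        # states both are present in all three Bradypus species
        "assoc": {"2/6": 1, "3/21": 1, "4/8": 1, "7/10": 1, "7/16": 1,
                  "11/19": 1, "12/22": 1, "12/22/16": 1, "14/15": 1,
                  "17/19": 1},
        "conserved": {"1", "5", "9", "11", "13", "14", "15", "17", "18",
                      "20", "21", "X"},
        "two": {"2", "3", "4", "7", "10", "12", "16", "19", "22"},
        "three": {"6"},          # 8? -> range, checked separately
    },
    "Choloepus_hoffmanni": {
        "assoc": {"3/21": 1, "4/8": 1, "7/16": 1, "12/22": 2, "14/15": 1,
                  "16/19": 1},
        "conserved": {"1", "3", "4", "5", "6", "9", "10", "11", "13", "14",
                      "15", "17", "18", "20", "21", "X"},
        "two": {"2", "7", "12", "19", "22"},
        "three": {"16"},         # 8? -> range
    },
    "Choloepus_didactylus": {
        "assoc": {"2/8": 1, "3/21": 1, "4/8": 1, "7/10": 1, "7/16": 1,
                  "12/22": 2, "14/15": 1},
        "conserved": {"9", "13", "15", "17", "18", "20", "21", "X"},
        "two": {"1", "3", "4", "5", "6", "10", "11", "12", "14", "16",
                "19", "22"},
        "three": {"2", "7", "8"},
    },
    "Dasypus_novemcinctus": {
        "assoc": {"3/21": 2, "4/8": 1, "7/16": 1, "10/12": 1, "12/22": 2,
                  "14/15": 1, "16/19": 1},
        "conserved": {"5", "9", "13", "14", "15", "17", "18", "20", "X"},
        "two": {"1", "4", "6", "7", "10", "11", "16", "21", "22"},  # 19? -> range
        "three": {"3", "8", "12"},                                  # 2? -> range
    },
    "Euphractus_sexcinctus": {
        # 11/19 restored: the text twice states it is present in
        # E. sexcinctus (and B. tridactylus) though the printed cell omits it
        "assoc": {"2/8": 1, "3/21": 1, "4/8": 1, "7/10": 1, "7/16": 1,
                  "11/19": 1, "12/22": 2, "14/15": 1, "16/19": 1},
        "conserved": {"5", "9", "13", "14", "15", "17", "18", "20", "21", "X"},
        "two": {"1", "6", "7", "10", "11", "16", "19", "22"},
        "three": {"2", "3", "4", "8", "12"},
    },
    "Tamandua_tetradactyla": {
        "assoc": {"1/9": 1, "1/13": 1, "1/19": 1, "2/8": 1, "3/6": 1,
                  "3/21": 1, "4/8": 1, "7/16": 1, "8/17": 1, "12/22": 2,
                  "14/15": 2, "16/19": 1, "3/22": 1, "5/11": 1, "7/20": 1,
                  "20/7/10": 1},
        "conserved": {"9", "10", "13", "17", "18", "20", "21", "X"},
        "two": {"2", "6", "7", "11", "12", "14", "15", "16", "19", "22"},
        "three": {"1", "3", "4", "5", "8"},
    },
}


class TestFixtureTranscription:
    @pytest.mark.parametrize("taxon", FIXTURE_TAXA)
    def test_association_cells(self, fixtures, taxon):
        got = {str(a): n for a, n in extract_associations(fixtures.maps[taxon]).items()}
        assert got == TABLE[taxon]["assoc"]

    def test_uncertain_association_cells(self, fixtures):
        got = {str(a): n for a, n in
               uncertain_associations(fixtures.maps["Bradypus_variegatus"]).items()}
        assert got == TABLE["Bradypus_variegatus"]["uncertain_assoc"]

    @pytest.mark.parametrize("taxon", FIXTURE_TAXA)
    def test_count_columns(self, fixtures, taxon):
        counts = extract_fragment_counts(fixtures.maps[taxon])
        row = TABLE[taxon]
        for hsa in row["conserved"]:
            assert counts[hsa] == 1, (taxon, hsa)
        for hsa in row["two"]:
            assert counts[hsa] == 2, (taxon, hsa)
        for hsa in row["three"]:
            assert counts[hsa] == 3, (taxon, hsa)

    def test_uncertain_count_cells_are_ranges(self, fixtures):
        assert extract_fragment_counts(
            fixtures.maps["Bradypus_tridactylus"])["8"] == (2, 3)
        assert extract_fragment_counts(
            fixtures.maps["Choloepus_hoffmanni"])["8"] == (2, 3)
        dno = extract_fragment_counts(fixtures.maps["Dasypus_novemcinctus"])
        assert dno["2"] == (2, 3) and dno["19"] == (1, 2)

    def test_probe_failures(self, fixtures):
        assert fixtures.maps["Bradypus_variegatus"].probes_failed == {"21"}
        assert extract_fragment_counts(
            fixtures.maps["Bradypus_variegatus"])["21"] is None


class TestMapRoundTrip:
    @pytest.mark.parametrize("taxon", FIXTURE_TAXA + ("AEK", "AEK_alt"))
    def test_write_read_identity(self, fixtures, taxon):
        text = write_painting_map(fixtures.maps[taxon])
        again = read_painting_map(text)
        assert write_painting_map(again) == text
        assert again.taxon == taxon
        assert again.printed_counts == fixtures.maps[taxon].printed_counts

    def test_uncertain_token_round_trip(self):
        text = ("# taxon: t\n# 2n: 6\ntaxon\tchrom_id\tsegments\tflags\n"
                "t\tc1\t3,21?\t-\nt\tc2\t5\t-\n")
        m = read_painting_map(text)
        assert m.uncertain_entries == {"21"}
        assert "21?" in write_painting_map(m)

    def test_parse_errors_name_the_line(self):
        with pytest.raises(ParseError, match="line 3"):
            read_painting_map("# taxon: t\n# 2n: 4\nt\tc1\t\t-\n")
        with pytest.raises(ParseError, match="line 4"):
            read_painting_map("# taxon: t\n# 2n: 4\nt\tc1\t5\t-\n"
                              "t\tc1\t6\t-\n")
        with pytest.raises(ParseError, match="25"):
            read_painting_map("# taxon: t\n# 2n: 4\nt\tc1\t25\t-\n")


class TestTreeReading:
    def test_fixture_topology(self, fixtures, tree):
        xen = tree.index_of("Xenarthra")
        kids = {tree.labels[c] for c in tree.children[xen]}
        assert kids == {"Pilosa", "Cingulata"}
        assert set(tree.tip_labels) == set(FIXTURE_TAXA) | {"AEK"}
        assert tree.labels[tree.root] == "Eutheria"

    def test_single_tip(self):
        t = PhyloTree.from_newick("A;")
        assert t.tip_labels == ["A"]

    def test_polytomy_preserved(self):
        t = PhyloTree.from_newick("(A,B,C)R;")
        assert len(t.children[t.index_of("R")]) == 3


class TestMatrixSerialization:
    def test_tsv_round_trip(self, matrix):
        text = write_character_matrix(matrix, "tsv")
        again = read_character_matrix_tsv(text)
        assert again == matrix

    def test_nexus_loadable_by_dendropy(self, matrix):
        text = write_character_matrix(matrix, "nexus")
        data = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
        assert len(data) == len(matrix.taxa)  # 9 taxa: 8 species + AEK
        assert data.max_sequence_size == len(matrix.characters)
        # "?" symbols survive: B. variegatus has missing cells
        bva = [t for t in data.taxon_namespace if "variegatus" in t.label][0]
        assert "?" in str(data[bva])

    def test_empty_matrix_is_header_only(self, fixtures):
        from karyoanc.character_extraction import CharacterMatrix

        m = CharacterMatrix(taxa=[], characters=[], states={})
        text = write_character_matrix(m, "tsv")
        assert text.splitlines()[0] == "taxon"

    def test_colliding_character_labels_rejected(self):
        from karyoanc.character_extraction import Character, CharacterMatrix

        ch1 = Character.from_label("3/21")
        ch2 = Character.from_label("21/3")   # same canonical identity
        m = CharacterMatrix(taxa=["a"], characters=[ch1, ch2],
                            states={ch1: {"a": 1}, ch2: {"a": 0}})
        with pytest.raises(ParseError, match="collide"):
            write_character_matrix(m, "tsv")
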