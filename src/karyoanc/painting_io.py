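"""Readers and writers for painting maps, trees and character matrices,
plus the packaged study fixtures.

Painting-map files are tab-separated, one row per chromosome::

    taxon  chrom_id  segments  flags

with ``segments`` a comma-separated list of block labels (``3``, ``8a``,
``16p``; a trailing ``?`` marks an uncertain segment) and ``flags`` one of
``-`` or a comma list from {``sex``, ``unordered``, ``uncertain``}.
``# key: value`` header lines carry taxon-level metadata, including the
block-count columns exactly as printed in the source correspondence table
(``conserved`` / ``two_blocks`` / ``three_blocks``; a ``?`` suffix widens a
count to a range).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Union

import dendropy

from .karyo_model import (
    BlockLabel,
    MapValidationError,
    PaintedChromosome,
    PaintingMap,
)

__all__ = [
    "ParseError",
    "read_painting_map",
    "write_painting_map",
    "read_tree",
    "FixtureSet",
    "load_fixtures",
    "fixture_path_text",
    "write_character_matrix",
    "read_character_matrix_tsv",
]

FIXTURE_TAXA = (
    "Bradypus_torquatus",
    "Bradypus_variegatus",
    "Bradypus_tridactylus",
    "Choloepus_hoffmanni",
    "Choloepus_didactylus",
    "Dasypus_novemcinctus",
    "Euphractus_sexcinctus",
    "Tamandua_tetradactyla",
)
PSEUDO_TAXA = ("AEK", "AEK_alt")

_FIXTURE_FILES = {
    "Bradypus_torquatus": "btorquatus.tsv",
    "Bradypus_variegatus": "bvariegatus.tsv",
    "Bradypus_tridactylus": "btridactylus.tsv",
    "Choloepus_hoffmanni": "choffmanni.tsv",
    "Choloepus_didactylus": "cdidactylus.tsv",
    "Dasypus_novemcinctus": "dnovemcinctus.tsv",
    "Euphractus_sexcinctus": "esexcinctus.tsv",
    "Tamandua_tetradactyla": "ttetradactyla.tsv",
    "AEK": "aek.tsv",
    "AEK_alt": "aek_alt.tsv",
}


class ParseError(ValueError):
    """Malformed painting-map / matrix input; message names the line."""


def _parse_count_column(text: str, level: int) -> dict:
    """Printed block-count column -> {hsa: count or (lo, hi) range}."""
    out = {}
    for tok in filter(None, (t.strip() for t in text.split(","))):
        if tok.endswith("?"):
            out[tok[:-1]] = (level - 1, level)
        else:
            out[tok] = level
    return out


def read_painting_map(source: Union[str, io.TextIOBase]) -> PaintingMap:
    """Parse one painting-map file (path-like text content or open handle)."""
    text = source.read() if hasattr(source, "read") else source
    meta: dict[str, str] = {}
    notes: list[str] = []
    chromosomes: list[PaintedChromosome] = []
    taxon_seen: Optional[str] = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" not in body:
                continue
            key, _, value = body.partition(":")
            key = key.strip().lower()
            if key == "note":
                notes.append(value.strip())
            else:
                meta[key] = value.strip()
            continue
        fields = line.split("\t")
        if fields[0].strip().lower() == "taxon":  # column header row
            continue
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: expected 4 tab-separated fields")
        taxon, chrom_id, seg_field, flag_field = (f.strip() for f in fields[:4])
        if taxon_seen is None:
            taxon_seen = taxon
        elif taxon != taxon_seen:
            raise ParseError(f"line {lineno}: taxon {taxon!r} != {taxon_seen!r}")
        if any(c.chrom_id == chrom_id for c in chromosomes):
            raise ParseError(f"line {lineno}: duplicate chrom_id {chrom_id!r}")
        seg_tokens = [t.strip() for t in seg_field.split(",") if t.strip()]
        if not seg_tokens:
            raise ParseError(f"line {lineno}: empty chromosome record {chrom_id!r}")
        segments, uncertain = [], set()
        for i, tok in enumerate(seg_tokens):
            if tok.endswith("?"):
                uncertain.add(i)
                tok = tok[:-1]
            try:
                segments.append(BlockLabel.parse(tok))
            except MapValidationError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
        flags = set() if flag_field in ("-", "") else \
            {f.strip() for f in flag_field.split(",")}
        unknown = flags - {"sex", "unordered", "uncertain"}
        if unknown:
            raise ParseError(f"line {lineno}: unknown flags {sorted(unknown)}")
        chromosomes.append(PaintedChromosome(
            chrom_id=chrom_id,
            segments=segments,
            uncertain_segments=frozenset(uncertain),
            ordered="unordered" not in flags,
            is_sex_chromosome="sex" in flags,
            uncertain_chromosome="uncertain" in flags,
        ))

    if taxon_seen is None:
        raise ParseError("no chromosome rows found")
    if "2n" not in meta:
        raise ParseError("missing required header '# 2n:'")

    printed_counts: Optional[dict] = None
    if any(k in meta for k in ("conserved", "two_blocks", "three_blocks")):
        printed_counts = {}
        printed_counts.update(_parse_count_column(meta.get("conserved", ""), 1))
        printed_counts.update(_parse_count_column(meta.get("two_blocks", ""), 2))
        printed_counts.update(_parse_count_column(meta.get("three_blocks", ""), 3))

    return PaintingMap(
        taxon=meta.get("taxon", taxon_seen),
        diploid_number_reported=int(meta["2n"]),
        chromosomes=chromosomes,
        unpainted_pairs=[p for p in meta.get("unpainted_pairs", "").split(",") if p],
        probes_failed={p for p in meta.get("probes_failed", "").split(",") if p},
        sex_chromosome_count=int(meta.get("sex_chromosomes", "2")),
        printed_counts=printed_counts,
        layout_inferred=meta.get("layout_inferred", "false").lower() == "true",
        notes=notes,
    )


def write_painting_map(pmap: PaintingMap) -> str:
    """Serialize a map to the TSV dialect; ``read(write(m))`` is canonical."""
    lines = [f"# taxon: {pmap.taxon}",
             f"# 2n: {pmap.diploid_number_reported}",
             f"# sex_chromosomes: {pmap.sex_chromosome_count}",
             f"# probes_failed: {','.join(sorted(pmap.probes_failed))}",
             f"# unpainted_pairs: {','.join(pmap.unpainted_pairs)}",
             f"# layout_inferred: {str(pmap.layout_inferred).lower()}"]
    if pmap.printed_counts is not None:
        cols: dict[int, list[str]] = {1: [], 2: [], 3: []}
        for hsa, cnt in pmap.printed_counts.items():
            if isinstance(cnt, tuple):
                cols[cnt[1]].append(hsa + "?")
            else:
                cols[cnt].append(hsa)
        from .karyo_model import HUMAN_CHROMOSOMES
        order = {h: i for i, h in enumerate(HUMAN_CHROMOSOMES)}
        for level, key in ((1, "conserved"), (2, "two_blocks"), (3, "three_blocks")):
            toks = sorted(cols[level], key=lambda t: order[t.rstrip("?")])
            lines.append(f"# {key}: {','.join(toks)}")
    for note in pmap.notes:
        lines.append(f"# note: {note}")
    lines.append("taxon\tchrom_id\tsegments\tflags")
    for chrom in pmap.chromosomes:
        toks = [str(s) + ("?" if i in chrom.uncertain_segments else "")
                for i, s in enumerate(chrom.segments)]
        flags = []
        if chrom.is_sex_chromosome:
            flags.append("sex")
        if not chrom.ordered:
            flags.append("unordered")
        if chrom.uncertain_chromosome:
            flags.append("uncertain")
        lines.append("\t".join([pmap.taxon, chrom.chrom_id, ",".join(toks),
                                ",".join(flags) or "-"]))
    return "\n".join(lines) + "\n"


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick tree with internal node labels permitted."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=False,
        rooting="default-rooted",
    )
    return tree


def fixture_path_text(name: str) -> str:
    """Raw text of one packaged data file."""
    return (resources.files("karyoanc") / "data" / name).read_text()


@dataclass
class FixtureSet:
    """The packaged study inputs: the eight species maps, the two ancestral
    Eutherian pseudo-taxa, the genus-level phylogeny and the run config."""

    maps: dict[str, PaintingMap]
    tree: dendropy.Tree
    overrides: dict
    paper_config: dict
    tree_newick: str = ""

    @property
    def species_maps(self) -> dict[str, PaintingMap]:
        return {t: self.maps[t] for t in FIXTURE_TAXA}

    @property
    def matrix_maps(self) -> dict[str, PaintingMap]:
        """Maps entering the default character matrix: species + AEK outgroup."""
        out = {t: self.maps[t] for t in FIXTURE_TAXA}
        out["AEK"] = self.maps["AEK"]
        return out


def load_fixtures() -> FixtureSet:
    import yaml

    maps = {taxon: read_painting_map(fixture_path_text(fname))
            for taxon, fname in _FIXTURE_FILES.items()}
    newick = fixture_path_text("xenarthra.nwk")
    overrides = yaml.safe_load(fixture_path_text("overrides.yaml")) or {}
    paper_config = yaml.safe_load(fixture_path_text("paper.yaml")) or {}
    return FixtureSet(maps=maps, tree=read_tree(newick), overrides=overrides,
                      paper_config=paper_config, tree_newick=newick)


# ---------------------------------------------------------------------------
# character-matrix serialization


def _state_to_token(state) -> str:
    if state is None:
        return "?"
    if isinstance(state, tuple):
        return f"{state[0]}-{state[1]}"
    return str(state)


def _token_to_state(token: str):
    token = token.strip()
    if token == "?":
        return None
    if "-" in token:
        lo, hi = token.split("-")
        return (int(lo), int(hi))
    return int(token)


def write_character_matrix(matrix, dialect: str = "tsv") -> str:
    """Serialize a CharacterMatrix (see character_extraction) to TSV or NEXUS.

    The NEXUS dialect writes a STANDARD datatype block with integer symbols
    and ``?`` for missing; ranges become NEXUS ambiguity sets so standard
    phylogenetics software can load the file.
    """
    labels = [c.label for c in matrix.characters]
    if len(set(labels)) != len(labels):
        raise ParseError("character labels collide after canonicalization")
    if dialect == "tsv":
        lines = ["\t".join(["taxon"] + labels)]
        for taxon in matrix.taxa:
            row = [_state_to_token(matrix.state(ch, taxon)) for ch in matrix.characters]
            lines.append(taxon + "\t" + "\t".join(row))
        lines.append(f"#policy\t{matrix.uncertainty_policy_applied}")
        return "\n".join(lines) + "\n"
    if dialect == "nexus":
        max_state = 1
        for ch in matrix.characters:
            for taxon in matrix.taxa:
                s = matrix.state(ch, taxon)
                if isinstance(s, tuple):
                    max_state = max(max_state, s[1])
                elif s is not None:
                    max_state = max(max_state, s)
        if max_state > 9:
            raise ParseError("NEXUS standard symbols limited to single digits")
        symbols = "".join(str(i) for i in range(max_state + 1))
        out = ["#NEXUS", "", "BEGIN DATA;",
               f"    DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={len(matrix.characters)};",
               f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=?;',
               "    CHARLABELS",
               "        " + " ".join(f"'{lab}'" for lab in labels) + ";",
               "    MATRIX"]
        width = max(len(t) for t in matrix.taxa) + 2
        for taxon in matrix.taxa:
            cells = []
            for ch in matrix.characters:
                s = matrix.state(ch, taxon)
                if s is None:
                    cells.append("?")
                elif isinstance(s, tuple):
                    cells.append("{" + "".join(str(v) for v in range(s[0], s[1] + 1)) + "}")
                else:
                    cells.append(str(s))
            out.append(f"    {taxon:<{width}}" + "".join(cells))
        out += ["    ;", "END;", ""]
        return "\n".join(out)
    raise ValueError(f"unknown dialect: {dialect!r}")


def read_character_matrix_tsv(text: str):
    """Round-trip reader for the TSV character-matrix dialect."""
    from .character_extraction import Character, CharacterMatrix

    lines = [ln for ln in text.splitlines() if ln.strip()]
    policy = "missing"
    rows = []
    header = None
    for ln in lines:
        if ln.startswith("#policy"):
            policy = ln.split("\t")[1]
        elif header is None:
            header = ln.split("\t")[1:]
        else:
            rows.append(ln.split("\t"))
    if header is None:
        raise ParseError("empty matrix file")
    characters = [Character.from_label(lab) for lab in header]
    taxa, states = [], {}
    for row in rows:
        taxon = row[0]
        taxa.append(taxon)
        for ch, tok in zip(characters, row[1:]):
            states.setdefault(ch, {})[taxon] = _token_to_state(tok)
    return CharacterMatrix(taxa=taxa, characters=characters, states=states,
                           uncertainty_policy_applied=policy)
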