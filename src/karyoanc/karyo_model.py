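"""Core data types for comparative chromosome-painting maps.

A painting map records, for one species, which human chromosome probes
(HSA 1-22, X) label which chromosomes of the target karyotype.  Each
contiguous painted region is a *conserved segment*; two or more segments
from different human chromosomes on one target chromosome form an
*association* (e.g. HSA 7/10).  The arithmetic connecting segments,
junctions and the diploid number is::

    painted chromosomes = segments - junctions
    2n = 2 * (painted autosome pairs + unpainted autosome pairs) + sex chromosomes

All counts here are per haploid complement except the diploid number.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

__all__ = [
    "HUMAN_CHROMOSOMES",
    "BlockLabel",
    "PaintedChromosome",
    "PaintingMap",
    "AssociationType",
    "Violation",
    "MapValidationError",
    "count_segments",
    "count_junctions",
    "painted_chromosome_count",
    "diploid_number",
    "validate_map",
]

#: Human chromosomes usable as painting probes (the Y yields no cross-species
#: signal and is carried as metadata only).
HUMAN_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

_HSA_ORDER = {h: i for i, h in enumerate(HUMAN_CHROMOSOMES)}

_BLOCK_RE = re.compile(r"^(?P<hsa>[0-9]{1,2}|X)(?P<arm>[pq])?(?P<sub>[a-f])?$")

# Printed forms for associations whose members the source tables list in
# non-numeric order; canonical identity is always the sorted member tuple.
_DISPLAY_FORMS = {
    ("12", "16", "22"): "12/22/16",
    ("7", "10", "20"): "20/7/10",
}


class MapValidationError(ValueError):
    """Raised when a painting map violates a structural invariant."""


def _hsa_key(hsa: str) -> int:
    try:
        return _HSA_ORDER[hsa]
    except KeyError:
        raise MapValidationError(f"unknown human chromosome label: {hsa!r}") from None


@dataclass(frozen=True, order=True)
class BlockLabel:
    """One conserved segment identity: a human chromosome plus optional tags.

    ``sub_block`` (a, b, c, ...) distinguishes multiple blocks of the same
    human chromosome within one karyotype; ``arm_hint`` records p/q arm
    information where the source states it (e.g. the ancestral Eutherian
    blocks 4/8p and 16q/19q).
    """

    sort_index: int = field(init=False, repr=False, compare=True)
    human_chromosome: str = field(compare=True)
    sub_block: Optional[str] = field(default=None, compare=True)
    arm_hint: Optional[str] = field(default=None, compare=True)

    def __post_init__(self) -> None:
        if self.human_chromosome not in _HSA_ORDER:
            raise MapValidationError(
                f"unknown human chromosome label: {self.human_chromosome!r}"
            )
        if self.arm_hint not in (None, "p", "q"):
            raise MapValidationError(f"bad arm hint: {self.arm_hint!r}")
        if self.sub_block is not None and not re.fullmatch(r"[a-f]", self.sub_block):
            raise MapValidationError(f"bad sub-block tag: {self.sub_block!r}")
        object.__setattr__(self, "sort_index", _hsa_key(self.human_chromosome))

    @classmethod
    def parse(cls, token: str) -> "BlockLabel":
        m = _BLOCK_RE.match(token.strip())
        if not m:
            raise MapValidationError(f"cannot parse block label: {token!r}")
        return cls(
            human_chromosome=m.group("hsa"),
            sub_block=m.group("sub"),
            arm_hint=m.group("arm"),
        )

    def __str__(self) -> str:
        return f"{self.human_chromosome}{self.arm_hint or ''}{self.sub_block or ''}"


@dataclass
class PaintedChromosome:
    """One chromosome (pair) of the target species and its painted segments.

    ``uncertain_segments`` holds indices of segments the source marks "?"
    (inferred but unconfirmed); ``uncertain_chromosome`` marks a whole
    element whose existence is inferred (e.g. the hypothesised third HSA 8
    chromosome of *B. tridactylus*).
    """

    chrom_id: str
    segments: list[BlockLabel]
    uncertain_segments: frozenset[int] = frozenset()
    unpainted_regions: int = 0
    ordered: bool = True
    is_sex_chromosome: bool = False
    uncertain_chromosome: bool = False

    def counted_segments(self, include_uncertain: bool = False) -> list[BlockLabel]:
        if self.uncertain_chromosome and not include_uncertain:
            return []
        if include_uncertain:
            return list(self.segments)
        return [s for i, s in enumerate(self.segments) if i not in self.uncertain_segments]

    def junctions(self, include_uncertain: bool = False) -> int:
        return max(len(self.counted_segments(include_uncertain)) - 1, 0)


@dataclass
class PaintingMap:
    """A species karyotype as painted by the human probe set.

    ``printed_counts`` optionally carries the per-human-chromosome block
    counts exactly as printed in the source table; for literature rows whose
    full chromosome-level layout was never published these are authoritative
    over counts derived from the stored layout (the layout is then a
    one-chromosome-per-association expansion and may disagree; see
    :func:`validate_map`).
    """

    taxon: str
    diploid_number_reported: int
    chromosomes: list[PaintedChromosome]
    unpainted_pairs: list[str] = field(default_factory=list)
    probes_failed: set[str] = field(default_factory=set)
    sex_chromosome_count: int = 2
    printed_counts: Optional[dict[str, Union[int, tuple[int, int]]]] = None
    layout_inferred: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def uncertain_entries(self) -> set[str]:
        """String forms of all segments flagged uncertain anywhere in the map."""
        out: set[str] = set()
        for chrom in self.chromosomes:
            if chrom.uncertain_chromosome:
                out.update(str(s) for s in chrom.segments)
            out.update(str(chrom.segments[i]) for i in chrom.uncertain_segments)
        return out


@dataclass(frozen=True)
class AssociationType:
    """An unordered co-occurrence of >=2 human chromosomes on one target
    chromosome.  Identity is the canonically sorted member tuple; the
    multiplicity of an association within a map is carried by the multiset
    returned from extraction, not by this record."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise MapValidationError("an association needs >= 2 members")
        canon = tuple(sorted(set(self.members), key=_hsa_key))
        if len(canon) != len(self.members):
            raise MapValidationError(f"duplicate members in association: {self.members}")
        object.__setattr__(self, "members", canon)

    @classmethod
    def parse(cls, token: str) -> "AssociationType":
        return cls(tuple(p.strip().rstrip("?") for p in token.split("/")))

    def __str__(self) -> str:
        return _DISPLAY_FORMS.get(self.members, "/".join(self.members))

    def contains(self, other: "AssociationType") -> bool:
        return set(other.members) <= set(self.members)


@dataclass(frozen=True)
class Violation:
    """One validation finding.  ``severity`` is ``"error"`` for invariant
    breaks and ``"advisory"`` for documented tensions in the source data."""

    chromosome: Optional[str]
    rule: str
    severity: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" [{self.chromosome}]" if self.chromosome else ""
        return f"{self.severity}:{self.rule}{where}: {self.message}"


def _check_usable(pmap: PaintingMap) -> None:
    errors = [v for v in validate_map(pmap) if v.severity == "error"]
    if errors:
        raise MapValidationError(
            f"map for {pmap.taxon} fails validation: " + "; ".join(map(str, errors))
        )


def count_segments(pmap: PaintingMap, include_uncertain: bool = False) -> int:
    """Total conserved segments in the map (X included, Y and unpainted
    regions excluded).  Uncertain ("?") segments are excluded unless
    ``include_uncertain`` is set, matching the way the source reports
    e.g. 35 vs 36 segments for *B. variegatus*."""
    _check_usable(pmap)
    return sum(len(c.counted_segments(include_uncertain)) for c in pmap.chromosomes)


def count_junctions(pmap: PaintingMap, include_uncertain: bool = False) -> int:
    """Total segment-segment junctions, ``sum(len(segments) - 1)``."""
    _check_usable(pmap)
    return sum(c.junctions(include_uncertain) for c in pmap.chromosomes)


def painted_chromosome_count(pmap: PaintingMap, include_uncertain: bool = False) -> int:
    """Chromosomes carrying at least one counted segment; equals
    ``count_segments - count_junctions`` for any valid map."""
    return sum(1 for c in pmap.chromosomes if c.counted_segments(include_uncertain))


def diploid_number(pmap: PaintingMap) -> int:
    """2n computed from the stored layout: twice the autosome pairs (painted,
    inferred-uncertain and unpainted alike) plus the sex chromosomes."""
    autosome_pairs = sum(1 for c in pmap.chromosomes if not c.is_sex_chromosome)
    autosome_pairs += len(pmap.unpainted_pairs)
    return 2 * autosome_pairs + pmap.sex_chromosome_count


def _derived_counts(pmap: PaintingMap) -> Counter:
    counts: Counter = Counter()
    for chrom in pmap.chromosomes:
        for seg in chrom.segments:
            counts[seg.human_chromosome] += 1
    return counts


def validate_map(pmap: PaintingMap) -> list[Violation]:
    """Check all structural invariants; total function returning findings.

    Errors: duplicate chromosome ids, empty chromosomes, ambiguous duplicate
    sub-blocks, certain segments from probes recorded as failed.
    Advisories: reported 2n inconsistent with the layout, printed block
    counts differing from layout-derived counts (both are real tensions in
    the transcribed literature rows and are surfaced, not fatal).
    """
    out: list[Violation] = []
    seen_ids: set[str] = set()
    for chrom in pmap.chromosomes:
        if chrom.chrom_id in seen_ids:
            out.append(Violation(chrom.chrom_id, "duplicate-id", "error",
                                 "chromosome id appears twice"))
        seen_ids.add(chrom.chrom_id)
        if not chrom.segments:
            out.append(Violation(chrom.chrom_id, "empty-chromosome", "error",
                                 "painted chromosome with no segments "
                                 "(wholly unpainted pairs belong in unpainted_pairs)"))
        for i in chrom.uncertain_segments:
            if i >= len(chrom.segments):
                out.append(Violation(chrom.chrom_id, "bad-uncertain-index", "error",
                                     f"uncertain segment index {i} out of range"))
        for i, seg in enumerate(chrom.segments):
            certain = (i not in chrom.uncertain_segments
                       and not chrom.uncertain_chromosome)
            if certain and seg.human_chromosome in pmap.probes_failed:
                out.append(Violation(chrom.chrom_id, "failed-probe-segment", "error",
                                     f"certain segment {seg} from failed probe"))

    # sub-block disambiguation: >=2 blocks of one human chromosome must not
    # share an identical (possibly absent) tag
    tags: dict[str, list[tuple]] = {}
    for chrom in pmap.chromosomes:
        for seg in chrom.segments:
            tags.setdefault(seg.human_chromosome, []).append((seg.sub_block, seg.arm_hint))
    for hsa, tag_list in tags.items():
        if len(tag_list) >= 2:
            dupes = [t for t, n in Counter(tag_list).items() if n > 1]
            if dupes:
                out.append(Violation(None, "ambiguous-sub-blocks", "error",
                                     f"HSA {hsa} has {len(tag_list)} blocks with "
                                     f"indistinguishable tags {dupes}"))

    computed = diploid_number(pmap)
    if computed != pmap.diploid_number_reported:
        out.append(Violation(None, "diploid-mismatch", "advisory",
                             f"layout yields 2n={computed} but reported "
                             f"2n={pmap.diploid_number_reported}"))

    if pmap.printed_counts is not None:
        derived = _derived_counts(pmap)
        for hsa, printed in pmap.printed_counts.items():
            got = derived.get(hsa, 0)
            ok = (printed[0] <= got <= printed[1]) if isinstance(printed, tuple) \
                else got == printed
            if not ok:
                out.append(Violation(None, "printed-count-tension", "advisory",
                                     f"HSA {hsa}: printed block count {printed} vs "
                                     f"{got} in stored layout"))
    return out
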