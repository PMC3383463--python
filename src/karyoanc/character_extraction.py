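"""Turn painting maps into a phylogenetic character matrix.

Two character kinds are extracted:

* **association** characters — one per distinct human-chromosome
  co-occurrence (HSA 7/10, 12/22/16, ...), scored as a non-negative integer
  multiplicity (how many chromosomes of the taxon carry that association;
  the ancestral Eutherian complement itself carries 12/22 twice).
  Multi-way associations are characters in their own right and are *not*
  decomposed into their contained pairs (painting cannot resolve which
  segments touch), except where an explicit credit table says a printed
  multi-way form evidences a contained pair.
* **fragment_count** characters — one per human chromosome: the number of
  blocks it paints (1 = conserved intact), an integer range where the
  source is uncertain, or missing where the probe failed.

Uncertain ("?") entries are resolved by policy: ``missing`` (default),
``optimistic`` (count the inferred entry as printed) or ``pessimistic``
(drop it).  Probe failures are always missing, whatever the policy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Union

from .karyo_model import (
    HUMAN_CHROMOSOMES,
    AssociationType,
    PaintingMap,
    validate_map,
    MapValidationError,
)

__all__ = [
    "Character",
    "CharacterMatrix",
    "extract_associations",
    "uncertain_associations",
    "extract_fragment_counts",
    "build_character_matrix",
]

State = Union[int, tuple, None]

_HSA_ORDER = {h: i for i, h in enumerate(HUMAN_CHROMOSOMES)}


@dataclass(frozen=True)
class Character:
    """One matrix column: an association or a per-chromosome block count."""

    kind: str  # "association" | "fragment_count"
    identity: Union[AssociationType, str]

    def __post_init__(self) -> None:
        if self.kind not in ("association", "fragment_count"):
            raise ValueError(f"unknown character kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "association":
            return str(self.identity)
        return f"n{self.identity}"

    @classmethod
    def from_label(cls, label: str) -> "Character":
        if "/" in label:
            return cls("association", AssociationType.parse(label))
        if label.startswith("n"):
            return cls("fragment_count", label[1:])
        raise ValueError(f"cannot interpret character label {label!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def _chromosome_association(chrom) -> Optional[AssociationType]:
    hsas = {seg.human_chromosome for seg in chrom.segments}
    if len(hsas) >= 2:
        return AssociationType(tuple(hsas))
    return None


def extract_associations(pmap: PaintingMap) -> Counter:
    """Multiset of certain associations: one maximal co-occurrence per
    multi-probe chromosome, multiplicity counting repeats.  Permutation
    invariant and idempotent by construction."""
    out: Counter = Counter()
    for chrom in pmap.chromosomes:
        if chrom.uncertain_chromosome:
            continue
        certain = {s.human_chromosome for i, s in enumerate(chrom.segments)
                   if i not in chrom.uncertain_segments}
        if len(certain) >= 2:
            out[AssociationType(tuple(certain))] += 1
    return out


def uncertain_associations(pmap: PaintingMap) -> Counter:
    """Associations that exist only if the map's "?" entries are real
    (e.g. 3/21 in *B. variegatus*, hanging on the inferred HSA 21 block)."""
    out: Counter = Counter()
    for chrom in pmap.chromosomes:
        hsas = {s.human_chromosome for s in chrom.segments}
        if len(hsas) < 2:
            continue
        certain_hsas = {s.human_chromosome for i, s in enumerate(chrom.segments)
                        if i not in chrom.uncertain_segments}
        if chrom.uncertain_chromosome or certain_hsas != hsas:
            out[AssociationType(tuple(hsas))] += 1
    return out


def extract_fragment_counts(pmap: PaintingMap) -> dict[str, State]:
    """Blocks painted per human chromosome.

    Printed count columns, where present, are authoritative (the full
    chromosome-level layout of the literature rows was never published);
    otherwise counts derive from the stored layout, with uncertain segments
    widening the value to a range.  Failed probes are missing.
    """
    out: dict[str, State] = {}
    derived_cert: Counter = Counter()
    derived_all: Counter = Counter()
    for chrom in pmap.chromosomes:
        for i, seg in enumerate(chrom.segments):
            derived_all[seg.human_chromosome] += 1
            if i not in chrom.uncertain_segments and not chrom.uncertain_chromosome:
                derived_cert[seg.human_chromosome] += 1
    for hsa in HUMAN_CHROMOSOMES:
        if hsa in pmap.probes_failed:
            out[hsa] = None
        elif pmap.printed_counts is not None:
            out[hsa] = pmap.printed_counts.get(hsa, 0)
        else:
            lo, hi = derived_cert[hsa], derived_all[hsa]
            out[hsa] = lo if lo == hi else (lo, hi)
    return out


def _apply_policy(lo: int, hi: int, policy: str) -> State:
    if lo == hi:
        return lo
    return {"missing": None if lo == 0 else (lo, hi),
            "optimistic": hi,
            "pessimistic": lo}[policy]


@dataclass
class CharacterMatrix:
    """Taxa x characters with integer / range / missing states."""

    taxa: list[str]
    characters: list[Character]
    states: dict[Character, dict[str, State]]
    uncertainty_policy_applied: str = "missing"

    def state(self, character: Character, taxon: str) -> State:
        return self.states[character][taxon]

    def column(self, character: Character) -> dict[str, State]:
        return dict(self.states[character])

    def get(self, label: str) -> Character:
        for ch in self.characters:
            if ch.label == label:
                return ch
        raise KeyError(label)

    def variable_characters(self) -> list[Character]:
        out = []
        for ch in self.characters:
            seen = {s for s in self.states[ch].values() if s is not None}
            flat = set()
            for s in seen:
                flat.update(range(s[0], s[1] + 1) if isinstance(s, tuple) else (s,))
            if len(flat) > 1:
                out.append(ch)
        return out

    def conserved_chromosomes(self, taxon: str) -> set[str]:
        """Human chromosomes with block count exactly 1 in this taxon."""
        out = set()
        for ch in self.characters:
            if ch.kind == "fragment_count" and self.states[ch][taxon] == 1:
                out.add(ch.identity)
        return out

    def to_frame(self):
        import pandas as pd

        from .painting_io import _state_to_token
        data = {ch.label: [_state_to_token(self.states[ch][t]) for t in self.taxa]
                for ch in self.characters}
        return pd.DataFrame(data, index=self.taxa)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxa == other.taxa
                and self.characters == other.characters
                and all(self.states[ch] == other.states[ch] for ch in self.characters)
                and self.uncertainty_policy_applied == other.uncertainty_policy_applied)


def build_character_matrix(
    maps: dict[str, PaintingMap] | list[PaintingMap],
    policy: str = "missing",
    association_credits: Optional[dict[str, list[str]]] = None,
) -> CharacterMatrix:
    """Union all maps into one matrix.

    ``association_credits`` maps a printed association label to contained
    pairs it should additionally count toward (e.g. the lesser anteater's
    20/7/10 carrying the 7/10 adjacency).
    """
    if policy not in ("missing", "optimistic", "pessimistic"):
        raise ValueError(f"unknown uncertainty policy {policy!r}")
    if not isinstance(maps, dict):
        maps = {m.taxon: m for m in maps}
        if len(maps) != len(set(maps)):
            raise ValueError("taxon name collision")
    if len(maps) < 2:
        raise ValueError("need at least two maps to build a matrix")
    for pmap in maps.values():
        bad = [v for v in validate_map(pmap) if v.severity == "error"]
        if bad:
            raise MapValidationError(f"{pmap.taxon}: {bad[0]}")

    credits = {AssociationType.parse(k): [AssociationType.parse(t) for t in v]
               for k, v in (association_credits or {}).items()}

    per_taxon_cert = {t: extract_associations(m) for t, m in maps.items()}
    per_taxon_unc = {t: uncertain_associations(m) for t, m in maps.items()}

    universe: set[AssociationType] = set()
    for cnt in (*per_taxon_cert.values(), *per_taxon_unc.values()):
        universe.update(cnt)
    for targets in credits.values():
        universe.update(targets)

    taxa = list(maps)
    characters: list[Character] = [
        Character("association", a)
        for a in sorted(universe, key=lambda a: tuple(_HSA_ORDER[m] for m in a.members))
    ] + [Character("fragment_count", h) for h in HUMAN_CHROMOSOMES]

    states: dict[Character, dict[str, State]] = {ch: {} for ch in characters}
    counts = {t: extract_fragment_counts(m) for t, m in maps.items()}

    for taxon, pmap in maps.items():
        cert, unc = per_taxon_cert[taxon], per_taxon_unc[taxon]
        for ch in characters:
            if ch.kind == "fragment_count":
                raw = counts[taxon][ch.identity]
                if raw is None:
                    states[ch][taxon] = None
                elif isinstance(raw, tuple):
                    states[ch][taxon] = _apply_policy(raw[0], raw[1], policy)
                else:
                    states[ch][taxon] = raw
                continue
            assoc = ch.identity
            lo = cert[assoc]
            hi = lo + unc[assoc]
            for printed, targets in credits.items():
                if assoc in targets:
                    lo += cert[printed]
                    hi += cert[printed] + unc[printed]
            if hi == 0 and any(m in pmap.probes_failed for m in assoc.members):
                # no observation at all through a failed probe: always
                # missing, whatever the policy; a flagged "?" inference
                # (hi > 0) instead goes through the policy
                states[ch][taxon] = None
                continue
            states[ch][taxon] = _apply_policy(lo, hi, policy)

    return CharacterMatrix(taxa=taxa, characters=characters, states=states,
                           uncertainty_policy_applied=policy)
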