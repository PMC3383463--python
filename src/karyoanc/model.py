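"""Model/results facade over the reconstruction pipeline.

:class:`AncestralKaryotypeModel` is built from data (a character matrix and
a rooted tree, or painting maps directly); :meth:`fit` runs per-character
parsimony, ambiguity resolution and karyotype assembly for a target node
and returns an :class:`AncestralKaryotypeResults` carrying the inferred
karyotype, the per-character reconstructions with their provenance, the
signature classifications, and a ``summary()`` table.

>>> model = AncestralKaryotypeModel.from_fixtures()
>>> results = model.fit("Xenarthra")
>>> results.karyotype.diploid_number
48
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .character_extraction import CharacterMatrix, build_character_matrix
from .karyotype_assembly import (
    AncestralKaryotype,
    InferenceConfig,
    compare_karyotypes,
    infer_ancestral_karyotype,
    reconstruct_character,
)
from .parsimony import PhyloTree, Reconstruction
from .signature_detection import SignatureReport, build_signature_report

__all__ = ["AncestralKaryotypeModel", "AncestralKaryotypeResults"]


class AncestralKaryotypeModel:
    """Ancestral-karyotype parsimony model on a fixed topology."""

    def __init__(self, matrix: CharacterMatrix, tree,
                 config: Optional[InferenceConfig] = None):
        self.matrix = matrix
        self.tree = tree if isinstance(tree, PhyloTree) else \
            PhyloTree.from_dendropy(tree)
        self.config = config or InferenceConfig()
        missing = set(matrix.taxa) - set(self.tree.tip_labels)
        if missing:
            raise KeyError(f"matrix taxa absent from tree: {sorted(missing)}")

    @classmethod
    def from_maps(cls, maps, tree, config: Optional[InferenceConfig] = None,
                  policy: str = "missing",
                  association_credits: Optional[dict] = None) -> "AncestralKaryotypeModel":
        matrix = build_character_matrix(maps, policy=policy,
                                        association_credits=association_credits)
        return cls(matrix, tree, config)

    @classmethod
    def from_fixtures(cls, policy: Optional[str] = None) -> "AncestralKaryotypeModel":
        """The packaged study: eight species maps + ancestral-Eutherian
        outgroup on the genus-level topology, with the replication config."""
        from .painting_io import load_fixtures

        fx = load_fixtures()
        cfg = InferenceConfig.from_dict(fx.paper_config, fx.overrides)
        if policy is not None:
            cfg.uncertainty_policy = policy
        matrix = build_character_matrix(
            fx.matrix_maps, policy=cfg.uncertainty_policy,
            association_credits=fx.paper_config.get("association_credits"))
        return cls(matrix, PhyloTree.from_newick(fx.tree_newick), cfg)

    def reconstruct(self, label: str) -> Reconstruction:
        """Parsimony reconstruction for one character by label."""
        return reconstruct_character(self.matrix, self.tree,
                                     self.matrix.get(label), self.config)

    def fit(self, node: Optional[str] = None) -> "AncestralKaryotypeResults":
        target = node or getattr(self.config, "target_node", None) or "Xenarthra"
        karyotype = infer_ancestral_karyotype(self.matrix, self.tree, target,
                                              self.config)
        return AncestralKaryotypeResults(model=self, node=target,
                                         karyotype=karyotype)


@dataclass
class AncestralKaryotypeResults:
    """Fitted ancestral karyotype plus diagnostics."""

    model: AncestralKaryotypeModel
    node: str
    karyotype: AncestralKaryotype
    _signatures: Optional[SignatureReport] = field(default=None, repr=False)

    @property
    def diploid_number(self) -> int:
        return self.karyotype.diploid_number

    @property
    def provenance(self) -> dict:
        return self.karyotype.provenance

    def signatures(self, clades: Optional[list[str]] = None) -> SignatureReport:
        if self._signatures is None or clades is not None:
            report = build_signature_report(self.model.matrix, self.model.tree,
                                            self.model.config, clades)
            if clades is None:
                self._signatures = report
            return report
        return self._signatures

    def compare(self, other: AncestralKaryotype):
        return compare_karyotypes(self.karyotype, other)

    def summary(self) -> str:
        k = self.karyotype
        lines = [
            f"Ancestral karyotype at node {self.node}",
            "=" * 46,
            f"diploid number (2n)      {k.diploid_number}",
            f"conserved segments       {k.segment_count}",
            f"junctions (associations) {k.junction_count}",
            "",
            "associations: " + ", ".join(
                f"{lab} (x{m})" if m > 1 else lab
                for lab, m in sorted(k.association_multiset().items())),
            "block counts: " + ", ".join(
                f"{h}:{c}" for h, c in sorted(
                    k.blocks.items(),
                    key=lambda kv: (kv[0] != "X", len(kv[0]), kv[0]))),
            "",
            "chromosomes:",
        ]
        for chrom in k.chromosomes:
            lines.append("  " + "/".join(chrom))
        if k.variants:
            lines.append("")
            lines.append("labeled variants: " + ", ".join(
                f"{name} (2n={v.diploid_number})" for name, v in k.variants.items()))
        return "\n".join(lines)
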