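"""Host classification of CRISPR-bearing scaffolds.

A scaffold carrying a CRISPR array is evidence of past viral infection of
its source organism.  Classification is bin-first; unbinned scaffolds are
only eligible for a gene-annotation consensus when they are at least
2,500 bp long and carry at least three annotated genes — shorter or
sparser scaffolds are reported as unknown rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .taxonomy import (
    HomologyHit,
    Lineage,
    TaxonomyTree,
    rank_consensus,
)
from .viral_classify import GenomeBin, HostCall, ScaffoldRecord

logger = logging.getLogger(__name__)

MIN_SCAFFOLD_LENGTH_BP = 2500
MIN_ANNOTATED_GENES = 3


@dataclass(frozen=True)
class CrisprArray:
    start: int
    end: int
    n_repeats: int

    def __post_init__(self):
        if self.n_repeats < 2:
            raise ValueError("a CRISPR array needs >= 2 repeats")
        if not (1 <= self.start < self.end):
            raise ValueError("invalid array interval")


@dataclass
class CrisprAnnotation:
    scaffold_id: str
    arrays: list[CrisprArray]
    detector_label: str = "CRT"  # CRT | PILER-CR | other

    def validate_against(self, scaffold: ScaffoldRecord) -> None:
        if scaffold.scaffold_id != self.scaffold_id:
            raise ValueError("annotation/scaffold id mismatch")
        for arr in self.arrays:
            if arr.end > scaffold.length:
                raise ValueError(
                    f"CRISPR array [{arr.start},{arr.end}) exceeds scaffold "
                    f"{scaffold.scaffold_id} length {scaffold.length}")


@dataclass(frozen=True)
class GeneTaxonLabel:
    """A per-gene taxonomic identification with a confidence score.

    Stands in for annotation-pipeline BLAST-based gene identifications;
    ``evalue``/``bitscore`` order the labels for the two-best-score rule.
    """

    gene_id: str
    taxid: str
    evalue: float
    bitscore: float = 0.0

    def as_hit(self) -> HomologyHit:
        return HomologyHit(self.gene_id, self.gene_id, self.taxid,
                           self.evalue, self.bitscore, "nr")


def is_eligible(scaffold: ScaffoldRecord, n_annotated_genes: int) -> bool:
    """Eligibility gate for gene-based classification of unbinned scaffolds."""
    return (scaffold.length >= MIN_SCAFFOLD_LENGTH_BP
            and n_annotated_genes >= MIN_ANNOTATED_GENES)


def classify_crispr_scaffold(
    scaffold: ScaffoldRecord,
    annotation: CrisprAnnotation,
    bins: Mapping[str, GenomeBin],
    gene_labels: Sequence[GeneTaxonLabel],
    tree: TaxonomyTree,
) -> HostCall:
    """Classify one CRISPR-bearing scaffold to a host taxon.

    Binned scaffolds take the bin lineage.  Unbinned scaffolds passing the
    length/gene-count gate get a domain-level consensus over per-gene
    taxonomic labels (two best-scoring labels + strict majority); anything
    else is unknown.
    """
    annotation.validate_against(scaffold)

    if scaffold.bin_id is not None:
        gbin = bins.get(scaffold.bin_id)
        if gbin is not None and gbin.lineage:
            return HostCall(scaffold.scaffold_id, "bin", gbin.lineage,
                            gbin.domain or "unknown")

    if not is_eligible(scaffold, len(gene_labels)):
        return HostCall(scaffold.scaffold_id, "none", Lineage(), "unknown")

    hits = [lbl.as_hit() for lbl in gene_labels]
    assignment = rank_consensus(hits, tree, max_rank="domain",
                                min_classified_rank="domain")
    if assignment.lineage:
        return HostCall(scaffold.scaffold_id, "consensus_nr",
                        assignment.lineage,
                        assignment.lineage.domain or "unknown")
    return HostCall(scaffold.scaffold_id, "none", Lineage(), "unknown")


def crispr_domain_summary(calls: Sequence[HostCall]) -> dict:
    """Summarize CRISPR scaffold host calls.

    Shares of archaeal vs bacterial scaffolds are computed over the
    domain-classified calls only; the unclassified share is reported
    separately against all calls.
    """
    n = len(calls)
    classified = [c for c in calls if c.domain in ("Archaea", "Bacteria")]
    n_classified = len(classified)
    unclassified_fraction = (100.0 * (n - n_classified) / n) if n else None
    if n_classified:
        n_arch = sum(1 for c in classified if c.domain == "Archaea")
        archaeal = 100.0 * n_arch / n_classified
        bacterial = 100.0 * (n_classified - n_arch) / n_classified
    else:
        archaeal = bacterial = None

    per_taxon: dict[str, int] = {}
    for c in classified:
        name = str(c.lineage) if c.lineage else c.domain
        per_taxon[name] = per_taxon.get(name, 0) + 1

    return {
        "n_scaffolds": n,
        "n_classified": n_classified,
        "unclassified_fraction": unclassified_fraction,
        "archaeal_share_of_classified": archaeal,
        "bacterial_share_of_classified": bacterial,
        "per_taxon": dict(sorted(per_taxon.items())),
    }
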