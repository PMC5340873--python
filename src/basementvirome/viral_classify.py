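"""Viral scaffold taxonomy, host inference, and depth-weighted fractions.

Host inference for a virus-like scaffold is bin-first: a scaffold placed in
a genomic bin inherits the bin's lineage to the lowest level the bin was
identified to.  Unbinned scaffolds fall back to a domain-level consensus
over their genes' best hits against a comprehensive protein database, with
hits to viral subjects first substituted by the known host domain of that
virus.  Relative abundances are reported as depth-weighted fractions
(scaffold coverage x length, a proxy for reads assigned) rather than
scaffold counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import (
    DEFAULT_EVALUE_THRESHOLD,
    Assignment,
    HomologyHit,
    Lineage,
    TaxonomyTree,
    best_hit_per_gene,
    rank_consensus,
)

logger = logging.getLogger(__name__)

#: Viral-signal detector categories: 1-3 are free (fully viral) scaffolds at
#: decreasing confidence, 4-6 are prophages within host scaffolds.
FREE_VIRUS_CATEGORIES = frozenset({1, 2, 3})
PROPHAGE_CATEGORIES = frozenset({4, 5, 6})

PROKARYOTE_DOMAINS = frozenset({"Archaea", "Bacteria"})


@dataclass
class Gene:
    gene_id: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class ScaffoldRecord:
    """An assembled contig with coverage, genes, and viral annotation."""

    scaffold_id: str
    sample_id: str
    length: int
    mean_depth: float
    genes: list[Gene] = field(default_factory=list)
    bin_id: str | None = None
    viral_category: int | None = None
    is_prophage: bool = False

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"scaffold {self.scaffold_id}: nonpositive length")
        if self.mean_depth < 0:
            raise ValueError(f"scaffold {self.scaffold_id}: negative depth")
        for g in self.genes:
            if not (1 <= g.start <= g.end <= self.length):
                raise ValueError(
                    f"gene {g.gene_id} outside scaffold {self.scaffold_id}")

    @property
    def is_viral(self) -> bool:
        return self.viral_category is not None

    @property
    def read_weight(self) -> float:
        """Estimated reads assigned: mean depth x length."""
        return self.mean_depth * self.length


@dataclass
class GenomeBin:
    bin_id: str
    lineage: Lineage
    member_scaffolds: set[str] = field(default_factory=set)

    @property
    def domain(self) -> str | None:
        return self.lineage.domain


@dataclass
class HostCall:
    """Inferred host for one virus-like scaffold."""

    scaffold_id: str
    method: str  # "bin" | "consensus_nr" | "none"
    lineage: Lineage
    domain: str  # Archaea | Bacteria | prokaryote_unresolved | unknown


class VirSorterParseError(ValueError):
    pass


def parse_virsorter_table(path: str | Path) -> dict[str, int]:
    """Read a viral-signal detector CSV (scaffold id, category 1-6).

    Returns ``{scaffold_id: category}``.  All three confidence levels of
    both the free-virus (1-3) and prophage (4-6) classes are retained.
    """
    categories: dict[str, int] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0].lower() in ("scaffold_id", "contig_id"):
                continue  # header
            if len(parts) < 2:
                raise VirSorterParseError(
                    f"{path.name}:{lineno}: expected scaffold_id,category")
            try:
                cat = int(parts[1])
            except ValueError:
                raise VirSorterParseError(
                    f"{path.name}:{lineno}: non-integer category {parts[1]!r}"
                ) from None
            if cat not in FREE_VIRUS_CATEGORIES | PROPHAGE_CATEGORIES:
                raise VirSorterParseError(
                    f"{path.name}:{lineno}: unknown category {cat}")
            categories[parts[0]] = cat
    return categories


def apply_viral_categories(
    scaffolds: Mapping[str, ScaffoldRecord],
    categories: Mapping[str, int],
) -> None:
    """Annotate scaffolds in place with detector categories."""
    for sid, cat in categories.items():
        rec = scaffolds.get(sid)
        if rec is None:
            logger.warning("viral category for unknown scaffold %r", sid)
            continue
        rec.viral_category = cat
        rec.is_prophage = cat in PROPHAGE_CATEGORIES


def assign_viral_taxonomy(
    scaffold: ScaffoldRecord,
    viral_refseq_hits: Sequence[HomologyHit],
    tree: TaxonomyTree,
    *,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    permissive: bool = False,
) -> Assignment:
    """Consensus viral taxonomic affiliation (family level or above) from
    hits of the scaffold's proteins against a viral reference database.

    Zero significant hits gives status ``unknown``; consensus reached only
    above family gives ``undetermined``; a winning taxon that is a named but
    unplaced virus gives ``unclassified_virus``.
    """
    hits = [h for h in viral_refseq_hits if h.database == "viral_refseq"]
    best = best_hit_per_gene(hits, evalue_threshold)
    return rank_consensus(best, tree, permissive=permissive)


def _substitute_viral_hits(
    hits: Sequence[HomologyHit],
    virus_host_map: Mapping[str, str],
    tree: TaxonomyTree,
    domain_taxids: Mapping[str, str],
) -> list[HomologyHit]:
    """Replace hits to viral subjects by their virus's host domain."""
    out = []
    viruses_root = None
    for taxid in tree.taxids():
        node = tree.node(taxid)
        if node.rank == "domain" and node.name == "Viruses":
            viruses_root = taxid
            break
    for hit in hits:
        if hit.subject_taxid in tree and viruses_root is not None and \
                tree.is_under(hit.subject_taxid, viruses_root):
            host_domain = virus_host_map.get(hit.subject_taxid)
            if host_domain is None:
                logger.warning(
                    "viral hit %s has no host-domain mapping; dropped",
                    hit.subject_taxid)
                continue
            host_taxid = domain_taxids.get(host_domain)
            if host_taxid is None:
                logger.warning("host domain %r not in taxonomy; hit dropped",
                               host_domain)
                continue
            out.append(HomologyHit(hit.query_gene, hit.subject, host_taxid,
                                   hit.evalue, hit.bitscore, hit.database))
        else:
            out.append(hit)
    return out


def _domain_taxids(tree: TaxonomyTree) -> dict[str, str]:
    return {tree.node(t).name: t for t in tree.taxids()
            if tree.node(t).rank == "domain"}


def infer_host(
    scaffold: ScaffoldRecord,
    bins: Mapping[str, GenomeBin],
    nr_hits: Sequence[HomologyHit],
    virus_host_map: Mapping[str, str],
    tree: TaxonomyTree,
    *,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> HostCall:
    """Infer the likely host of one virus-like scaffold.

    Bin-first: a binned scaffold takes its bin's lineage to the lowest
    level identified.  Otherwise the call is a domain-level consensus over
    the scaffold's best per-gene hits to the comprehensive database, after
    substituting viral subjects by their hosts' domains.  A failed domain
    consensus whose hits are all prokaryotic is reported as
    ``prokaryote_unresolved``; no hits at all is ``unknown``.
    """
    if scaffold.bin_id is not None:
        gbin = bins.get(scaffold.bin_id)
        if gbin is not None and gbin.lineage:
            return HostCall(scaffold.scaffold_id, "bin", gbin.lineage,
                            gbin.domain or "unknown")
        # bin lacks a lineage: fall through to the consensus path
        logger.warning("scaffold %s in bin %r without lineage; using consensus",
                       scaffold.scaffold_id, scaffold.bin_id)

    hits = [h for h in nr_hits if h.database == "nr"]
    best = best_hit_per_gene(hits, evalue_threshold)
    domains = _domain_taxids(tree)
    best = _substitute_viral_hits(best, virus_host_map, tree, domains)
    if not best:
        return HostCall(scaffold.scaffold_id, "none", Lineage(), "unknown")

    assignment = rank_consensus(best, tree, max_rank="domain",
                                min_classified_rank="domain")
    if assignment.lineage:
        domain = assignment.lineage.domain or "unknown"
        return HostCall(scaffold.scaffold_id, "consensus_nr",
                        assignment.lineage, domain)

    # no domain-level winner: resolved to prokaryote if every hit is one
    hit_domains = {tree.lineage_of(h.subject_taxid).domain for h in best}
    if hit_domains and hit_domains <= PROKARYOTE_DOMAINS:
        return HostCall(scaffold.scaffold_id, "consensus_nr", Lineage(),
                        "prokaryote_unresolved")
    return HostCall(scaffold.scaffold_id, "none", Lineage(), "unknown")


def infer_hosts(
    scaffolds: Iterable[ScaffoldRecord],
    bins: Mapping[str, GenomeBin],
    nr_hits_by_scaffold: Mapping[str, Sequence[HomologyHit]],
    virus_host_map: Mapping[str, str],
    tree: TaxonomyTree,
    **kwargs,
) -> dict[str, HostCall]:
    return {
        s.scaffold_id: infer_host(s, bins,
                                  nr_hits_by_scaffold.get(s.scaffold_id, ()),
                                  virus_host_map, tree, **kwargs)
        for s in scaffolds
    }


@dataclass
class AgreementReport:
    percent_agreement: float | None  # None when no eligible scaffolds
    n: int
    resolved_calls: dict[str, HostCall]


def prophage_host_agreement(
    prophage_scaffolds: Sequence[ScaffoldRecord],
    bins: Mapping[str, GenomeBin],
    nr_hits_by_scaffold: Mapping[str, Sequence[HomologyHit]],
    virus_host_map: Mapping[str, str],
    tree: TaxonomyTree,
    *,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> AgreementReport:
    """Cross-validate prophage host calls between binning and consensus.

    For prophage scaffolds that are both binned and have significant hits,
    the bin's host domain is compared with the domain-level hit consensus.
    Agreement is the percentage of such scaffolds where the two methods
    name the same domain; disagreements are resolved in favor of the bin.
    """
    n = 0
    agree = 0
    resolved: dict[str, HostCall] = {}
    for scaffold in prophage_scaffolds:
        if scaffold.bin_id is None or scaffold.bin_id not in bins:
            continue
        gbin = bins[scaffold.bin_id]
        if not gbin.lineage:
            continue
        hits = nr_hits_by_scaffold.get(scaffold.scaffold_id, ())
        unbinned = ScaffoldRecord(
            scaffold.scaffold_id, scaffold.sample_id, scaffold.length,
            scaffold.mean_depth, scaffold.genes, bin_id=None,
            viral_category=scaffold.viral_category,
            is_prophage=scaffold.is_prophage)
        consensus_call = infer_host(unbinned, {}, hits, virus_host_map, tree,
                                    evalue_threshold=evalue_threshold)
        if consensus_call.method == "none":
            continue  # no significant hits: not cross-validatable
        n += 1
        if consensus_call.domain == gbin.domain:
            agree += 1
        resolved[scaffold.scaffold_id] = HostCall(
            scaffold.scaffold_id, "bin", gbin.lineage,
            gbin.domain or "unknown")
    percent = 100.0 * agree / n if n else None
    return AgreementReport(percent, n, resolved)


def depth_weighted_fractions(
    scaffolds: Sequence[ScaffoldRecord],
    calls: Mapping[str, HostCall],
    *,
    group_rank: str = "domain",
    mode: str = "depth_x_length",
) -> pd.DataFrame:
    """Share of virus-affiliated reads per host group.

    Weight per scaffold is ``mean_depth * length`` (estimated reads
    assigned, the default) or ``mean_depth`` alone (``mode="depth_only"``).
    Groups are the call's taxon at ``group_rank`` where available, else the
    call's domain category (including ``unknown``/``prokaryote_unresolved``);
    fractions over all groups sum to 1.
    """
    if mode not in ("depth_x_length", "depth_only"):
        raise ValueError(f"unknown depth-normalization mode {mode!r}")
    weights: dict[str, float] = {}
    for s in scaffolds:
        if s.length <= 0:
            raise ValueError(f"scaffold {s.scaffold_id}: nonpositive length")
        call = calls.get(s.scaffold_id)
        if call is None:
            group = "unknown"
        else:
            entry = call.lineage.at_rank(group_rank) if call.lineage else None
            group = entry.name if entry is not None else call.domain
        w = s.read_weight if mode == "depth_x_length" else s.mean_depth
        weights[group] = weights.get(group, 0.0) + w
    total = sum(weights.values())
    if total == 0:
        return pd.DataFrame(columns=["group", "weight", "fraction"])
    df = pd.DataFrame(
        [{"group": g, "weight": w, "fraction": w / total}
         for g, w in sorted(weights.items())]
    )
    return df


def prophage_bin_prevalence(
    bins: Mapping[str, GenomeBin],
    scaffolds: Sequence[ScaffoldRecord],
) -> dict[str, float]:
    """Per-domain percentage of genomic bins containing >=1 prophage scaffold."""
    prophage_bins = {s.bin_id for s in scaffolds
                     if s.is_prophage and s.bin_id is not None}
    counts: dict[str, list[int]] = {}
    for gbin in bins.values():
        domain = gbin.domain
        if domain is None:
            logger.warning("bin %r has no domain; excluded from prevalence",
                           gbin.bin_id)
            continue
        total, with_pp = counts.setdefault(domain, [0, 0])
        counts[domain][0] += 1
        if gbin.bin_id in prophage_bins:
            counts[domain][1] += 1
    return {
        f"{domain.lower()}_bins_with_prophage_percent":
            100.0 * with_pp / total
        for domain, (total, with_pp) in sorted(counts.items())
    }
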