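"""Taxonomy tree, lineages, and rank-consensus taxonomic assignment.

The consensus rule implemented here assigns a set of significant protein
homology hits to the deepest taxonomic rank at which BOTH of the following
hold:

* the two hits with the lowest E-values fall under a single taxon at that
  rank, and
* a strict majority (>50%) of all retained hits fall under that taxon.

A single significant hit is assigned the full lineage of its subject.  The
same machinery drives viral family-level classification and domain-level
host inference; callers choose how deep the walk may go.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical rank ladder from shallowest to deepest.  ``no_rank`` nodes may
#: appear anywhere in a parent chain but never terminate an assignment.
RANK_LADDER = (
    "root",
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

CANONICAL_RANKS = RANK_LADDER[1:]  # everything below root

_RANK_DEPTH = {rank: i for i, rank in enumerate(RANK_LADDER)}


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy table (cycle, orphan, duplicate)."""


class UnknownTaxidError(KeyError):
    """A taxid was looked up that is not present in the tree."""


@dataclass(frozen=True)
class TaxNode:
    taxid: str
    name: str
    rank: str
    parent: str | None
    classified: bool = True


@dataclass(frozen=True)
class LineageEntry:
    rank: str
    taxid: str
    name: str


class Lineage(tuple):
    """Ordered (rank, taxid, name) entries from domain downward.

    Ranks strictly descend the canonical ladder; ``no_rank`` nodes are not
    part of the ranked view.  An empty lineage is the degenerate truncation
    at the root.
    """

    def __new__(cls, entries: Iterable[LineageEntry] = ()):
        entries = tuple(entries)
        depths = [_RANK_DEPTH[e.rank] for e in entries]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("lineage ranks must strictly descend the ladder")
        return super().__new__(cls, entries)

    @property
    def domain(self) -> str | None:
        for e in self:
            if e.rank == "domain":
                return e.name
        return None

    def at_rank(self, rank: str) -> LineageEntry | None:
        for e in self:
            if e.rank == rank:
                return e
        return None

    def truncate(self, rank: str) -> "Lineage":
        """Lineage down to and including ``rank`` (empty if absent)."""
        depth = _RANK_DEPTH[rank]
        return Lineage(e for e in self if _RANK_DEPTH[e.rank] <= depth)

    def __str__(self) -> str:
        abbrev = {"domain": "d", "phylum": "p", "class": "c", "order": "o",
                  "family": "f", "genus": "g", "species": "s"}
        return ";".join(f"{abbrev[e.rank]}__{e.name}" for e in self)


@dataclass(frozen=True)
class HomologyHit:
    """One query-gene -> subject protein match from a homology search."""

    query_gene: str
    subject: str
    subject_taxid: str
    evalue: float
    bitscore: float
    database: str = "nr"  # "viral_refseq" or "nr"

    def __post_init__(self):
        if not (self.evalue >= 0.0):  # also rejects NaN
            raise ValueError(f"E-value must be finite and >= 0, got {self.evalue}")
        if self.bitscore < 0:
            raise ValueError(f"bit score must be >= 0, got {self.bitscore}")


#: Deterministic hit ordering: lowest E-value first, ties broken by highest
#: bit score, then lexicographic subject accession.
def hit_sort_key(hit: HomologyHit):
    return (hit.evalue, -hit.bitscore, hit.subject)


@dataclass(frozen=True)
class Assignment:
    """Result of consensus classification over a scaffold's hits.

    status:
      classified         consensus (or single hit) reached a taxon that is
                         classified in the reference taxonomy
      unclassified_virus deepest supporting node is a named virus that is
                         not classified in the reference taxonomy
      undetermined       no consensus below order level
      unknown            no significant hits at all
    """

    lineage: Lineage
    status: str
    n_genes_with_hits: int = 0
    n_hits_used: int = 0

    @property
    def deepest_rank(self) -> str | None:
        return self.lineage[-1].rank if self.lineage else None


class TaxonomyTree:
    """Rank-ordered lineage store for reference taxa, viruses, and bins."""

    def __init__(self, nodes: Iterable[TaxNode]):
        self._nodes: dict[str, TaxNode] = {}
        root = None
        for node in nodes:
            if node.taxid in self._nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid!r}")
            self._nodes[node.taxid] = node
            if node.parent is None or node.rank == "root":
                if root is not None and node.taxid != root:
                    raise TaxonomyError("multiple root nodes")
                root = node.taxid
        if root is None:
            raise TaxonomyError("taxonomy has no root node")
        self.root = root
        self._validate()
        self._lineage_cache: dict[str, Lineage] = {}
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _validate(self) -> None:
        for node in self._nodes.values():
            if node.taxid == self.root:
                continue
            if node.parent not in self._nodes:
                raise TaxonomyError(
                    f"node {node.taxid!r} has orphan parent {node.parent!r}"
                )
            # walk up; detect cycles and rank inversions
            seen = {node.taxid}
            depth = _RANK_DEPTH[node.rank] if node.rank != "no_rank" else None
            cur = node.parent
            while cur is not None:
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at taxid {cur!r}")
                seen.add(cur)
                parent = self._nodes[cur]
                if parent.rank != "no_rank" and depth is not None:
                    if _RANK_DEPTH[parent.rank] >= depth:
                        raise TaxonomyError(
                            f"rank inversion: {node.taxid!r} ({node.rank}) under "
                            f"{cur!r} ({parent.rank})"
                        )
                    break  # rank order checked against nearest ranked ancestor
                cur = parent.parent

    # -- basic queries ----------------------------------------------------

    def __contains__(self, taxid: str) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxid: str) -> TaxNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise UnknownTaxidError(f"taxid {taxid!r} not in taxonomy") from None

    def taxids(self) -> list[str]:
        return list(self._nodes)

    def children(self, taxid: str) -> list[str]:
        return [t for t, n in self._nodes.items()
                if n.parent == taxid and t != self.root]

    def ancestors(self, taxid: str) -> frozenset[str]:
        """All taxids on the path from ``taxid`` up to the root, inclusive."""
        cached = self._ancestor_cache.get(taxid)
        if cached is not None:
            return cached
        node = self.node(taxid)
        path = {taxid}
        cur = node.parent
        while cur is not None:
            path.add(cur)
            cur = self._nodes[cur].parent
        result = frozenset(path)
        self._ancestor_cache[taxid] = result
        return result

    def is_under(self, taxid: str, ancestor: str) -> bool:
        return ancestor in self.ancestors(taxid)

    def lineage_of(self, taxid: str) -> Lineage:
        """Ranked domain-to-leaf path; ``no_rank`` nodes omitted."""
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        node = self.node(taxid)
        entries: list[LineageEntry] = []
        cur: TaxNode | None = node
        while cur is not None:
            if cur.rank in _RANK_DEPTH and cur.rank != "root":
                entries.append(LineageEntry(cur.rank, cur.taxid, cur.name))
            cur = self._nodes[cur.parent] if cur.parent is not None else None
        lineage = Lineage(reversed(entries))
        self._lineage_cache[taxid] = lineage
        return lineage

    def is_classified(self, taxid: str) -> bool:
        return self.node(taxid).classified

    def ancestor_at_rank(self, taxid: str, rank: str) -> str | None:
        entry = self.lineage_of(taxid).at_rank(rank)
        return entry.taxid if entry is not None else None


def load_taxonomy(path: str | Path) -> TaxonomyTree:
    """Load a taxonomy tree from a TSV with columns
    taxid, parent, rank, name, classified (# comments allowed).

    The root node marks itself by an empty parent field or ``parent == taxid``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    required = {"taxid", "parent", "rank", "name", "classified"}
    missing = required - set(df.columns)
    if missing:
        raise TaxonomyError(f"taxonomy table missing columns: {sorted(missing)}")
    nodes = []
    for row in df.itertuples(index=False):
        parent = row.parent or None
        if parent == row.taxid:
            parent = None
        nodes.append(TaxNode(
            taxid=row.taxid,
            name=row.name,
            rank=row.rank,
            parent=parent,
            classified=str(row.classified) not in ("0", "false", "False"),
        ))
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, path: str | Path) -> None:
    rows = []
    for taxid in tree.taxids():
        n = tree.node(taxid)
        rows.append({
            "taxid": n.taxid,
            "parent": n.parent or "",
            "rank": n.rank,
            "name": n.name,
            "classified": int(n.classified),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- consensus assignment -------------------------------------------------

DEFAULT_EVALUE_THRESHOLD = 1e-5


def best_hit_per_gene(
    hits: Sequence[HomologyHit],
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> list[HomologyHit]:
    """Significance-filter hits and keep the single best hit per query gene.

    Hits with E-value above ``threshold`` are removed.  For each gene the hit
    with the lowest E-value is kept (ties: highest bit score, then
    lexicographic subject accession).  Output is sorted by ascending E-value
    under the same deterministic key.
    """
    best: dict[str, HomologyHit] = {}
    for hit in hits:
        if hit.evalue > threshold:
            continue
        incumbent = best.get(hit.query_gene)
        if incumbent is None or hit_sort_key(hit) < hit_sort_key(incumbent):
            best[hit.query_gene] = hit
    return sorted(best.values(), key=hit_sort_key)


def rank_consensus(
    hits: Sequence[HomologyHit],
    tree: TaxonomyTree,
    *,
    max_rank: str = "species",
    min_classified_rank: str = "family",
    permissive: bool = False,
) -> Assignment:
    """Assign a lineage by rank consensus over significance-filtered hits.

    With no hits the status is ``unknown``.  A single hit contributes its
    subject's full lineage.  With two or more hits the rank ladder is walked
    from the deepest rank upward; a taxon wins at a rank iff the two hits
    with the lowest E-values both lie under it and a strict majority of all
    hits lie under it.  The assignment is the lineage down to the deepest
    winning rank.

    ``max_rank`` caps how deep the walk may go (``"domain"`` gives the
    domain-only consensus used for host inference).  Assignments whose
    deepest winning rank is shallower than ``min_classified_rank`` get
    status ``undetermined``.

    ``permissive`` drops hits whose subject taxid is absent from the tree
    (with a warning) instead of raising.
    """
    resolved: list[HomologyHit] = []
    for hit in hits:
        if hit.subject_taxid not in tree:
            if permissive:
                logger.warning(
                    "dropping hit %s -> %s: taxid %r not in taxonomy",
                    hit.query_gene, hit.subject, hit.subject_taxid)
                continue
            raise UnknownTaxidError(
                f"hit subject taxid {hit.subject_taxid!r} not in taxonomy")
        resolved.append(hit)

    n = len(resolved)
    if n == 0:
        return Assignment(Lineage(), "unknown", 0, 0)

    n_genes = len({h.query_gene for h in resolved})

    if n == 1:
        leaf = resolved[0].subject_taxid
        lineage = tree.lineage_of(leaf).truncate(max_rank)
        status = "classified" if tree.is_classified(leaf) else "unclassified_virus"
        if not lineage:
            status = "undetermined"
        elif _RANK_DEPTH[lineage[-1].rank] < _RANK_DEPTH[min_classified_rank]:
            status = "undetermined"
        return Assignment(lineage, status, n_genes, 1)

    ordered = sorted(resolved, key=hit_sort_key)
    top_two = ordered[:2]
    majority = n / 2.0

    winner: str | None = None
    max_depth = _RANK_DEPTH[max_rank]
    for rank in reversed(RANK_LADDER[1:max_depth + 1]):
        candidate = tree.ancestor_at_rank(top_two[0].subject_taxid, rank)
        if candidate is None:
            continue
        if tree.ancestor_at_rank(top_two[1].subject_taxid, rank) != candidate:
            continue
        support = sum(
            1 for h in ordered
            if tree.ancestor_at_rank(h.subject_taxid, rank) == candidate
        )
        if support > majority:
            winner = candidate
            break

    if winner is None:
        return Assignment(Lineage(), "undetermined", n_genes, n)

    lineage = tree.lineage_of(winner)
    if _RANK_DEPTH[lineage[-1].rank] < _RANK_DEPTH[min_classified_rank]:
        status = "undetermined"
    elif tree.is_classified(winner):
        status = "classified"
    else:
        status = "unclassified_virus"
    return Assignment(lineage, status, n_genes, n)
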