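"""Taxonomy tree structure, lineage traversal, and consensus assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from basementvirome.taxonomy import (
    Assignment,
    HomologyHit,
    Lineage,
    RANK_LADDER,
    TaxNode,
    TaxonomyError,
    TaxonomyTree,
    UnknownTaxidError,
    best_hit_per_gene,
    hit_sort_key,
    load_taxonomy,
    rank_consensus,
    write_taxonomy,
)

from conftest import random_tree

_RANK_DEPTH = {rank: i for i, rank in enumerate(RANK_LADDER)}


def vhit(gene, taxid, evalue, bitscore=50.0, subject=None):
    return HomologyHit(gene, subject or f"{taxid}|{gene}", taxid, evalue,
                       bitscore, "viral_refseq")


# -- tree construction ----------------------------------------------------

class TestTreeConstruction:
    def test_minimal_three_node_tree(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("taxid\tparent\trank\tname\tclassified\n"
                     "1\t\troot\troot\t1\n"
                     "2\t1\tdomain\tArchaea\t1\n"
                     "3\t1\tdomain\tBacteria\t1\n")
        tree = load_taxonomy(p)
        assert len(tree) == 3
        domains = [t for t in tree.taxids() if tree.node(t).rank == "domain"]
        assert len(domains) == 2

    def test_orphan_parent_rejected(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("taxid\tparent\trank\tname\tclassified\n"
                     "1\t\troot\troot\t1\n"
                     "2\t99\tdomain\tArchaea\t1\n")
        with pytest.raises(TaxonomyError, match="orphan"):
            load_taxonomy(p)

    def test_cycle_rejected(self):
        with pytest.raises(TaxonomyError):
            TaxonomyTree([
                TaxNode("1", "root", "root", None),
                TaxNode("a", "a", "no_rank", "b"),
                TaxNode("b", "b", "no_rank", "a"),
            ])

    def test_duplicate_taxid_rejected(self):
        with pytest.raises(TaxonomyError, match="duplicate"):
            TaxonomyTree([
                TaxNode("1", "root", "root", None),
                TaxNode("a", "a", "domain", "1"),
                TaxNode("a", "a2", "domain", "1"),
            ])

    def test_toy_taxonomy_has_caudovirales_families(self, tree):
        families = [t for t in tree.taxids()
                    if tree.node(t).rank == "family"
                    and tree.is_under(t, "V.caud")]
        assert len(families) >= 3

    def test_taxonomy_roundtrip(self, tree, tmp_path):
        p = tmp_path / "tax.tsv"
        write_taxonomy(tree, p)
        reloaded = load_taxonomy(p)
        assert set(reloaded.taxids()) == set(tree.taxids())
        for t in tree.taxids():
            assert reloaded.node(t) == tree.node(t)


# -- lineage traversal ----------------------------------------------------

class TestLineage:
    def test_direct_family_path(self, tree):
        lin = tree.lineage_of("V.myo")
        assert [(e.rank, e.name) for e in lin] == [
            ("domain", "Viruses"),
            ("order", "Caudovirales"),
            ("family", "Myoviridae"),
        ]

    def test_root_has_empty_ranked_lineage(self, tree):
        assert tree.lineage_of(tree.root) == Lineage()

    def test_no_rank_nodes_omitted_but_ancestry_kept(self, tree):
        lin = tree.lineage_of("V.halo.s1")
        assert all(e.rank != "no_rank" for e in lin)
        assert tree.is_under("V.halo.s1", "V.halo")

    def test_unknown_taxid_raises(self, tree):
        with pytest.raises(UnknownTaxidError):
            tree.lineage_of("not-a-taxid")

    def test_lineage_matches_brute_force_parent_walk(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            tree = random_tree(rng, n_nodes=50)
            taxid = f"n{rng.integers(0, 50)}"
            # independent parent-following walk
            path = []
            cur = taxid
            while cur is not None:
                node = tree.node(cur)
                if node.rank not in ("root", "no_rank"):
                    path.append((node.rank, node.taxid, node.name))
                cur = node.parent
            path.reverse()
            assert [(e.rank, e.taxid, e.name)
                    for e in tree.lineage_of(taxid)] == path


# -- best hit per gene ----------------------------------------------------

class TestBestHitPerGene:
    def test_threshold_filters_then_keeps_minimum(self):
        hits = [vhit("g1", "a", 1e-3), vhit("g1", "b", 1e-8)]
        kept = best_hit_per_gene(hits, 1e-5)
        assert len(kept) == 1 and kept[0].evalue == 1e-8

    def test_per_gene_minimum_over_two_genes(self):
        # 2 genes x 3 hits; hand-enumerated minima are b (1e-12) and e (1e-9)
        hits = [
            vhit("g1", "a", 1e-10), vhit("g1", "b", 1e-12), vhit("g1", "c", 1e-6),
            vhit("g2", "d", 1e-7), vhit("g2", "e", 1e-9), vhit("g2", "f", 1e-8),
        ]
        kept = best_hit_per_gene(hits, 1e-5)
        assert {h.subject_taxid for h in kept} == {"b", "e"}
        assert [h.evalue for h in kept] == sorted(h.evalue for h in kept)

    def test_all_above_threshold_gives_empty(self):
        assert best_hit_per_gene([vhit("g1", "a", 1e-2)], 1e-5) == []

    def test_evalue_tie_broken_by_bitscore_then_accession(self):
        hits = [vhit("g1", "a", 1e-8, bitscore=40.0, subject="zzz"),
                vhit("g1", "b", 1e-8, bitscore=60.0, subject="aaa")]
        assert best_hit_per_gene(hits)[0].subject_taxid == "b"
        hits = [vhit("g1", "a", 1e-8, bitscore=40.0, subject="zzz"),
                vhit("g1", "b", 1e-8, bitscore=40.0, subject="aaa")]
        assert best_hit_per_gene(hits)[0].subject_taxid == "b"


# -- rank consensus: examples ---------------------------------------------

class TestRankConsensus:
    def test_family_consensus_from_two_species_one_dissenter(self, tree):
        # two lowest-E hits in Myoviridae (different species), one Siphoviridae:
        # family wins via the top-2 + 2/3 strict majority conditions
        hits = [vhit("g1", "V.myo.s", 1e-20), vhit("g2", "V.myo.s2", 1e-15),
                vhit("g3", "V.sipho.s", 1e-8)]
        a = rank_consensus(hits, tree)
        assert a.status == "classified"
        assert a.lineage[-1].name == "Myoviridae"

    def test_split_top_two_truncates_at_order(self, tree):
        # top-2 in different families: family fails condition (a); order passes
        hits = [vhit("g1", "V.myo.s", 1e-20), vhit("g2", "V.sipho.s", 1e-18)]
        a = rank_consensus(hits, tree)
        assert a.status == "undetermined"
        assert a.lineage[-1].name == "Caudovirales"

    def test_single_hit_to_unclassified_halovirus(self, tree):
        a = rank_consensus([vhit("g1", "V.halo.s1", 1e-10)], tree)
        assert a.status == "unclassified_virus"
        assert a.lineage[-1].name == "Halovirus HVTV-1"

    def test_empty_hits_unknown(self, tree):
        a = rank_consensus([], tree)
        assert a.status == "unknown" and a.lineage == Lineage()

    def test_unclassified_consensus_winner_flagged(self, tree):
        hits = [vhit("g1", "V.halo.s1", 1e-20), vhit("g2", "V.halo.s1", 1e-10)]
        a = rank_consensus(hits, tree)
        assert a.status == "unclassified_virus"

    def test_missing_taxid_raises_unless_permissive(self, tree):
        hits = [vhit("g1", "nope", 1e-20), vhit("g2", "V.myo.s", 1e-10)]
        with pytest.raises(UnknownTaxidError):
            rank_consensus(hits, tree)
        a = rank_consensus(hits, tree, permissive=True)
        assert a.n_hits_used == 1
        assert a.lineage[-1].taxid == "V.myo.s"


# -- rank consensus: properties -------------------------------------------

def oracle_consensus(hits, tree, max_rank="species"):
    """Brute force: test both conditions independently at EVERY node and
    take the deepest passing canonical-rank node (parent-walk ancestry)."""

    def under(taxid, node):
        cur = taxid
        while cur is not None:
            if cur == node:
                return True
            cur = tree.node(cur).parent
        return False

    ordered = sorted(hits, key=hit_sort_key)
    top_two = ordered[:2]
    best = None
    for node in tree.taxids():
        rank = tree.node(node).rank
        if rank in ("root", "no_rank"):
            continue
        if _RANK_DEPTH[rank] > _RANK_DEPTH[max_rank]:
            continue
        if not all(under(h.subject_taxid, node) for h in top_two):
            continue
        support = sum(1 for h in ordered if under(h.subject_taxid, node))
        if support <= len(ordered) / 2:
            continue
        if best is None or _RANK_DEPTH[rank] > _RANK_DEPTH[tree.node(best).rank]:
            best = node
    return best


def random_hits(rng, tree, n_max=10):
    taxids = tree.taxids()
    n = int(rng.integers(2, n_max + 1))
    return [
        HomologyHit(f"g{i}", f"s{i}", taxids[int(rng.integers(0, len(taxids)))],
                    float(10.0 ** rng.uniform(-30, -6)),
                    float(rng.uniform(20, 100)), "viral_refseq")
        for i in range(n)
    ]


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_consensus_matches_all_nodes_oracle(seed):
    """The ladder walk equals an exhaustive every-node test of both
    consensus conditions on random trees and random hit sets."""
    rng = np.random.default_rng(seed)
    tree = random_tree(rng, n_nodes=int(rng.integers(5, 51)))
    hits = random_hits(rng, tree)
    expected = oracle_consensus(hits, tree)
    got = rank_consensus(hits, tree)
    if expected is None:
        assert got.lineage == Lineage()
    else:
        assert got.lineage[-1].taxid == expected


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_consensus_permutation_invariant(seed):
    rng = np.random.default_rng(seed)
    tree = random_tree(rng, n_nodes=30)
    hits = random_hits(rng, tree)
    base = rank_consensus(hits, tree)
    perm = list(hits)
    rng.shuffle(perm)
    assert rank_consensus(perm, tree) == base


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_adding_supporting_hit_never_shallows_assignment(seed):
    """A new hit under the current deepest node keeps or deepens the call."""
    rng = np.random.default_rng(seed)
    tree = random_tree(rng, n_nodes=30)
    hits = random_hits(rng, tree)
    base = rank_consensus(hits, tree)
    if not base.lineage:
        return
    deepest = base.lineage[-1].taxid
    descendants = [t for t in tree.taxids() if tree.is_under(t, deepest)]
    extra = HomologyHit("g_new", "s_new",
                        descendants[int(rng.integers(0, len(descendants)))],
                        float(10.0 ** rng.uniform(-30, -6)), 50.0,
                        "viral_refseq")
    more = rank_consensus(list(hits) + [extra], tree)
    assert len(more.lineage) >= len(base.lineage)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_single_and_duplicate_hits_give_full_lineage(seed):
    rng = np.random.default_rng(seed)
    tree = random_tree(rng, n_nodes=30)
    taxid = f"n{rng.integers(1, 30)}"
    one = [HomologyHit("g1", "s1", taxid, 1e-10, 50.0, "viral_refseq")]
    two = one + [HomologyHit("g2", "s2", taxid, 1e-8, 40.0, "viral_refseq")]
    full = tree.lineage_of(taxid)
    assert rank_consensus(one, tree).lineage == full
    assert rank_consensus(two, tree).lineage == full
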