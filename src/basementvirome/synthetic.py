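"""Ground-truthed synthetic communities for end-to-end pipeline testing.

The generator emulates the inputs the pipeline consumes — scaffold tables
with coverage, genomic bins, per-gene homology hits against a viral and a
comprehensive reference set, CRISPR annotations — with planted host
lineages, so that recovered quantities (depth-weighted host fractions,
prophage agreement, CRISPR shares) can be checked against known truth.

Scaffold lengths are log-uniform and coverages log-normal, generic
assembly-like marginals; the ``weight_matching`` allocation rescales
coverages so planted depth-weighted domain fractions are met exactly,
giving deterministic expectations for the noise-free pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .crispr import CrisprAnnotation, CrisprArray
from .fluids import FluidSample
from .taxonomy import HomologyHit, TaxNode, TaxonomyTree
from .viral_classify import Gene, GenomeBin, ScaffoldRecord

# ---------------------------------------------------------------------------
# toy taxonomy

_TOY_NODES: list[tuple] = [
    # (taxid, rank, name, parent, classified)
    ("root", "root", "root", None, True),
    ("A", "domain", "Archaea", "root", True),
    ("B", "domain", "Bacteria", "root", True),
    ("E", "domain", "Eukaryota", "root", True),
    ("V", "domain", "Viruses", "root", True),
    # Archaea
    ("A.eury", "phylum", "Euryarchaeota", "A", True),
    ("A.arcg", "class", "Archaeoglobi", "A.eury", True),
    ("A.arcg.o", "order", "Archaeoglobales", "A.arcg", True),
    ("A.arcg.f", "family", "Archaeoglobaceae", "A.arcg.o", True),
    ("A.arcg.g", "genus", "Archaeoglobus", "A.arcg.f", True),
    ("A.arcg.s", "species", "Archaeoglobus fulgidus", "A.arcg.g", True),
    ("A.thmc", "class", "Thermococci", "A.eury", True),
    ("A.thmc.s", "species", "Thermococcus sp.", "A.thmc", True),
    ("A.bathy", "phylum", "Bathyarchaeota", "A", True),
    ("A.bathy.s", "species", "Bathyarchaeota archaeon", "A.bathy", True),
    ("A.mbge", "phylum", "MBG-E", "A", True),
    ("A.mbge.s", "species", "MBG-E archaeon", "A.mbge", True),
    ("A.aig", "phylum", "Aigarchaeota", "A", True),
    ("A.thscg", "class", "THSCG", "A.aig", True),
    ("A.thscg.s", "species", "THSCG archaeon", "A.thscg", True),
    # Bacteria
    ("B.nitr", "phylum", "Nitrospirae", "B", True),
    ("B.nitr.c", "class", "Nitrospira", "B.nitr", True),
    ("B.nitr.o", "order", "Nitrospirales", "B.nitr.c", True),
    ("B.nitr.f", "family", "Nitrospiraceae", "B.nitr.o", True),
    ("B.nitr.g", "genus", "Nitrospira", "B.nitr.f", True),
    ("B.nitr.s", "species", "Nitrospira moscoviensis", "B.nitr.g", True),
    ("B.amin", "phylum", "Aminicenantes", "B", True),
    ("B.amin.s", "species", "Aminicenantes bacterium", "B.amin", True),
    ("B.chlf", "phylum", "Chloroflexi", "B", True),
    ("B.chlf.s", "species", "Chloroflexi bacterium", "B.chlf", True),
    ("B.em3", "phylum", "EM3", "B", True),
    ("B.em3.s", "species", "EM3 bacterium", "B.em3", True),
    ("B.acet", "phylum", "Acetothermia", "B", True),
    ("B.acet.s", "species", "Acetothermia bacterium", "B.acet", True),
    ("B.prot", "phylum", "Proteobacteria", "B", True),
    ("B.prot.s", "species", "Proteobacteria bacterium", "B.prot", True),
    # Eukaryota (minimal; megavirus host)
    ("E.s", "species", "Acanthamoeba castellanii", "E", True),
    # Viruses: tailed phages
    ("V.caud", "order", "Caudovirales", "V", True),
    ("V.myo", "family", "Myoviridae", "V.caud", True),
    ("V.myo.s", "species", "Myovirus sp.", "V.myo", True),
    ("V.myo.s2", "species", "Halomyovirus sp.", "V.myo", True),
    ("V.sipho", "family", "Siphoviridae", "V.caud", True),
    ("V.sipho.s", "species", "Siphovirus sp.", "V.sipho", True),
    ("V.sipho.s2", "species", "Halosiphovirus sp.", "V.sipho", True),
    ("V.podo", "family", "Podoviridae", "V.caud", True),
    ("V.podo.s", "species", "Podovirus sp.", "V.podo", True),
    ("V.podo.s2", "species", "Halopodovirus sp.", "V.podo", True),
    # tailed haloviruses, named but not yet classified
    ("V.halo", "no_rank", "unclassified archaeal tailed viruses", "V", False),
    ("V.halo.s1", "species", "Halovirus HVTV-1", "V.halo", False),
    ("V.halo.s2", "species", "Halovirus HSTV-2", "V.halo", False),
    # fusiform clade
    ("V.bicauda", "family", "Bicaudaviridae", "V", True),
    ("V.bicauda.s", "species", "Acidianus two-tailed virus", "V.bicauda", True),
    ("V.fusi", "no_rank", "unclassified fusiform archaeal viruses", "V", False),
    ("V.fusi.s", "species", "Fusiform virus His1-like", "V.fusi", False),
    # proposed giant-virus order
    ("V.mega", "order", "Megavirales", "V", False),
    ("V.mega.s", "species", "Mimivirus-like virus", "V.mega", False),
]

#: Host domain for each viral leaf in the toy taxonomy.
TOY_VIRUS_HOST_MAP: dict[str, str] = {
    "V.myo.s": "Bacteria",
    "V.myo.s2": "Archaea",
    "V.sipho.s": "Bacteria",
    "V.sipho.s2": "Archaea",
    "V.podo.s": "Bacteria",
    "V.podo.s2": "Archaea",
    "V.halo.s1": "Archaea",
    "V.halo.s2": "Archaea",
    "V.bicauda.s": "Archaea",
    "V.fusi.s": "Archaea",
    "V.mega.s": "Eukaryota",
}

#: Which viral leaves plausibly infect each prokaryotic domain (used when
#: planting true virus taxa for scaffolds with a known host domain).
_VIRUS_BY_HOST = {
    "Archaea": ("V.halo.s1", "V.halo.s2", "V.bicauda.s", "V.fusi.s"),
    "Bacteria": ("V.myo.s", "V.sipho.s", "V.podo.s"),
}


def make_toy_taxonomy(seed: int = 0) -> tuple[TaxonomyTree, dict[str, str]]:
    """Deterministic small taxonomy with the lineages of the study system.

    Returns the tree and a virus-taxid -> host-domain map.  ``seed`` is
    accepted for interface uniformity; the tree is fixed.
    """
    nodes = [TaxNode(t, name, rank, parent, classified)
             for t, rank, name, parent, classified in _TOY_NODES]
    return TaxonomyTree(nodes), dict(TOY_VIRUS_HOST_MAP)


# ---------------------------------------------------------------------------
# community simulation


@dataclass(frozen=True)
class CommunityConfig:
    """Study conditions for a simulated borehole community.

    Defaults mirror the observed system where stated (80/20 archaeal vs
    bacterial depth-weighted host fractions for the viral scaffolds,
    roughly a fifth of viral scaffolds being prophages); the remaining
    marginals are generic assembly-like choices.
    """

    n_scaffolds: int = 300
    host_domain_depth_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"Archaea": 0.80, "Bacteria": 0.20})
    length_bounds_bp: tuple[int, int] = (1000, 100_000)
    depth_lognormal_mu: float = 2.0
    depth_lognormal_sigma: float = 1.0
    binning_rate: float = 0.5
    viral_rate: float = 0.2
    prophage_rate: float = 0.2     # share of viral scaffolds that are prophages
    crispr_rate: float = 0.1       # share of cellular scaffolds with an array
    genes_per_kb: float = 1.0
    allocation: str = "weight_matching"  # or "greedy"
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.host_domain_depth_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("host domain fractions must sum to 1")
        for name in ("binning_rate", "viral_rate", "prophage_rate",
                     "crispr_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.allocation not in ("weight_matching", "greedy"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if self.n_scaffolds < 1:
            raise ValueError("need at least one scaffold")


@dataclass(frozen=True)
class HitNoiseConfig:
    p_correct_lineage: float = 1.0
    p_virus_subject: float = 0.2   # nr hits routed through a viral subject
    evalue_log10_bounds: tuple[float, float] = (-30.0, -6.0)
    hits_per_gene: tuple[int, int] = (1, 5)
    p_gene_no_hit: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_correct_lineage", "p_virus_subject", "p_gene_no_hit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class ScaffoldTruth:
    host_taxid: str | None      # species-level source organism (None: free virus)
    host_domain: str | None
    virus_taxid: str | None     # planted virus for viral scaffolds


@dataclass
class SimulatedCommunity:
    scaffolds: dict[str, ScaffoldRecord]
    bins: dict[str, GenomeBin]
    crispr: list[CrisprAnnotation]
    truth: dict[str, ScaffoldTruth]

    @property
    def viral_scaffolds(self) -> list[ScaffoldRecord]:
        return [s for s in self.scaffolds.values() if s.is_viral]


def _species_by_domain(tree: TaxonomyTree) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for taxid in tree.taxids():
        node = tree.node(taxid)
        if node.rank != "species":
            continue
        domain = tree.lineage_of(taxid).domain
        if domain in ("Archaea", "Bacteria"):
            out.setdefault(domain, []).append(taxid)
    return out


def _allocate_domains(weights: np.ndarray, fractions: Mapping[str, float],
                      rng: np.random.Generator) -> list[str]:
    """Greedy largest-deficit allocation of scaffolds to domains.

    Scaffolds are visited in descending weight order (randomized among
    ties) and each goes to the domain whose running weight share is
    furthest below its target, keeping realized depth-weight shares within
    one scaffold weight of the targets.
    """
    domains = list(fractions)
    targets = np.array([fractions[d] for d in domains])
    total = weights.sum()
    got = np.zeros(len(domains))
    order = np.argsort(-weights + rng.uniform(0, 1e-9, size=len(weights)))
    assigned = [""] * len(weights)
    for i in order:
        deficit = targets - got / total
        j = int(np.argmax(deficit))
        assigned[i] = domains[j]
        got[j] += weights[i]
    return assigned


def simulate_community(cfg: CommunityConfig,
                       tree: TaxonomyTree) -> SimulatedCommunity:
    """Generate scaffolds, bins, CRISPR annotations and truth labels.

    Every scaffold carries a true source lineage.  Viral scaffolds'
    depth-weighted host-domain shares follow
    ``cfg.host_domain_depth_fractions`` — exactly in the default
    ``weight_matching`` allocation (coverages rescaled per domain group),
    approximately under ``greedy``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    species = _species_by_domain(tree)
    n = cfg.n_scaffolds

    lo, hi = cfg.length_bounds_bp
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)
    lengths = np.clip(lengths, lo, hi)
    depths = rng.lognormal(cfg.depth_lognormal_mu, cfg.depth_lognormal_sigma,
                           size=n)

    n_viral = int(round(cfg.viral_rate * n))
    is_viral = np.zeros(n, dtype=bool)
    is_viral[rng.choice(n, size=n_viral, replace=False)] = True

    # host-domain allocation for viral scaffolds
    viral_idx = np.flatnonzero(is_viral)
    weights = depths[viral_idx] * lengths[viral_idx]
    domains_for_viral = _allocate_domains(
        weights, cfg.host_domain_depth_fractions, rng)
    if cfg.allocation == "weight_matching" and len(viral_idx):
        total = weights.sum()
        by_domain: dict[str, list[int]] = {}
        for pos, d in enumerate(domains_for_viral):
            by_domain.setdefault(d, []).append(pos)
        for d, positions in by_domain.items():
            current = weights[positions].sum()
            target = cfg.host_domain_depth_fractions[d] * total
            scale = target / current
            for pos in positions:
                depths[viral_idx[pos]] *= scale

    scaffolds: dict[str, ScaffoldRecord] = {}
    truth: dict[str, ScaffoldTruth] = {}
    bins: dict[str, GenomeBin] = {}
    crispr: list[CrisprAnnotation] = []

    cell_domains = list(cfg.host_domain_depth_fractions)
    viral_pos = {int(i): d for i, d in zip(viral_idx, domains_for_viral)}
    n_prophage_target = int(round(cfg.prophage_rate * n_viral))

    viral_seen = 0
    for i in range(n):
        sid = f"scf{i:05d}"
        length = int(lengths[i])
        n_genes = max(1, int(round(cfg.genes_per_kb * length / 1000.0)))
        genes = []
        gene_span = length // n_genes
        for g in range(n_genes):
            start = g * gene_span + 1
            end = min(length, start + max(2, gene_span - 2))
            genes.append(Gene(f"{sid}_g{g:03d}", start, end,
                              "+" if rng.random() < 0.5 else "-"))

        if i in viral_pos:
            domain = viral_pos[i]
            host_taxid = str(rng.choice(species[domain]))
            virus_taxid = str(rng.choice(_VIRUS_BY_HOST[domain]))
            is_prophage = viral_seen < n_prophage_target
            viral_seen += 1
            category = int(rng.integers(4, 7)) if is_prophage \
                else int(rng.integers(1, 4))
        else:
            domain = cell_domains[int(rng.choice(len(cell_domains)))]
            host_taxid = str(rng.choice(species[domain]))
            virus_taxid = None
            is_prophage = False
            category = None

        bin_id = None
        if rng.random() < cfg.binning_rate:
            bin_id = f"bin_{host_taxid}"
            if bin_id not in bins:
                bins[bin_id] = GenomeBin(bin_id, tree.lineage_of(host_taxid),
                                         set())
            bins[bin_id].member_scaffolds.add(sid)

        rec = ScaffoldRecord(sid, "synthetic", length, float(depths[i]),
                             genes, bin_id=bin_id, viral_category=category,
                             is_prophage=is_prophage)
        scaffolds[sid] = rec
        truth[sid] = ScaffoldTruth(host_taxid, domain, virus_taxid)

        if category is None and rng.random() < cfg.crispr_rate:
            arr_len = min(400, length - 1)
            start = int(rng.integers(1, max(2, length - arr_len)))
            crispr.append(CrisprAnnotation(
                sid, [CrisprArray(start, start + arr_len,
                                  int(rng.integers(2, 30)))],
                "CRT" if rng.random() < 0.5 else "PILER-CR"))

    return SimulatedCommunity(scaffolds, bins, crispr, truth)


def simulate_hits(
    community: SimulatedCommunity,
    tree: TaxonomyTree,
    noise: HitNoiseConfig,
    virus_host_map: Mapping[str, str] | None = None,
) -> dict[str, dict[str, list[HomologyHit]]]:
    """Per-scaffold homology-hit tables for both reference-set roles.

    Viral scaffolds get hits against the viral reference set (subjects are
    virus leaves; correct with probability ``p_correct_lineage``) and
    against the comprehensive set (subjects drawn from the true host
    lineage, or — with probability ``p_virus_subject`` — a virus whose
    known host matches).  With ``p_correct_lineage=1`` and
    ``p_gene_no_hit=0`` every gene's best hit lies under its true lineage.
    """
    noise.validate()
    if virus_host_map is None:
        virus_host_map = TOY_VIRUS_HOST_MAP
    rng = np.random.default_rng(noise.seed)
    species = _species_by_domain(tree)
    all_virus = sorted(virus_host_map)
    lo10, hi10 = noise.evalue_log10_bounds

    def draw_evalues(k: int, correct: np.ndarray) -> np.ndarray:
        ev = 10.0 ** rng.uniform(lo10, hi10, size=k)
        ev.sort()
        # correct hits take the most significant E-values
        out = np.empty(k)
        order = np.argsort(~correct, kind="stable")  # correct first
        out[order] = ev
        return out

    def gene_hits(gene_id: str, true_subject: str, pool: Sequence[str],
                  database: str) -> list[HomologyHit]:
        if rng.random() < noise.p_gene_no_hit:
            return []
        k = int(rng.integers(noise.hits_per_gene[0],
                             noise.hits_per_gene[1] + 1))
        correct = rng.random(k) < noise.p_correct_lineage
        evalues = draw_evalues(k, correct)
        hits = []
        for j in range(k):
            if correct[j]:
                subject_taxid = true_subject
            else:
                others = [p for p in pool if p != true_subject] or [true_subject]
                subject_taxid = str(rng.choice(others))
            bitscore = max(0.0, -2.0 * np.log10(evalues[j]))
            hits.append(HomologyHit(gene_id, f"{subject_taxid}.p{j}",
                                    subject_taxid, float(evalues[j]),
                                    float(bitscore), database))
        return hits

    viral_tables: dict[str, list[HomologyHit]] = {}
    nr_tables: dict[str, list[HomologyHit]] = {}
    cell_pool = sorted(species["Archaea"]) + sorted(species["Bacteria"])

    for sid, rec in community.scaffolds.items():
        t = community.truth[sid]
        if rec.is_viral:
            vhits: list[HomologyHit] = []
            nhits: list[HomologyHit] = []
            for g in rec.genes:
                vhits.extend(gene_hits(g.gene_id, t.virus_taxid, all_virus,
                                       "viral_refseq"))
                if rng.random() < noise.p_virus_subject:
                    # nr best hit is to a virus infecting the true host domain
                    candidates = [v for v in all_virus
                                  if virus_host_map[v] == t.host_domain]
                    subject = str(rng.choice(candidates)) if candidates \
                        else t.host_taxid
                    nhits.extend(gene_hits(g.gene_id, subject, all_virus, "nr"))
                else:
                    nhits.extend(gene_hits(g.gene_id, t.host_taxid, cell_pool,
                                           "nr"))
            viral_tables[sid] = vhits
            nr_tables[sid] = nhits
        else:
            nr_tables[sid] = [
                h for g in rec.genes
                for h in gene_hits(g.gene_id, t.host_taxid, cell_pool, "nr")
            ]
    return {"viral_refseq": viral_tables, "nr": nr_tables}


# ---------------------------------------------------------------------------
# printed fluid-sample table


def table1_fixture() -> list[FluidSample]:
    """The published fluid-sample table as typed records (microscopy rows).

    Includes the eight basement virus counts, the seven cell counts (the
    filtered-only sample is flagged ``excluded_from_cells``), and the
    near-bottom-seawater reference row.
    """
    from importlib.resources import files

    from .io_tables import read_fluids

    path = files("basementvirome.data").joinpath("table1.tsv")
    samples = read_fluids(str(path))
    return [s for s in samples if s.virus_conc is not None]


def basement_samples(samples: Sequence[FluidSample]) -> list[FluidSample]:
    """Drop reference seawater rows, keeping borehole samples only."""
    return [s for s in samples if s.location.startswith("U1362")]
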