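"""End-to-end orchestration: load inputs, run every stage, write reports.

The run directory receives per-scaffold viral taxonomy and host-call
tables, depth-weighted fraction tables for hosts and viral taxa, the
CRISPR summary, the fluid purity/abundance summary, and a manifest
recording parameters and seed so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import crispr as crispr_mod
from . import fluids as fluids_mod
from . import io_tables, viral_classify
from .taxonomy import DEFAULT_EVALUE_THRESHOLD, load_taxonomy

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    taxonomy: str
    scaffolds: str
    genes: str | None = None
    bins: str | None = None
    viral_hits: str | None = None
    nr_hits: str | None = None
    crispr: str | None = None
    gene_labels: str | None = None  # per-gene taxon labels for CRISPR path
    fluids: str | None = None
    virus_host_map: str | None = None  # TSV: taxid, host_domain
    output_dir: str = "run"
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD
    depth_mode: str = "depth_x_length"
    mg_seawater: float = 53.0
    mg_crustal: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("E-value threshold must be > 0")
        for name in ("taxonomy", "scaffolds", "genes", "bins", "viral_hits",
                     "nr_hits", "crispr", "gene_labels", "fluids",
                     "virus_host_map"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")


def read_virus_host_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    return dict(zip(df["taxid"], df["host_domain"]))


def write_virus_host_map(mapping: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        [{"taxid": k, "host_domain": v} for k, v in sorted(mapping.items())],
        columns=("taxid", "host_domain"),
    ).to_csv(path, sep="\t", index=False)


def run_all(config: PipelineConfig) -> dict:
    """Run every applicable stage; returns the report bundle as a dict.

    Output files are only written once all stages succeed, so a failing
    stage leaves no partial outputs.
    """
    config.validate()
    outdir = Path(config.output_dir)
    tree = load_taxonomy(config.taxonomy)
    report: dict = {}
    outputs: list[tuple[str, object, str]] = []  # (filename, payload, kind)

    scaffolds = io_tables.read_scaffolds(config.scaffolds, config.genes)
    bins = io_tables.read_bins(config.bins, tree) if config.bins else {}
    vhm = read_virus_host_map(config.virus_host_map) \
        if config.virus_host_map else {}

    viral_scaffolds = [s for s in scaffolds.values() if s.is_viral]

    if config.viral_hits:
        vhits = io_tables.read_hits_by_scaffold(config.viral_hits)
        assignments = {
            s.scaffold_id: viral_classify.assign_viral_taxonomy(
                s, vhits.get(s.scaffold_id, ()), tree,
                evalue_threshold=config.evalue_threshold)
            for s in viral_scaffolds
        }
        outputs.append(("viral_taxonomy.tsv", assignments, "assignments"))
        status_counts = pd.Series(
            [a.status for a in assignments.values()]).value_counts()
        report["viral_taxonomy_status_counts"] = status_counts.to_dict()

    if config.nr_hits:
        nr = io_tables.read_hits_by_scaffold(config.nr_hits)
        calls = viral_classify.infer_hosts(
            viral_scaffolds, bins, nr, vhm, tree,
            evalue_threshold=config.evalue_threshold)
        outputs.append(("host_calls.tsv", calls, "calls"))
        fractions = viral_classify.depth_weighted_fractions(
            viral_scaffolds, calls, mode=config.depth_mode)
        outputs.append(("host_fractions.tsv", fractions, "frame"))
        report["host_domain_fractions"] = {
            row.group: row.fraction for row in fractions.itertuples()}

        prophages = [s for s in viral_scaffolds if s.is_prophage]
        agreement = viral_classify.prophage_host_agreement(
            prophages, bins, nr, vhm, tree,
            evalue_threshold=config.evalue_threshold)
        report["prophage_agreement_percent"] = agreement.percent_agreement
        report["prophage_agreement_n"] = agreement.n
        if bins:
            report["prophage_bin_prevalence"] = \
                viral_classify.prophage_bin_prevalence(
                    bins, list(scaffolds.values()))

    if config.crispr:
        annotations = io_tables.read_crispr(config.crispr)
        labels_by_scaffold: dict[str, list] = {}
        if config.gene_labels:
            df = pd.read_csv(config.gene_labels, sep="\t", comment="#",
                             dtype=str, keep_default_na=False)
            for row in df.itertuples(index=False):
                labels_by_scaffold.setdefault(row.scaffold_id, []).append(
                    crispr_mod.GeneTaxonLabel(row.gene_id, row.taxid,
                                              float(row.evalue),
                                              float(row.bitscore)))
        crispr_calls = []
        for ann in annotations:
            if ann.scaffold_id not in scaffolds:
                raise KeyError(
                    f"CRISPR annotation for unknown scaffold {ann.scaffold_id}")
            crispr_calls.append(crispr_mod.classify_crispr_scaffold(
                scaffolds[ann.scaffold_id], ann, bins,
                labels_by_scaffold.get(ann.scaffold_id, ()), tree))
        report["crispr_summary"] = crispr_mod.crispr_domain_summary(
            crispr_calls)
        outputs.append(
            ("crispr_calls.tsv",
             {c.scaffold_id: c for c in crispr_calls}, "calls"))

    if config.fluids:
        samples = io_tables.read_fluids(config.fluids)
        em = fluids_mod.EndMembers(config.mg_seawater, config.mg_crustal)
        purity = {
            s.sample_id: fluids_mod.sample_purity(s, em)
            for s in samples if s.mg_low is not None
        }
        report["sample_purity_percent"] = {
            k: list(v) for k, v in purity.items() if v is not None}
        basement = [s for s in samples
                    if s.location.startswith("U1362")
                    and s.virus_conc is not None]
        if basement:
            report["abundance"] = fluids_mod.abundance_report(basement)

    # all stages succeeded: write outputs
    outdir.mkdir(parents=True, exist_ok=True)
    for filename, payload, kind in outputs:
        target = outdir / filename
        if kind == "assignments":
            io_tables.write_assignments(payload, target)
        elif kind == "calls":
            io_tables.write_host_calls(payload, target)
        elif kind == "frame":
            payload.to_csv(target, sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "evalue_threshold": config.evalue_threshold,
        "depth_mode": config.depth_mode,
        "mg_seawater": config.mg_seawater,
        "mg_crustal": config.mg_crustal,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
    return report
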