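"""Tab-separated readers/writers for the pipeline's tabular dialects.

All tables are UTF-8, tab-delimited with a header row; ``#`` lines are
comments; missing optional fields are empty strings; parsing is
locale-independent.  Unknown columns are preserved on read where the
caller works with DataFrames, and ignored by the typed readers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .crispr import CrisprAnnotation, CrisprArray
from .fluids import FluidSample
from .taxonomy import HomologyHit, TaxonomyTree
from .viral_classify import Gene, GenomeBin, ScaffoldRecord

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing or a key constraint is violated."""


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(
            f"{Path(path).name}: missing required columns {sorted(missing)}")
    return df


def _opt_float(value: str) -> float | None:
    return float(value) if value != "" else None


# -- homology hits --------------------------------------------------------

HITS_COLUMNS = ("scaffold_id", "query_gene", "subject", "subject_taxid",
                "evalue", "bitscore", "database")


def read_hits(path: str | Path) -> list[HomologyHit]:
    """Flat hit list from a BLAST-tabular-like TSV (scientific-notation
    E-values are parsed); malformed rows are counted and reported."""
    return [h for _, h in read_hits_with_scaffold(path)]


def read_hits_with_scaffold(path: str | Path) -> list[tuple[str, HomologyHit]]:
    df = _read_tsv(path, HITS_COLUMNS)
    out: list[tuple[str, HomologyHit]] = []
    bad = 0
    for row in df.itertuples(index=False):
        try:
            hit = HomologyHit(row.query_gene, row.subject, row.subject_taxid,
                              float(row.evalue), float(row.bitscore),
                              row.database)
        except (ValueError, TypeError):
            bad += 1
            continue
        out.append((row.scaffold_id, hit))
    if bad:
        logger.warning("%s: skipped %d malformed hit rows", path, bad)
    return out


def read_hits_by_scaffold(path: str | Path) -> dict[str, list[HomologyHit]]:
    tables: dict[str, list[HomologyHit]] = {}
    for sid, hit in read_hits_with_scaffold(path):
        tables.setdefault(sid, []).append(hit)
    return tables


def write_hits(tables: Mapping[str, Sequence[HomologyHit]],
               path: str | Path) -> None:
    rows = [
        {"scaffold_id": sid, "query_gene": h.query_gene, "subject": h.subject,
         "subject_taxid": h.subject_taxid, "evalue": repr(h.evalue),
         "bitscore": repr(h.bitscore), "database": h.database}
        for sid in sorted(tables) for h in tables[sid]
    ]
    pd.DataFrame(rows, columns=HITS_COLUMNS).to_csv(path, sep="\t",
                                                    index=False)


# -- scaffolds and genes --------------------------------------------------

SCAFFOLD_COLUMNS = ("scaffold_id", "sample_id", "length", "mean_depth",
                    "bin_id", "viral_category")
GENE_COLUMNS = ("scaffold_id", "gene_id", "start", "end", "strand")


def read_scaffolds(scaffold_path: str | Path,
                   gene_path: str | Path | None = None
                   ) -> dict[str, ScaffoldRecord]:
    df = _read_tsv(scaffold_path, SCAFFOLD_COLUMNS)
    if df["scaffold_id"].duplicated().any():
        dup = df.loc[df["scaffold_id"].duplicated(), "scaffold_id"].iloc[0]
        raise SchemaError(f"duplicate scaffold id {dup!r}")
    genes_by_scaffold: dict[str, list[Gene]] = {}
    if gene_path is not None:
        gdf = _read_tsv(gene_path, GENE_COLUMNS)
        for row in gdf.itertuples(index=False):
            genes_by_scaffold.setdefault(row.scaffold_id, []).append(
                Gene(row.gene_id, int(row.start), int(row.end), row.strand))
    out: dict[str, ScaffoldRecord] = {}
    for row in df.itertuples(index=False):
        category = int(row.viral_category) if row.viral_category != "" else None
        out[row.scaffold_id] = ScaffoldRecord(
            row.scaffold_id, row.sample_id, int(row.length),
            float(row.mean_depth),
            genes_by_scaffold.get(row.scaffold_id, []),
            bin_id=row.bin_id or None,
            viral_category=category,
            is_prophage=category in (4, 5, 6) if category else False,
        )
    return out


def write_scaffolds(scaffolds: Mapping[str, ScaffoldRecord],
                    scaffold_path: str | Path,
                    gene_path: str | Path | None = None) -> None:
    rows = [
        {"scaffold_id": s.scaffold_id, "sample_id": s.sample_id,
         "length": s.length, "mean_depth": repr(s.mean_depth),
         "bin_id": s.bin_id or "",
         "viral_category": s.viral_category if s.viral_category else ""}
        for s in (scaffolds[k] for k in sorted(scaffolds))
    ]
    pd.DataFrame(rows, columns=SCAFFOLD_COLUMNS).to_csv(
        scaffold_path, sep="\t", index=False)
    if gene_path is not None:
        grows = [
            {"scaffold_id": s.scaffold_id, "gene_id": g.gene_id,
             "start": g.start, "end": g.end, "strand": g.strand}
            for s in (scaffolds[k] for k in sorted(scaffolds))
            for g in s.genes
        ]
        pd.DataFrame(grows, columns=GENE_COLUMNS).to_csv(
            gene_path, sep="\t", index=False)


# -- genomic bins ---------------------------------------------------------

BIN_COLUMNS = ("bin_id", "taxid", "member_scaffolds")


def read_bins(path: str | Path, tree: TaxonomyTree) -> dict[str, GenomeBin]:
    df = _read_tsv(path, BIN_COLUMNS)
    if df["bin_id"].duplicated().any():
        raise SchemaError("duplicate bin id")
    out: dict[str, GenomeBin] = {}
    for row in df.itertuples(index=False):
        members = set(row.member_scaffolds.split(",")) \
            if row.member_scaffolds else set()
        out[row.bin_id] = GenomeBin(row.bin_id, tree.lineage_of(row.taxid),
                                    members)
    return out


def write_bins(bins: Mapping[str, GenomeBin], path: str | Path) -> None:
    rows = [
        {"bin_id": b.bin_id,
         "taxid": b.lineage[-1].taxid if b.lineage else "",
         "member_scaffolds": ",".join(sorted(b.member_scaffolds))}
        for b in (bins[k] for k in sorted(bins))
    ]
    pd.DataFrame(rows, columns=BIN_COLUMNS).to_csv(path, sep="\t", index=False)


# -- CRISPR annotations ---------------------------------------------------

CRISPR_COLUMNS = ("scaffold_id", "start", "end", "n_repeats", "detector")


def read_crispr(path: str | Path) -> list[CrisprAnnotation]:
    df = _read_tsv(path, CRISPR_COLUMNS)
    grouped: dict[tuple[str, str], list[CrisprArray]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault((row.scaffold_id, row.detector), []).append(
            CrisprArray(int(row.start), int(row.end), int(row.n_repeats)))
    return [CrisprAnnotation(sid, arrays, detector)
            for (sid, detector), arrays in grouped.items()]


def write_crispr(annotations: Iterable[CrisprAnnotation],
                 path: str | Path) -> None:
    rows = [
        {"scaffold_id": ann.scaffold_id, "start": arr.start, "end": arr.end,
         "n_repeats": arr.n_repeats, "detector": ann.detector_label}
        for ann in annotations for arr in ann.arrays
    ]
    pd.DataFrame(rows, columns=CRISPR_COLUMNS).to_csv(path, sep="\t",
                                                      index=False)


# -- fluid samples --------------------------------------------------------

FLUID_COLUMNS = ("sample_id", "analysis", "location", "collection_method",
                 "mg_mM", "virus_conc_1e4_per_ml", "cell_conc_1e4_per_ml",
                 "excluded_from_cells")


def read_fluids(path: str | Path) -> list[FluidSample]:
    """Fluid-sample table; ``mg_mM`` may be a point value or a
    ``low-high`` range as printed."""
    df = _read_tsv(path, FLUID_COLUMNS)
    if df["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample id")
    out = []
    for row in df.itertuples(index=False):
        mg_low = mg_high = None
        if row.mg_mM:
            parts = row.mg_mM.split("-")
            mg_low = float(parts[0])
            mg_high = float(parts[1]) if len(parts) > 1 else mg_low
        out.append(FluidSample(
            sample_id=row.sample_id,
            location=row.location,
            collection_method=row.collection_method,
            mg_low=mg_low, mg_high=mg_high,
            virus_conc=_opt_float(row.virus_conc_1e4_per_ml),
            cell_conc=_opt_float(row.cell_conc_1e4_per_ml),
            excluded_from_cells=row.excluded_from_cells == "1",
        ))
    return out


def write_fluids(samples: Iterable[FluidSample], path: str | Path) -> None:
    def fmt(v):
        return "" if v is None else f"{v:g}"

    rows = []
    for s in samples:
        if s.mg_low is None:
            mg = ""
        elif s.mg_high is not None and s.mg_high != s.mg_low:
            mg = f"{s.mg_low:g}-{s.mg_high:g}"
        else:
            mg = f"{s.mg_low:g}"
        rows.append({
            "sample_id": s.sample_id, "analysis": "EfM",
            "location": s.location,
            "collection_method": s.collection_method, "mg_mM": mg,
            "virus_conc_1e4_per_ml": fmt(s.virus_conc),
            "cell_conc_1e4_per_ml": fmt(s.cell_conc),
            "excluded_from_cells": int(s.excluded_from_cells),
        })
    pd.DataFrame(rows, columns=FLUID_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


# -- host calls / assignments (outputs) -----------------------------------

def write_host_calls(calls, path: str | Path) -> None:
    rows = [
        {"scaffold_id": c.scaffold_id, "method": c.method,
         "domain": c.domain, "lineage": str(c.lineage)}
        for c in (calls[k] for k in sorted(calls))
    ]
    pd.DataFrame(rows, columns=("scaffold_id", "method", "domain",
                                "lineage")).to_csv(path, sep="\t", index=False)


def write_assignments(assignments, path: str | Path) -> None:
    rows = [
        {"scaffold_id": sid, "status": a.status,
         "deepest_rank": a.deepest_rank or "",
         "lineage": str(a.lineage),
         "n_genes_with_hits": a.n_genes_with_hits,
         "n_hits_used": a.n_hits_used}
        for sid, a in sorted(assignments.items())
    ]
    pd.DataFrame(rows, columns=("scaffold_id", "status", "deepest_rank",
                                "lineage", "n_genes_with_hits",
                                "n_hits_used")).to_csv(path, sep="\t",
                                                       index=False)
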