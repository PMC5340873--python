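"""Nucleotide-sequence statistics and genome-interval arithmetic.

Coordinates are 1-based, half-open ``[start, end)`` throughout: an interval
of ``end - start`` bases.  This is the convention under which the printed
prophage coordinates (nt 116,961 -> 144,621) give exactly the printed
27,660 bp.  GenBank feature locations are 1-based inclusive; use
:func:`from_genbank_coords` to convert.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

UNAMBIGUOUS = frozenset("ACGTacgt")
IUPAC_NT = frozenset("ACGTURYSWKMBDHVNacgturyswkmbdhvn")


@dataclass(frozen=True)
class NucleotideSequence:
    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - IUPAC_NT
        if bad:
            raise ValueError(f"non-IUPAC characters in {self.id}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id,
                                  str(Seq(self.residues).reverse_complement()))


@dataclass(frozen=True)
class GenomeInterval:
    """1-based half-open interval on a scaffold; length = end - start."""

    scaffold_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def from_genbank_coords(scaffold_id: str, first: int, last: int) -> GenomeInterval:
    """Convert a 1-based inclusive (GenBank-style) span to an interval."""
    return GenomeInterval(scaffold_id, first, last + 1)


def gc_content(seq: NucleotideSequence | str) -> float:
    """G+C percentage over unambiguous A/C/G/T positions only.

    Ambiguity codes are excluded from both numerator and denominator; an
    all-ambiguous sequence has no defined G+C content.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    denom = sum(1 for c in residues if c in UNAMBIGUOUS)
    if denom == 0:
        raise ValueError("G+C content undefined: no unambiguous bases")
    gc = sum(1 for c in residues if c in "GCgc")
    return 100.0 * gc / denom


def at_content(seq: NucleotideSequence | str) -> float:
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    denom = sum(1 for c in residues if c in UNAMBIGUOUS)
    if denom == 0:
        raise ValueError("A+T content undefined: no unambiguous bases")
    at = sum(1 for c in residues if c in "ATat")
    return 100.0 * at / denom


def extract_interval(seq: NucleotideSequence,
                     interval: GenomeInterval) -> NucleotideSequence:
    """Subsequence for a 1-based half-open interval."""
    if interval.end > seq.length + 1:
        raise IndexError(
            f"interval [{interval.start},{interval.end}) out of bounds for "
            f"{seq.id} (length {seq.length})")
    sub = seq.residues[interval.start - 1:interval.end - 1]
    return NucleotideSequence(
        f"{seq.id}:{interval.start}-{interval.end}", sub)


def genome_summary(seq: NucleotideSequence,
                   gene_annotations: Iterable[dict]) -> dict:
    """Length, G+C, and ORF-annotation counts for a genome.

    ORF calling is not performed here; ``gene_annotations`` are supplied
    records with at least ``start``/``end`` (1-based half-open) and an
    optional truthy ``function`` field marking functional annotation.
    """
    annotations = list(gene_annotations)
    for ann in annotations:
        if ann["end"] > seq.length + 1:
            raise IndexError(
                f"annotation {ann.get('gene_id', '?')} beyond sequence end")
    n_annotated = sum(1 for a in annotations if a.get("function"))
    return {
        "length_nt": seq.length,
        "gc_percent": gc_content(seq),
        "n_orfs": len(annotations),
        "n_annotated": n_annotated,
    }


# -- file I/O (Biopython-backed) -----------------------------------------

def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    return [NucleotideSequence(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, s.length, width):
                fh.write(s.residues[i:i + width] + "\n")


def read_genbank(path: str | Path) -> list[NucleotideSequence]:
    return [NucleotideSequence(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "genbank")]


#: Published statistics for the two deposited genomes, used only to verify
#: a locally supplied copy of the records.
DEPOSITED_GENOMES = {
    "KY229235": {"length_nt": 55906, "gc_percent": 35.2},
    "KY229234": {
        "prophage_interval": (116961, 144621),
        "prophage_length": 27660,
        "prophage_gc_percent": 39.3,
        "remainder_gc_percent": 40.6,
    },
}


def validate_deposited_genomes(ky229235_path: str | Path | None = None,
                               ky229234_path: str | Path | None = None) -> dict:
    """Recompute the deposited genomes' published statistics from local
    copies of the GenBank/FASTA records (not bundled; supply file paths).
    """
    results: dict = {}
    if ky229235_path is not None:
        seq = _read_any(ky229235_path)[0]
        results["KY229235"] = {
            "length_nt": seq.length,
            "gc_percent": round(gc_content(seq), 1),
        }
    if ky229234_path is not None:
        seq = _read_any(ky229234_path)[0]
        start, end = DEPOSITED_GENOMES["KY229234"]["prophage_interval"]
        if seq.length >= end - 1:
            # full parent scaffold: excise the prophage at its coordinates
            prophage = extract_interval(seq, GenomeInterval(seq.id, start, end))
            remainder = seq.residues[:start - 1] + seq.residues[end - 1:]
            results["KY229234"] = {
                "prophage_length": prophage.length,
                "prophage_gc_percent": round(gc_content(prophage), 1),
                "remainder_gc_percent": round(gc_content(remainder), 1),
            }
        else:
            # record holds the excised prophage region itself
            results["KY229234"] = {
                "prophage_length": seq.length,
                "prophage_gc_percent": round(gc_content(seq), 1),
            }
    return results


def _read_any(path: str | Path) -> list[NucleotideSequence]:
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return read_genbank(path)
    return read_fasta(path)
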