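"""Fluid-sample purity and virus/cell abundance statistics.

Sample purity uses Mg2+ as a conservative tracer in a two end-member
mixing model: unaltered bottom seawater is Mg-rich (~53 mM) while reacted
crustal fluid is strongly Mg-depleted, so the crustal-fluid fraction of a
sample is the linear interpolant between the two end-member concentrations.

Virus-like-particle and cell concentrations come from epifluorescence
microscopy: stained particles are tallied over ~20 microscope view fields
on a filter of known effective area, and the per-field mean is scaled by
the field-to-filter area ratio and the filtered volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EndMembers:
    """Mg2+ end-member concentrations (mM) for the mixing model."""

    mg_seawater: float = 53.0
    mg_crustal: float = 2.0

    def __post_init__(self):
        if not (self.mg_seawater > self.mg_crustal > 0):
            raise ValueError(
                "end members must satisfy mg_seawater > mg_crustal > 0")


@dataclass
class FluidSample:
    sample_id: str
    location: str
    collection_method: str = ""
    mg_low: float | None = None   # mM; mg_low == mg_high for point values
    mg_high: float | None = None
    virus_conc: float | None = None  # units of 1e4 per ml
    cell_conc: float | None = None
    excluded_from_cells: bool = False

    def __post_init__(self):
        for v in (self.virus_conc, self.cell_conc):
            if v is not None and v < 0:
                raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class FieldCountObservation:
    """Raw per-field microscopy tallies plus filtration geometry."""

    per_field_counts: tuple
    field_area: float            # mm^2
    effective_filter_area: float  # mm^2
    volume_filtered: float       # ml
    stain_class: str = "virus"   # "virus" | "cell"

    def __post_init__(self):
        if len(self.per_field_counts) < 1:
            raise ValueError("need at least one counted field")
        if any(c < 0 for c in self.per_field_counts):
            raise ValueError("field counts must be nonnegative")
        if self.field_area <= 0 or self.effective_filter_area <= 0:
            raise ValueError("areas must be positive")
        if self.volume_filtered <= 0:
            raise ValueError("filtered volume must be positive")


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float | None  # sample SD (n-1 denominator); None for n < 2
    cv: float | None  # 100 * sd / mean
    min: float
    max: float


class DegenerateMixingModelError(ValueError):
    pass


def crustal_fraction(mg_sample: float, em: EndMembers = EndMembers()) -> float:
    """Crustal-fluid fraction of a sample from its Mg2+ concentration.

    f = (mg_seawater - mg_sample) / (mg_seawater - mg_crustal); pure
    seawater gives 0, pure crustal fluid gives 1.  Concentrations outside
    the end-member interval are clamped with a warning.
    """
    span = em.mg_seawater - em.mg_crustal
    if span == 0:
        raise DegenerateMixingModelError("identical end-member concentrations")
    if mg_sample > em.mg_seawater:
        logger.warning("Mg %.3g mM above seawater end member; clamped",
                       mg_sample)
        mg_sample = em.mg_seawater
    elif mg_sample < em.mg_crustal:
        logger.warning("Mg %.3g mM below crustal end member; clamped",
                       mg_sample)
        mg_sample = em.mg_crustal
    return (em.mg_seawater - mg_sample) / span


def crustal_percent(mg_sample: float, em: EndMembers = EndMembers()) -> int:
    """Reported purity: crustal fraction as an integer percentage."""
    return round(100.0 * crustal_fraction(mg_sample, em))


def sample_purity(sample: FluidSample,
                  em: EndMembers = EndMembers()) -> tuple[int, int] | None:
    """Purity range (%) for a sample's Mg range; None when Mg unmeasured.

    A range like 2.5-3.1 mM is evaluated at both endpoints; the higher Mg
    endpoint gives the lower crustal content.
    """
    if sample.mg_low is None:
        return None
    high = crustal_percent(sample.mg_low, em)
    low = crustal_percent(sample.mg_high if sample.mg_high is not None
                          else sample.mg_low, em)
    return (min(low, high), max(low, high))


def field_counts_to_concentration(obs: FieldCountObservation) -> float:
    """Particle concentration (per ml) from per-field microscopy tallies.

    conc = mean(counts per field) x (effective filter area / field area)
           / volume filtered.
    """
    mean_count = float(np.mean(obs.per_field_counts))
    return mean_count * (obs.effective_filter_area / obs.field_area) \
        / obs.volume_filtered


def summarize_concentrations(values: Sequence[float]) -> SummaryStats:
    """n, mean, sample SD (n-1), CV%, min, max of a concentration list."""
    if len(values) == 0:
        raise ValueError("cannot summarize an empty list")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if arr.size >= 2:
        sd = float(arr.std(ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else None
    else:
        sd = cv = None
    return SummaryStats(n=int(arr.size), mean=mean, sd=sd, cv=cv,
                        min=float(arr.min()), max=float(arr.max()))


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (reporting layer only)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class RatioSummary:
    ratios: tuple
    stats: SummaryStats


def virus_cell_ratios(samples: Sequence[FluidSample]) -> RatioSummary:
    """Per-sample virus-to-cell ratios and their summary.

    Only samples with both counts and not flagged as filtered-only
    (``excluded_from_cells``) contribute; zero cell counts are skipped
    with a warning.
    """
    ratios = []
    for s in samples:
        if s.excluded_from_cells or s.virus_conc is None or s.cell_conc is None:
            continue
        if s.cell_conc == 0:
            logger.warning("sample %s has zero cell count; ratio skipped",
                           s.sample_id)
            continue
        ratios.append(s.virus_conc / s.cell_conc)
    if not ratios:
        return RatioSummary((), SummaryStats(0, float("nan"), None, None,
                                             float("nan"), float("nan")))
    return RatioSummary(tuple(ratios), summarize_concentrations(ratios))


def abundance_report(samples: Sequence[FluidSample],
                     location_filter: str | None = None) -> dict:
    """Paper-style abundance summary for basement-fluid samples.

    Concentrations are reported to one significant figure and ratios to
    two, matching the printed convention; full precision is retained in
    the ``*_exact`` fields.
    """
    if location_filter is not None:
        samples = [s for s in samples if s.location == location_filter]
    viruses = [s.virus_conc for s in samples if s.virus_conc is not None]
    cells = [s.cell_conc for s in samples
             if s.cell_conc is not None and not s.excluded_from_cells]
    vstats = summarize_concentrations(viruses) if viruses else None
    cstats = summarize_concentrations(cells) if cells else None
    ratio = virus_cell_ratios(samples)

    report: dict = {}
    if vstats:
        report.update({
            "virus_mean_1e4_per_ml": round_sig(vstats.mean, 1),
            "virus_sd_1e4_per_ml": round_sig(vstats.sd, 1),
            "virus_cv_percent": round(vstats.cv),
            "virus_min_1e4_per_ml": round_sig(vstats.min, 1),
            "virus_max_1e4_per_ml": round_sig(vstats.max, 1),
            "virus_n": vstats.n,
            "virus_mean_exact": vstats.mean,
            "virus_sd_exact": vstats.sd,
        })
    if cstats:
        report.update({
            "cell_mean_1e4_per_ml": round_sig(cstats.mean, 1),
            "cell_sd_1e4_per_ml": round_sig(cstats.sd, 1),
            "cell_cv_percent": round(cstats.cv),
            "cell_min_1e4_per_ml": round_sig(cstats.min, 1),
            "cell_max_1e4_per_ml": round_sig(cstats.max, 1),
            "cell_n": cstats.n,
            "cell_mean_exact": cstats.mean,
            "cell_sd_exact": cstats.sd,
        })
    if ratio.stats.n:
        report.update({
            "vcr_min": round_sig(ratio.stats.min, 2),
            "vcr_max": round_sig(ratio.stats.max, 2),
            "vcr_mean": round_sig(ratio.stats.mean, 1),
            "vcr_n": ratio.stats.n,
            "vcr_mean_exact": ratio.stats.mean,
        })
    return report
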