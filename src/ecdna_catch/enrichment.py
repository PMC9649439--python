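"""Enrichment quantification for CRISPR-CATCH fractions.

After gel extraction, the isolated fraction should be dominated by reads
from the targeted amplicon; bulk WGS provides the unenriched baseline.  The
summary statistics here are the on-amplicon read fraction, the fold
enrichment of that fraction over WGS, background-normalized coverage, and a
verdict on whether the reconstructed molecule length is concordant with the
PFGE band window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph_model import GelBand

#: Default coverage bin width (bp).
DEFAULT_BIN_SIZE = 10_000

#: Fractions below this fold enrichment are reported as "not enriched"
#: (typical of compression-zone bands with no resolved species).
LOW_ENRICHMENT_FOLD = 5.0


@dataclass
class CoverageTrack:
    """Binned read counts across one or more chromosomes.

    ``bins`` has columns chrom, start, end, count (0-based half-open
    intervals).  ``total_reads`` defaults to the sum of bin counts and may
    exceed it when reads fall outside the binned region.
    """

    bins: pd.DataFrame
    total_reads: float = 0.0

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "count"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"coverage track missing columns {sorted(missing)}")
        if (self.bins["count"] < 0).any():
            raise ValueError("negative bin counts")
        if self.total_reads <= 0:
            self.total_reads = float(self.bins["count"].sum())


def read_bedgraph(path, total_reads: float = 0.0) -> CoverageTrack:
    """Read a 4-column bedGraph (chrom, start, end, value) as a coverage track.

    A ``# total_reads=N`` comment line, when present, sets the library total.
    """
    header_total = 0.0
    with open(path) as fh:
        rows = []
        for line in fh:
            if line.startswith("#"):
                if "total_reads=" in line:
                    header_total = float(line.split("total_reads=")[1].strip())
                continue
            if line.startswith(("track", "browser")) or not line.strip():
                continue
            chrom, start, end, value = line.split("\t")[:4]
            rows.append((chrom, int(start), int(end), float(value)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
    return CoverageTrack(bins=bins, total_reads=total_reads or header_total)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_reads={track.total_reads:.1f}\n")
        for row in track.bins.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.count:.1f}\n")


def _on_amplicon_mask(bins: pd.DataFrame, amplicon: Sequence[tuple[str, int, int]]) -> np.ndarray:
    mask = np.zeros(len(bins), dtype=bool)
    for chrom, start, end in amplicon:
        mask |= (
            (bins["chrom"] == chrom)
            & (bins["end"] > start)
            & (bins["start"] < end)
        ).to_numpy()
    return mask


def amplicon_read_fraction(
    track: CoverageTrack, amplicon: Sequence[tuple[str, int, int]]
) -> float:
    """Fraction of total sequencing reads falling in the amplicon intervals."""
    if not amplicon:
        raise ValueError("empty amplicon interval set")
    if track.total_reads <= 0:
        raise ValueError("track has no mapped reads")
    mask = _on_amplicon_mask(track.bins, amplicon)
    return float(track.bins.loc[mask, "count"].sum() / track.total_reads)


def fold_enrichment(frac_enriched: float, frac_wgs: float) -> float:
    """Ratio of on-amplicon read fractions, enriched over unenriched WGS.

    A zero WGS fraction yields ``inf`` (infinite-enrichment flag) rather
    than a division error.
    """
    if frac_enriched < 0 or frac_wgs < 0:
        raise ValueError("fractions must be non-negative")
    if frac_wgs == 0:
        return math.inf if frac_enriched > 0 else math.nan
    return frac_enriched / frac_wgs


def normalized_coverage(
    track: CoverageTrack,
    background: Sequence[tuple[str, int, int]] | None = None,
    amplicon: Sequence[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Per-bin depth as a multiple of the background mean.

    Background bins are either the declared ``background`` intervals or, if
    an ``amplicon`` is given instead, all bins outside it.  With neither
    declared, the whole track is the background (uniform tracks normalize to
    1x everywhere).
    """
    if track.total_reads <= 0:
        raise ValueError("track has no mapped reads")
    bins = track.bins.copy()
    widths = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    depth = bins["count"].to_numpy(dtype=float) / np.where(widths > 0, widths, 1.0)
    if background is not None:
        bg_mask = _on_amplicon_mask(bins, background)
    elif amplicon is not None:
        bg_mask = ~_on_amplicon_mask(bins, amplicon)
    else:
        bg_mask = np.ones(len(bins), dtype=bool)
    if not bg_mask.any():
        raise ValueError("no background bins")
    bg_mean = depth[bg_mask].mean()
    if bg_mean <= 0:
        raise ValueError("zero background coverage")
    bins["normalized"] = depth / bg_mean
    return bins


@dataclass
class BandConcordance:
    passed: bool
    relative_deviation: float  # |length - midpoint| / midpoint, signed toward length


def band_concordance(length_bp: float, band: GelBand) -> BandConcordance:
    """Is a reconstructed molecule length consistent with its PFGE band?"""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    length_kb = length_bp / 1000.0
    deviation = (length_kb - band.midpoint_kb) / band.midpoint_kb
    return BandConcordance(passed=band.contains_kb(length_kb), relative_deviation=deviation)


@dataclass
class EnrichmentReport:
    on_amplicon_fraction: float
    wgs_fraction: float | None = None
    fold_enrichment: float | None = None
    mean_normalized_coverage: float | None = None
    band_concordance: BandConcordance | None = None
    enriched: bool | None = None

    def to_json(self, path) -> None:
        payload = {
            "on_amplicon_fraction": self.on_amplicon_fraction,
            "wgs_fraction": self.wgs_fraction,
            "fold_enrichment": self.fold_enrichment,
            "mean_normalized_coverage": self.mean_normalized_coverage,
            "band_pass": None if self.band_concordance is None else self.band_concordance.passed,
            "band_relative_deviation": (
                None if self.band_concordance is None
                else self.band_concordance.relative_deviation
            ),
            "enriched": self.enriched,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def enrichment_report(
    enriched_track: CoverageTrack,
    wgs_track: CoverageTrack | None,
    amplicon: Sequence[tuple[str, int, int]],
    length_bp: float | None = None,
    band: GelBand | None = None,
    low_enrichment_fold: float = LOW_ENRICHMENT_FOLD,
) -> EnrichmentReport:
    """Full enrichment summary for one CRISPR-CATCH fraction."""
    frac = amplicon_read_fraction(enriched_track, amplicon)
    report = EnrichmentReport(on_amplicon_fraction=frac)
    if wgs_track is not None:
        report.wgs_fraction = amplicon_read_fraction(wgs_track, amplicon)
        report.fold_enrichment = fold_enrichment(frac, report.wgs_fraction)
        if math.isfinite(report.fold_enrichment):
            report.enriched = report.fold_enrichment >= low_enrichment_fold
        else:
            report.enriched = frac > 0
    norm = normalized_coverage(enriched_track, amplicon=amplicon)
    mask = _on_amplicon_mask(norm, amplicon)
    if mask.any():
        report.mean_normalized_coverage = float(norm.loc[mask, "normalized"].mean())
    if length_bp is not None and band is not None:
        report.band_concordance = band_concordance(length_bp, band)
    return report
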