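"""Variant phasing between ecDNA and chromosomal fractions.

Physically separating ecDNA from its native chromosomal locus lets SNVs be
assigned to one or the other by comparing variant allele frequencies (VAFs)
across fractions.  The classification used here:

* **ecDNA-specific** — VAF above 0.03 in any ecDNA fraction (isolated with
  guide A, B or A+B; the threshold sits above typical 1-2% chromosomal
  carryover) and WGS VAF below 0.997 (non-homozygous);
* **chromosome-specific** — otherwise, WGS VAF below 0.1;
* **homozygous** — otherwise, WGS VAF above 0.99;
* **unclassified** — anything left.

Variants with depth of 5 or less in the sample under classification, or not
detected in WGS at all, are filtered before classification.

Flanking non-homozygous SNVs (WGS VAF < 0.99) further resolve how many
copies of the host chromosome each haplotype accounts for: a variant private
to a haplotype present in k of N chromosome copies has expected WGS VAF
k/N, so VAF modes identify the (k, N-k) haplotype split.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ECDNA_SPECIFIC = "ecDNA-specific"
CHROM_SPECIFIC = "chromosome-specific"
HOMOZYGOUS = "homozygous"
UNCLASSIFIED = "unclassified"
FILTERED = "filtered"

CLASSES = (ECDNA_SPECIFIC, CHROM_SPECIFIC, HOMOZYGOUS, UNCLASSIFIED, FILTERED)

#: Classification thresholds.
T_ECDNA_VAF = 0.03      # min VAF in an ecDNA fraction
T_WGS_NONHOM = 0.997    # WGS VAF must be below this for ecDNA-specific
T_CHROM_WGS = 0.1       # WGS VAF below this -> chromosome-specific
T_HOM_WGS = 0.99        # WGS VAF above this -> homozygous
MIN_DEPTH = 5           # depth <= 5 is filtered


def compute_vaf(ref_count: int, alt_count: int) -> float | None:
    """alt / (ref + alt); None when the site has no covering reads."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    depth = ref_count + alt_count
    if depth == 0:
        return None
    return alt_count / depth


@dataclass
class VariantRecord:
    """One SNV/SV with per-sample allelic depths ``{sample: (ref, alt)}``."""

    chrom: str
    pos: int  # 1-based, as in variant tables
    ref: str
    alt: str
    depths: dict[str, tuple[int, int]] = field(default_factory=dict)

    def vaf(self, sample: str) -> float | None:
        ref, alt = self.depths[sample]
        return compute_vaf(ref, alt)

    def depth(self, sample: str) -> int:
        ref, alt = self.depths[sample]
        return ref + alt


@dataclass
class PhasedVariant:
    record: VariantRecord
    vafs: dict[str, float | None]
    phase_class: str = UNCLASSIFIED
    filter_reason: str | None = None


def filter_variants(
    records: Iterable[VariantRecord],
    wgs_sample: str,
    classify_samples: Sequence[str],
    min_depth: int = MIN_DEPTH,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Apply the depth and WGS-detection filters.

    A record is dropped when any sample under classification has depth at or
    below ``min_depth``, or when the variant carries no alternate reads in
    WGS.  Every removal is returned with its reason.
    """
    kept: list[VariantRecord] = []
    dropped: list[tuple[VariantRecord, str]] = []
    for rec in records:
        if wgs_sample not in rec.depths:
            dropped.append((rec, "no WGS sample"))
            continue
        low = [s for s in classify_samples
               if s not in rec.depths or rec.depth(s) <= min_depth]
        if low:
            dropped.append((rec, f"depth <= {min_depth} in {','.join(low)}"))
            continue
        if rec.depths[wgs_sample][1] == 0:
            dropped.append((rec, "not detected in WGS"))
            continue
        kept.append(rec)
    return kept, dropped


def classify_variant(
    wgs_vaf: float | None,
    ecdna_vafs: Sequence[float | None],
    t_ec: float = T_ECDNA_VAF,
    t_wgs_hi: float = T_WGS_NONHOM,
    t_chr: float = T_CHROM_WGS,
    t_hom: float = T_HOM_WGS,
    mode: str = "any",
) -> str:
    """Assign one phase class from the fraction VAFs.

    ``mode='any'`` (default) calls a variant ecDNA-supported when any ecDNA
    fraction exceeds ``t_ec``; ``mode='all'`` requires every fraction with a
    defined VAF to exceed it.
    """
    if not ecdna_vafs:
        raise ValueError("at least one ecDNA fraction VAF is required")
    defined = [v for v in ecdna_vafs if v is not None]
    if mode == "any":
        ec_hit = any(v > t_ec for v in defined)
    elif mode == "all":
        ec_hit = bool(defined) and all(v > t_ec for v in defined)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    wgs = wgs_vaf if wgs_vaf is not None else 0.0
    if ec_hit and wgs < t_wgs_hi:
        return ECDNA_SPECIFIC
    if wgs < t_chr:
        return CHROM_SPECIFIC
    if wgs > t_hom:
        return HOMOZYGOUS
    return UNCLASSIFIED


def phase_variants(
    records: Iterable[VariantRecord],
    wgs_sample: str,
    ecdna_samples: Sequence[str],
    min_depth: int = MIN_DEPTH,
    mode: str = "any",
    **thresholds,
) -> list[PhasedVariant]:
    """Filter and classify a variant set; filtered records keep their reason."""
    records = list(records)
    kept, dropped = filter_variants(records, wgs_sample, list(ecdna_samples), min_depth)
    dropped_map = {id(rec): reason for rec, reason in dropped}
    out = []
    for rec in records:
        vafs = {s: rec.vaf(s) for s in rec.depths}
        if id(rec) in dropped_map:
            out.append(PhasedVariant(rec, vafs, FILTERED, dropped_map[id(rec)]))
            continue
        cls = classify_variant(
            vafs.get(wgs_sample),
            [vafs.get(s) for s in ecdna_samples if s in vafs],
            mode=mode,
            **thresholds,
        )
        out.append(PhasedVariant(rec, vafs, cls))
    return out


def class_counts(phased: Iterable[PhasedVariant]) -> Counter:
    return Counter(p.phase_class for p in phased)


# ---------------------------------------------------------------------------
# Haplotype copy counts from flanking VAF modes
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeCopyEstimate:
    total_copies: int
    modes: dict[int, float]          # copy count k -> supporting fraction of variants
    dominant_pair: tuple[int, int]   # (k, total - k)
    n_variants: int


def estimate_haplotype_copies(
    flank_vafs: Sequence[float],
    total_copies: int,
    support_threshold: float = 0.2,
    hom_cutoff: float = 0.99,
) -> HaplotypeCopyEstimate:
    """Infer the haplotype copy split from flanking heterozygous VAFs.

    Each non-homozygous variant (VAF < ``hom_cutoff``) votes for the copy
    count ``k = round(VAF * total_copies)``.  Copy counts supported by at
    least ``support_threshold`` of the votes are reported as modes; the
    dominant mode k (most votes, smaller k on ties) pairs with its
    complement ``total_copies - k``.
    """
    if total_copies < 2:
        raise ValueError("total_copies must be at least 2")
    informative = [v for v in flank_vafs if v is not None and 0 < v < hom_cutoff]
    if not informative:
        raise ValueError("no informative (non-homozygous) flank variants")
    votes = Counter(int(round(v * total_copies)) for v in informative)
    n = len(informative)
    modes = {k: c / n for k, c in votes.items() if c / n >= support_threshold}
    source = modes if modes else {k: c / n for k, c in votes.items()}
    dominant_k = min(source, key=lambda k: (-source[k], k))
    pair = tuple(sorted((dominant_k, total_copies - dominant_k)))
    return HaplotypeCopyEstimate(
        total_copies=total_copies,
        modes=dict(sorted(modes.items())),
        dominant_pair=pair,  # type: ignore[arg-type]
        n_variants=n,
    )


# ---------------------------------------------------------------------------
# Table I/O (variant-caller table-export convention)
# ---------------------------------------------------------------------------

def read_variant_table(path) -> list[VariantRecord]:
    """Read a TSV with CHROM, POS, REF, ALT and per-sample ``<sample>.AD`` columns.

    AD cells hold "ref,alt" allelic depths, the table-export convention of
    common somatic variant callers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    ad_cols = [c for c in df.columns if c.endswith(".AD")]
    if not ad_cols:
        raise ValueError(f"{path}: no <sample>.AD columns found")
    records = []
    for _, row in df.iterrows():
        depths = {}
        for col in ad_cols:
            sample = col[: -len(".AD")]
            ref_c, alt_c = str(row[col]).split(",")
            depths[sample] = (int(ref_c), int(alt_c))
        records.append(
            VariantRecord(chrom=str(row["CHROM"]), pos=int(row["POS"]),
                          ref=str(row["REF"]), alt=str(row["ALT"]), depths=depths)
        )
    return records


def write_phased_table(phased: Sequence[PhasedVariant], path) -> None:
    """Write the input table augmented with per-sample VAF and class columns."""
    samples = sorted({s for p in phased for s in p.record.depths})
    rows = []
    for p in phased:
        row = {
            "CHROM": p.record.chrom, "POS": p.record.pos,
            "REF": p.record.ref, "ALT": p.record.alt,
        }
        for s in samples:
            if s in p.record.depths:
                ref_c, alt_c = p.record.depths[s]
                row[f"{s}.AD"] = f"{ref_c},{alt_c}"
                vaf = p.vafs.get(s)
                row[f"{s}.VAF"] = "" if vaf is None else f"{vaf:.6f}"
        row["CLASS"] = p.phase_class
        row["FILTER_REASON"] = p.filter_reason or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
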