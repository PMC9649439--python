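"""Ground-truthed synthetic inputs for the CRISPR-CATCH analysis stack.

Generates, with a known truth record, every input the other modules
consume: a circular amplicon structure with its breakpoint graph, gel band
and cut sites; enriched/WGS coverage tracks; a haplotype-structured variant
table; and per-read CpG methylation calls with an ATAC peak table.

Default parameters emulate the GBM39-like study conditions: a megabase-scale
circle at ~90 copies per cell against a diploid background, six copies of
the host chromosome split 1:5 between the parental haplotypes (the single
allele-1 copy bearing the excision scar), 30-fold read enrichment of the
targeted locus (2% of WGS reads on the amplicon rising to 60% after
enrichment), ~200x sequencing depth for variant calls, 1-2% cross-fraction
carryover, and promoter CpG hypomethylation of 0.4 on ecDNA.  Noise models
are the simplest ones matching the statistics the pipeline assumes: Poisson
bin counts, binomial allelic depths, beta-perturbed per-site methylation
frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .camper import AmpliconPath, Step
from .enrichment import CoverageTrack, write_bedgraph
from .graph_model import (
    HEAD,
    TAIL,
    BreakpointEdge,
    BreakpointGraph,
    CutSite,
    GelBand,
    GenomeSegment,
    write_graph_file,
)
from .phasing import VariantRecord

ECDNA_SAMPLES = ("ecA", "ecB", "ecAB")
CHROM_SAMPLE = "chromFraction"
WGS_SAMPLE = "WGS"


@dataclass
class SimConfig:
    """All tunable study conditions; rates in [0, 1], lengths in bp."""

    seed: int = 0
    # structure
    # 3-10 segments of 50-180 kb keep whole circles inside the PFGE
    # resolution window (< 2.2 Mb); larger circles co-migrate in the
    # compression zone and are not size-resolvable
    n_segments: tuple[int, int] = (3, 10)
    segment_length: tuple[int, int] = (50_000, 180_000)
    trans_chrom_prob: float = 0.1
    circle_cn: float = 90.0
    background_cn: float = 2.0
    cn_noise_sd: float = 0.5
    band_error: float = 0.10
    # coverage
    wgs_amplicon_fraction: float = 0.02
    enrichment_factor: float = 30.0
    total_reads: int = 1_000_000
    bin_size: int = 10_000
    n_background_bins: int = 200
    # variants
    chrom_copies: int = 6
    haplotype_split: tuple[int, int] = (1, 5)  # (ecDNA-origin allele, other allele)
    depth_mean: float = 200.0
    carryover: float = 0.01          # chromosomal DNA in the ecDNA fraction
    chrom_fraction_purity: float = 0.75
    n_ecdna_clonal: int = 30
    n_ecdna_subclonal: int = 20
    subclonal_vaf: tuple[float, float] = (0.06, 0.30)
    n_chrom_specific: int = 30
    n_homozygous: int = 20
    n_flank_variants: int = 40
    # methylation
    baseline_methylation: float = 0.75
    methylation_concentration: float = 50.0
    hypomethylation_effect: float = 0.4
    n_peaks: int = 10
    peak_width: int = 500
    cpg_per_peak: int = 10
    n_hypo_peaks: int = 1
    reads_per_fraction: int = 60
    ambiguous_rate: float = 0.05
    low_coverage_peak_every: int = 0  # every k-th peak emitted below the score filter

    def __post_init__(self) -> None:
        for name in ("trans_chrom_prob", "band_error", "carryover",
                     "ambiguous_rate", "baseline_methylation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.segment_length[0] <= 0:
            raise ValueError("segment lengths must be positive")


@dataclass
class TruthRecord:
    """Planted ground truth, internally consistent with the emitted files."""

    steps: tuple[Step, ...]
    length_bp: int
    band: GelBand
    cut_sites: list[CutSite] = field(default_factory=list)
    variant_classes: dict[str, str] = field(default_factory=dict)   # "chrom:pos" -> class
    flank_copy_split: tuple[int, int] = (0, 0)
    hypo_peaks: list[tuple[str, int, int]] = field(default_factory=list)
    methylation_effect: float = 0.0

    @property
    def path(self) -> AmpliconPath:
        return AmpliconPath(steps=self.steps, circular=True)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["band"] = {"size_min_kb": self.band.size_min_kb,
                           "size_max_kb": self.band.size_max_kb,
                           "label": self.band.label}
        payload["cut_sites"] = [
            {"chrom": c.chrom, "position": c.position, "guide": c.guide}
            for c in self.cut_sites
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class StructureSim:
    graph: BreakpointGraph
    band: GelBand
    cuts: list[CutSite]
    truth: TruthRecord


# ---------------------------------------------------------------------------
# Circular structure
# ---------------------------------------------------------------------------

def simulate_structure(config: SimConfig, rng: np.random.Generator | None = None) -> StructureSim:
    """Sample an oriented segment cycle and its breakpoint graph.

    Segment copy numbers are background + circle CN x multiplicity plus
    Gaussian noise; the gel band is the true length +/- the configured band
    error; one cut site falls inside a cycle segment.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.n_segments
    n = int(rng.integers(lo, hi + 1))
    primary, secondary = "chr7", "chr11"

    segments: list[GenomeSegment] = []
    offsets = {primary: 10_000_000, secondary: 10_000_000}
    for i in range(1, n + 1):
        # the first segment anchors the primary locus; later ones may be trans
        chrom = secondary if (i > 1 and rng.random() < config.trans_chrom_prob) else primary
        length = int(rng.integers(config.segment_length[0], config.segment_length[1] + 1))
        gap = int(rng.integers(10_000, 100_000))
        start = offsets[chrom] + gap
        end = start + length
        offsets[chrom] = end
        noise = rng.normal(0.0, config.cn_noise_sd)
        cn = max(0.0, config.background_cn + config.circle_cn + noise)
        segments.append(GenomeSegment(id=i, chrom=chrom, start=start, end=end, cn=cn))

    order = rng.permutation(n)
    orients = rng.choice(["+", "-"], size=n)
    steps: tuple[Step, ...] = tuple(
        (int(segments[k].id), str(orients[j])) for j, k in enumerate(order)
    )

    edges = []
    for j in range(len(steps)):
        sid_a, o_a = steps[j]
        sid_b, o_b = steps[(j + 1) % len(steps)]
        exit_end = (sid_a, TAIL if o_a == "+" else HEAD)
        entry_end = (sid_b, HEAD if o_b == "+" else TAIL)
        seg_a, seg_b = segments[sid_a - 1], segments[sid_b - 1]
        adjacent = (
            seg_a.chrom == seg_b.chrom
            and ((exit_end[1] == TAIL and entry_end[1] == HEAD and seg_a.end == seg_b.start)
                 or (exit_end[1] == HEAD and entry_end[1] == TAIL and seg_b.end == seg_a.start))
        )
        kind = "concordant" if adjacent else "discordant"
        support = int(rng.integers(20, 200))
        edges.append(BreakpointEdge(left=exit_end, right=entry_end, support=support, kind=kind))

    graph = BreakpointGraph(segments=segments, edges=edges, source="synthetic")
    length_bp = sum(segments[sid - 1].length for sid, _o in steps)
    length_kb = length_bp / 1000.0
    band = GelBand(
        size_min_kb=length_kb * (1.0 - config.band_error),
        size_max_kb=length_kb * (1.0 + config.band_error),
        label="sim",
    )
    cut_seg = segments[steps[int(rng.integers(len(steps)))][0] - 1]
    cut = CutSite(chrom=cut_seg.chrom,
                  position=int((cut_seg.start + cut_seg.end) // 2), guide="A")
    truth = TruthRecord(steps=steps, length_bp=length_bp, band=band, cut_sites=[cut])
    return StructureSim(graph=graph, band=band, cuts=[cut], truth=truth)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def simulate_coverage(
    sim: StructureSim, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[CoverageTrack, CoverageTrack]:
    """Poisson bin counts for the enriched fraction and unenriched WGS.

    The planted WGS on-amplicon read fraction and the enrichment factor fix
    the two expected fractions (enriched = factor x WGS, capped at 0.95);
    reads are spread over amplicon bins proportionally to bin width and over
    a synthetic background chromosome otherwise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    bins: list[tuple[str, int, int]] = []
    for seg in sim.graph.segments:
        for b_start in range(seg.start, seg.end, config.bin_size):
            bins.append((seg.chrom, b_start, min(b_start + config.bin_size, seg.end)))
    n_amp = len(bins)
    bg_width = config.bin_size
    for k in range(config.n_background_bins):
        bins.append(("chrBg", k * bg_width, (k + 1) * bg_width))

    widths = np.array([e - s for _c, s, e in bins], dtype=float)
    amp_mask = np.arange(len(bins)) < n_amp

    def track(frac_on: float) -> CoverageTrack:
        rates = np.empty(len(bins))
        rates[amp_mask] = frac_on * config.total_reads * widths[amp_mask] / widths[amp_mask].sum()
        rates[~amp_mask] = (1 - frac_on) * config.total_reads * widths[~amp_mask] / widths[~amp_mask].sum()
        counts = rng.poisson(rates).astype(float)
        df = pd.DataFrame(bins, columns=["chrom", "start", "end"])
        df["count"] = counts
        return CoverageTrack(bins=df)

    p_wgs = config.wgs_amplicon_fraction
    p_enr = min(config.enrichment_factor * p_wgs, 0.95)
    return track(p_enr), track(p_wgs)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _binomial_record(rng, chrom, pos, vafs: dict[str, float], depth_mean: float) -> VariantRecord:
    depths = {}
    for sample, vaf in vafs.items():
        d = max(1, int(rng.poisson(depth_mean)))
        alt = int(rng.binomial(d, min(max(vaf, 0.0), 1.0)))
        depths[sample] = (d - alt, alt)
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="T", depths=depths)


def simulate_variants(
    sim: StructureSim, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[VariantRecord], TruthRecord]:
    """Emit SNVs with allelic depths consistent with the planted classes.

    Expected VAFs follow the copy-number mixture: at an amplicon site the
    cell carries ``circle_cn`` ecDNA copies plus the non-excised chromosomal
    haplotype copies; fraction purities (carryover into the ecDNA fraction,
    chromosomal-fraction purity) set the fraction-level VAFs.  Flanking
    heterozygous variants are placed outside the amplicon at VAF k/N for the
    planted haplotype split (k, N - k).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    truth = sim.truth
    seg0 = sim.graph.segments[0]
    chrom = seg0.chrom
    E = config.circle_cn
    k1, k2 = config.haplotype_split          # allele 1 (ecDNA origin), allele 2
    n_chrom_at_amp = k2                       # allele-1 copy lost the region (excision)
    wgs_total = E + n_chrom_at_amp
    c = config.carryover
    purity_chr = config.chrom_fraction_purity

    records: list[VariantRecord] = []
    pos_iter = iter(range(seg0.start + 100, seg0.end, 137))

    def add(pos: int, cls: str, vaf_ec_mol: float, vaf_chrom_mol: float, vaf_wgs: float):
        vafs = {WGS_SAMPLE: vaf_wgs, CHROM_SAMPLE: purity_chr * vaf_chrom_mol + (1 - purity_chr) * vaf_ec_mol}
        for s in ECDNA_SAMPLES:
            vafs[s] = (1 - c) * vaf_ec_mol + c * vaf_chrom_mol
        rec = _binomial_record(rng, chrom, pos + 1, vafs, config.depth_mean)
        records.append(rec)
        truth.variant_classes[f"{chrom}:{pos + 1}"] = cls

    for _ in range(config.n_ecdna_clonal):
        add(next(pos_iter), "ecDNA-specific", 1.0, 0.0, E / wgs_total)
    for _ in range(config.n_ecdna_subclonal):
        f = float(rng.uniform(*config.subclonal_vaf))
        add(next(pos_iter), "ecDNA-specific", f, 0.0, E * f / wgs_total)
    for _ in range(config.n_chrom_specific):
        add(next(pos_iter), "chromosome-specific", 0.0, 1.0, n_chrom_at_amp / wgs_total)
    for _ in range(config.n_homozygous):
        add(next(pos_iter), "homozygous", 1.0, 1.0, 1.0)

    # flanking heterozygous variants, outside the amplicon
    N = config.chrom_copies
    flank_start = seg0.start - 5_000_000
    for i in range(config.n_flank_variants):
        hap = k1 if i % 2 == 0 else k2
        vaf = hap / N
        pos = flank_start + i * 997
        rec = _binomial_record(rng, chrom, pos + 1, {WGS_SAMPLE: vaf}, config.depth_mean)
        records.append(rec)
        truth.variant_classes[f"{chrom}:{pos + 1}"] = f"flank:{hap}"
    truth.flank_copy_split = (min(k1, k2), max(k1, k2))
    return records, truth


def write_variant_table(records: list[VariantRecord], path) -> None:
    samples = sorted({s for r in records for s in r.depths})
    rows = []
    for r in records:
        row = {"CHROM": r.chrom, "POS": r.pos, "REF": r.ref, "ALT": r.alt}
        for s in samples:
            if s in r.depths:
                row[f"{s}.AD"] = f"{r.depths[s][0]},{r.depths[s][1]}"
            else:
                row[f"{s}.AD"] = "0,0"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    sim: StructureSim, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Per-read CpG calls for both fractions plus an ATAC peak table.

    CpG dyads sit inside consecutive peak regions; per-site frequencies are
    beta-perturbed around the baseline, and the designated hypomethylated
    (promoter-like) peaks have the ecDNA frequency reduced by the configured
    effect.  Reads split ~50/50 between strands with the +/- 1-bp dyad
    offset; emitted probabilities are categorizable at the 0.7 cutoff except
    for the configured ambiguous fraction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    truth = sim.truth
    seg0 = sim.graph.segments[0]
    chrom = seg0.chrom
    region_start = seg0.start

    peak_rows = []
    cpg_sites = []          # harmonized ('-' strand) coordinates
    site_peak = []          # peak index per site, -1 outside
    spacing = max(2_000, config.peak_width * 2)
    for p in range(config.n_peaks):
        start = region_start + p * spacing
        end = start + config.peak_width
        if config.low_coverage_peak_every and (p + 1) % config.low_coverage_peak_every == 0:
            norm_cov = 0.5 * config.peak_width   # score ~8, below the filter
        else:
            norm_cov = 3.0 * config.peak_width   # score ~10.6, passes the filter
        peak_rows.append((chrom, start, end, norm_cov))
        gap = max(2, config.peak_width // (config.cpg_per_peak + 1))
        for j in range(config.cpg_per_peak):
            cpg_sites.append(start + (j + 1) * gap)
            site_peak.append(p)
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "norm_coverage"])

    sites = np.array(cpg_sites)
    site_peak = np.array(site_peak)
    a = config.baseline_methylation * config.methylation_concentration
    b = (1 - config.baseline_methylation) * config.methylation_concentration
    base_freq = rng.beta(a, b, size=len(sites))

    hypo = np.zeros(len(sites), dtype=bool)
    hypo_peaks: list[tuple[str, int, int]] = []
    for p in range(min(config.n_hypo_peaks, config.n_peaks)):
        hypo |= site_peak == p
        hypo_peaks.append((chrom, peak_rows[p][1], peak_rows[p][2]))
    ec_freq = np.clip(base_freq - np.where(hypo, config.hypomethylation_effect, 0.0), 0.02, 0.98)
    chr_freq = np.clip(base_freq, 0.02, 0.98)

    def emit(freqs: np.ndarray, prefix: str) -> pd.DataFrame:
        n_reads = config.reads_per_fraction
        meth = rng.random((n_reads, len(sites))) < freqs[None, :]
        amb = rng.random((n_reads, len(sites))) < config.ambiguous_rate
        p_meth = np.where(meth, rng.uniform(0.75, 0.99, meth.shape),
                          rng.uniform(0.01, 0.25, meth.shape))
        p_meth = np.where(amb, rng.uniform(0.35, 0.65, meth.shape), p_meth)
        plus = rng.random(n_reads) < 0.5
        read_ids = np.array([f"{prefix}_read{r}" for r in range(n_reads)])
        rows = {
            "read_id": np.repeat(read_ids, len(sites)),
            "chrom": chrom,
            "strand": np.repeat(np.where(plus, "+", "-"), len(sites)),
            "pos": np.where(np.repeat(plus, len(sites)),
                            np.tile(sites - 1, n_reads), np.tile(sites, n_reads)),
            "p_meth": np.round(p_meth.ravel(), 4),
        }
        return pd.DataFrame(rows)

    ec_calls = emit(ec_freq, "ec")
    chr_calls = emit(chr_freq, "chr")
    truth.hypo_peaks = hypo_peaks
    truth.methylation_effect = config.hypomethylation_effect
    return ec_calls, chr_calls, peaks, truth


# ---------------------------------------------------------------------------
# File emission (round-trip contract with the readers)
# ---------------------------------------------------------------------------

def simulate_all(config: SimConfig, out_dir) -> dict[str, str]:
    """Run every generator under one seed and write all files to ``out_dir``.

    Returns a manifest of file paths.  Identical seed and config give
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sim = simulate_structure(config, rng)
    enriched, wgs = simulate_coverage(sim, config, rng)
    variants, truth = simulate_variants(sim, config, rng)
    ec_calls, chr_calls, peaks, truth = simulate_methylation(sim, config, rng)

    manifest = {
        "graph": str(out / "graph.txt"),
        "band": str(out / "band.json"),
        "cuts": str(out / "cuts.bed"),
        "coverage_enriched": str(out / "enriched.bedgraph"),
        "coverage_wgs": str(out / "wgs.bedgraph"),
        "variants": str(out / "variants.tsv"),
        "methylation_ecdna": str(out / "methylation_ec.tsv"),
        "methylation_chromosomal": str(out / "methylation_chr.tsv"),
        "peaks": str(out / "peaks.tsv"),
        "truth": str(out / "truth.json"),
    }
    write_graph_file(sim.graph, manifest["graph"])
    with open(manifest["band"], "w") as fh:
        json.dump({"size_min_kb": sim.band.size_min_kb,
                   "size_max_kb": sim.band.size_max_kb, "label": sim.band.label}, fh)
    with open(manifest["cuts"], "w") as fh:
        for cut in sim.cuts:
            fh.write(f"{cut.chrom}\t{cut.position}\t{cut.position + 1}\t{cut.guide}\n")
    write_bedgraph(enriched, manifest["coverage_enriched"])
    write_bedgraph(wgs, manifest["coverage_wgs"])
    write_variant_table(variants, manifest["variants"])
    ec_calls.to_csv(manifest["methylation_ecdna"], sep="\t", index=False)
    chr_calls.to_csv(manifest["methylation_chromosomal"], sep="\t", index=False)
    peaks.to_csv(manifest["peaks"], sep="\t", index=False)
    truth.to_json(manifest["truth"])
    return manifest
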