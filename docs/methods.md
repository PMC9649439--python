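# Methods

This note documents the models, parameter choices and numerical conventions
behind `ecdna-catch`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Background and scope

Extrachromosomal DNA (ecDNA) carries amplified oncogenes on megabase-scale
circles. CRISPR-CATCH isolates them physically: an in vitro Cas9 cut
linearizes the circle, pulsed-field gel electrophoresis (PFGE) separates the
linearized molecules by size, and the excised gel band is sequenced. The
computational problem this package addresses starts *after* alignment and
copy-number/breakpoint calling: given a copy-number-aware breakpoint graph
for an isolated band, the band's molecule-size window, and the cut sites
used, reconstruct the circular structure; and given reads from the separated
ecDNA and chromosomal fractions, quantify enrichment, phase variants between
fractions, and compare CpG methylation. Variant calling, alignment,
basecalling and peak calling are upstream tools' work; their text outputs
are this package's inputs.

## Breakpoint graphs and coordinates

Internally all intervals are 0-based half-open. The graph-file dialect
stores 1-based *boundary* positions: a `sequence` record `chrom:S- chrom:E+`
covers internal `[S-1, E-1)`, so its length is `E − S`, and parsing/writing
are exact inverses. Segment ends are named `head` (low coordinate) and
`tail` (high coordinate); a `+` traversal enters at the head and exits at
the tail. Breakpoint records `chrom:pos+` attach to the tail of the segment
ending at `pos`, `chrom:pos-` to the head of the segment starting there.
Concordant (reference-adjacent) and discordant (rearrangement) edges are
both traversable; a tail→head self-edge on a single segment is a simple
circularization.

## Segment multiplicity

A segment occurring *m* times per circle contributes *m* per-circle units of
copy number above background. The per-copy unit *u* is estimated as the
minimum CN among amplified segments (CN > 2× background) minus the
background, on the assumption that the least-amplified segment occurs once
per circle; `unit_cn` can override this when co-migrating species make the
assumption wrong. Multiplicity is `max(0, round((cn − background)/u))`;
`background_cn` defaults to 2 (human diploid). The estimate is invariant
under rescaling all CNs and the background together.

## Cycle enumeration (CAMPER)

The enumerator performs a depth-first search over oriented segment ends.
State is (current oriented segment, remaining per-segment multiplicity,
accumulated length); branches are pruned when the accumulated length
exceeds the band's upper bound, and a walk is recorded when an edge returns
to the starting oriented segment with length at or above the lower bound.
Each cycle is discovered from its minimum-id segment in `+` orientation,
and all results are deduplicated by a canonical form that is invariant
under rotation and traversal reversal (reversal flips every orientation);
the canonical form is the lexicographic minimum over all such
representations. Search limits (`max_candidates`, `max_steps`) never fail
silently: exceeding them sets a `truncated` flag on the result set.

Cut-site constraints mirror the linearization chemistry: a single-guide
experiment must cut the circle exactly once, so the segment containing the
cut must be traversed exactly once; multi-guide experiments relax this to
"at least one cut-bearing segment traversed". Cuts that fall outside every
segment are flagged off-amplicon and reported, not fatal.

Bands whose upper bound reaches 2200 kb overlap the PFGE compression zone,
where molecule sizes are unresolved; such bands are flagged
`compression_zone` and skipped rather than enumerated against a
meaningless window.

### Candidate scores

The published pipeline filters low-confidence reconstructions on quality
estimates whose exact formula is not public; the scores here implement the
same intent and are pinned as follows:

* `length_score = clip(1 − |L − band midpoint| / band halfwidth, 0, 1)` —
  1 at the band center, 0 at the band edge;
* `edge_utilization` = traversed discordant edges / all discordant edges in
  the graph (1.0 for a graph with none);
* `cn_residual` = RMS over positive-multiplicity segments of
  `(cn − background − u·usage)/u`, i.e. leftover copy number in per-copy
  units;
* `composite` = mean of `length_score`, `edge_utilization` and
  `1/(1 + cn_residual)`.

Candidates are ranked by composite score, ties broken lexicographically on
the canonical form (so output order is deterministic). `pass_filter`
requires `edge_utilization ≥ 0.8` (configurable) and `length_score > 0`.

## Enrichment

The on-amplicon read fraction is reads in amplicon bins divided by total
mapped reads; fold enrichment is the ratio of that fraction between the
enriched fraction and WGS (a zero WGS fraction yields an infinite-enrichment
flag rather than an error). Normalized coverage divides per-bin depth by
the mean depth of declared background bins (by default, all non-amplicon
bins), so a 200-copy amplicon over a diploid background reads ~200×. The
exact normalizer behind published "normalized coverage" figures is not
stated; background-mean scaling is this package's documented choice.
Default bin size is 10 kb. Fractions with fold enrichment below 5 are
flagged "not enriched" (typical of compression-zone bands).

## Variant phasing

VAF = alt/(ref+alt), undefined at zero depth. Variants are filtered when
depth ≤ 5 in any sample under classification or when WGS shows no alternate
reads. Classification applies, in order: ecDNA-specific if any ecDNA
fraction VAF > 0.03 (above the 1–2% chromosomal carryover seen in enriched
fractions) and WGS VAF < 0.997; otherwise chromosome-specific if WGS
VAF < 0.1; otherwise homozygous if WGS VAF > 0.99; otherwise unclassified.
The "any fraction" reading of the multi-guide rule is the default; an
`all` mode is available because the published wording is ambiguous on this
point. Classes partition the kept variants exactly.

Haplotype copy counts come from flanking heterozygous variants (WGS
VAF < 0.99, default flank 20 Mb in pipeline use): each votes for
`k = round(VAF × total copies)`; copy counts supported by ≥ 20% of votes
are modes, and the dominant mode pairs with its complement. Six chromosome
copies split 1:5 place VAF modes near 1/6 and 5/6.

## Methylation

Per-read CpG calls are harmonized by shifting `+`-strand positions +1 bp
onto the `-`-strand C of the dyad. Calls are methylated when
p > 0.7, unmethylated when 1 − p > 0.7, ambiguous otherwise; ambiguous
calls never enter coverage. Per-site frequency uses these categorized
counts (not a 0.5 split), consistently with the co-occurrence definition.

Locus-wide relative methylation: per-fraction site frequencies are averaged
(unweighted) in 100-bp windows sliding every 10 bp; paired window means are
regressed (ecDNA as response, chromosomal as predictor) and internally
studentized residuals — `residual / (s·sqrt(1 − leverage))`, R's
`rstandard` — express each window's relative methylation. A numerically
perfect fit has no residual scale, so residuals are reported as exact
zeros when the residual sum of squares vanishes; fewer than 3 paired
windows or a constant predictor raise a degenerate-regression error.

Per-peak testing: ATAC peaks are kept when
`log2(normcov/width × 500 + 1) > 9` (the "+1, scale to 500, log2" reading
of the filter; the published wording is ambiguous and this formula is
pinned). CpG sites with coverage > 5 in both fractions and inside kept
peaks are regressed per-site; for each peak, `z = (x − m)/s.e.` with `x`
the mean site residual inside the peak, `m` the mean and `s` the standard
deviation over all qualifying sites, `s.e. = s/sqrt(n_peak)`. Two-sided
normal p-values are Benjamini–Hochberg adjusted across peaks (peaks, not
sites, form the family) and called significant below adjusted p < 0.005.
Peaks with no qualifying CpG are omitted from the output.

Co-occurrence: for each pair of sites, the probability that both are
methylated (resp. both unmethylated) among reads where *both* are
categorizable — the both-sites-on-the-same-read reading of the
denominator. Matrices are symmetric, entries with empty denominators are
NaN, and diagonal entries give the within-site methylated/unmethylated
concordance (summing to 1 where covered). Loess smoothing of methylation
for display is out of scope here.

## Synthetic data: what it emulates

The generator's defaults are the study conditions of a GBM39-like sample:

| parameter | default | rationale |
|---|---|---|
| segments per circle | 3–10 | heterogeneous multi-segment amplicons |
| segment length | 50–180 kb | circles stay inside the PFGE resolution window (< 2.2 Mb), like the gel-resolvable 278 kb–1.6 Mb species |
| circle copy number | 90 | high-copy oncogene amplification implied by a ~2% WGS read share over ~1.26 Mb |
| background CN | 2 | diploid |
| chromosome copies | 6, split 1:5 | host chromosome gain; one allele-1 copy carries the excision scar |
| band window | truth ± 10% | gel sizing error |
| WGS amplicon fraction / enrichment | 2% / 30× | enriched fraction = 30 × 2% = 60% of reads |
| variant depth | ~200× | ultrahigh coverage of enriched fractions |
| carryover into ecDNA fraction | 1% | observed 1–2% chromosomal contamination, lower bound |
| chromosomal-fraction purity | 75% | observed ~70–75% chromosomal VAFs |
| baseline methylation / promoter effect | 0.75 / −0.4 | bulk CpG methylation with strong promoter hypomethylation on ecDNA |

Noise models are Poisson bin counts, binomial allelic depths and
beta-perturbed per-site methylation frequencies — the simplest models
matching the statistics the pipeline assumes. Reference coordinates are
synthetic chromosomes; no genome is downloaded.

What the simulations do *not* emulate: mapping artifacts and repeat-driven
coverage bias, gel bands containing co-migrating distinct species,
missing/false breakpoint edges from low-complexity junctions, sequencing
error in allele counts beyond binomial sampling, methylation caller bias,
and reads that span only part of a locus. Passing tests therefore
demonstrate correctness of the algorithms under their stated statistical
assumptions, not robustness to every real-data failure mode; on real data,
missing edges in particular leave bands unresolvable (reported by the
graph validator as unbalanced ends) rather than silently wrong.

## Problem sizes used in tests and the acceptance script

Oracle cross-checks run 200 random graphs with ≤ 6 segments and
multiplicity ≤ 2 against exhaustive closed-walk enumeration; structure
recovery runs 100 simulated amplicons; phasing metrics aggregate 5
simulations (~100 amplicon variants and 40 flank variants each); the
differential-methylation null uses one 200-peak simulation and power uses
five 20-peak simulations with one planted hypomethylated peak of 20 CpGs.
These sizes give stable statistics while keeping the whole suite and the
acceptance script each under a few seconds on one CPU.

## Known limitations

* Multiplicity estimation assumes one species per band; co-migrating
  circles of similar size violate the unit-CN assumption (the `unit_cn`
  override is the escape hatch).
* Composite score weights are equal by choice; no training data exists
  within this package to fit them.
* The enumerator is exhaustive within its limits; graphs with many
  high-multiplicity segments can hit `max_candidates`/`max_steps` and
  return a truncated (flagged) set.
* Haplotype copy estimation assumes exactly two haplotypes and an
  integer total copy number supplied by the caller.
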