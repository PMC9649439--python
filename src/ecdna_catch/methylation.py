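"""Per-read CpG methylation analytics for isolated ecDNA vs chromosomal DNA.

Nanopore modified-base callers emit a methylation probability per read per
CpG.  Calls on the two strands of a CpG dyad are harmonized to one
coordinate (the '+'-strand C is offset by +1 bp onto the '-'-strand
position), categorized with a 0.7 probability cutoff (methylated when
p > 0.7, unmethylated when 1 - p > 0.7, ambiguous otherwise), and summarized
into per-site frequencies.

Two comparative statistics follow:

* *Windowed relative methylation* — mean frequencies in 100-bp windows
  sliding every 10 bp for each fraction; the ecDNA window means are
  regressed on the chromosomal window means and internally studentized
  residuals (R's ``rstandard``) express per-window relative methylation.
* *Per-peak differential test* — per-site residuals from the same
  regression restricted to CpGs with coverage above 5 in both fractions and
  overlapping accessible (ATAC) peaks with log-normalized coverage above 9;
  for each peak z = (x - m) / s.e. with x the mean residual in the peak, m
  and the standard deviation taken over all qualifying CpGs; two-sided
  normal p-values are Benjamini-Hochberg adjusted across peaks and called
  significant below 0.005.

Single-molecule structure is captured by co-occurrence matrices: for each
site pair, the fraction of reads categorizable at both sites on which both
are methylated (resp. both unmethylated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import OLSInfluence

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
AMBIGUOUS = "ambiguous"

#: Probability cutoff for categorizing a single call.
CATEGORIZE_THRESHOLD = 0.7
#: Rolling-window geometry (bp) for locus-wide relative methylation.
WINDOW_BP = 100
STEP_BP = 10
#: ATAC peak filter: keep peaks with log-normalized coverage score above this.
PEAK_SCORE_MIN = 9.0
#: Differential test site filter: coverage must exceed this in both fractions.
MIN_SITE_COVERAGE = 5
#: BH-adjusted significance cutoff for differential peaks.
SIGNIFICANCE_ALPHA = 0.005


class DegenerateRegressionError(ValueError):
    """Raised when a regression has too few points or a constant predictor."""


# ---------------------------------------------------------------------------
# Per-read calls
# ---------------------------------------------------------------------------

def read_calls(path) -> pd.DataFrame:
    """Read a per-read call TSV: read_id, chrom, strand, pos, p_meth."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"read_id", "chrom", "strand", "pos", "p_meth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def harmonize_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse CpG dyads onto one coordinate per site.

    '+'-strand call positions are shifted +1 bp to the position of the
    corresponding C on the '-' strand; '-' positions are unchanged.
    """
    strands = set(calls["strand"].unique())
    unknown = strands - {"+", "-"}
    if unknown:
        raise ValueError(f"unknown strand codes {sorted(unknown)}")
    out = calls.copy()
    out["pos"] = out["pos"] + (out["strand"] == "+").astype(int)
    return out


def categorize_call(p_meth: float, threshold: float = CATEGORIZE_THRESHOLD) -> str:
    """Categorize one call: methylated, unmethylated, or ambiguous."""
    if p_meth > threshold:
        return METHYLATED
    if (1.0 - p_meth) > threshold:
        return UNMETHYLATED
    return AMBIGUOUS


def categorize(calls: pd.DataFrame, threshold: float = CATEGORIZE_THRESHOLD) -> pd.DataFrame:
    """Vectorized categorization; adds a ``category`` column."""
    out = calls.copy()
    p = out["p_meth"].to_numpy(dtype=float)
    cat = np.full(len(out), AMBIGUOUS, dtype=object)
    cat[p > threshold] = METHYLATED
    cat[(1.0 - p) > threshold] = UNMETHYLATED
    out["category"] = cat
    return out


def site_frequencies(calls: pd.DataFrame, threshold: float = CATEGORIZE_THRESHOLD) -> pd.DataFrame:
    """Per-site counts and methylation frequency from harmonized calls.

    Ambiguous calls are excluded from coverage; sites where every call is
    ambiguous keep coverage 0 and an undefined (NaN) frequency.
    """
    cat = categorize(calls, threshold)
    grouped = cat.groupby(["chrom", "pos"])["category"].agg(
        n_meth=lambda s: (s == METHYLATED).sum(),
        n_unmeth=lambda s: (s == UNMETHYLATED).sum(),
        n_ambiguous=lambda s: (s == AMBIGUOUS).sum(),
    ).reset_index()
    grouped["coverage"] = grouped["n_meth"] + grouped["n_unmeth"]
    with np.errstate(invalid="ignore"):
        grouped["frequency"] = np.where(
            grouped["coverage"] > 0,
            grouped["n_meth"] / grouped["coverage"].replace(0, np.nan),
            np.nan,
        )
    return grouped


# ---------------------------------------------------------------------------
# Windowed relative methylation
# ---------------------------------------------------------------------------

def _studentized_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Internally studentized residuals of the OLS fit y ~ x (R's rstandard)."""
    if len(x) < 3:
        raise DegenerateRegressionError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("constant predictor (zero variance)")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    # a numerically perfect fit has no residual scale; report exact zeros
    if model.ssr <= 1e-12 * max(1.0, float(np.sum(np.square(y)))):
        return np.zeros(len(x))
    infl = OLSInfluence(model)
    return np.asarray(infl.resid_studentized_internal)


def _window_means(sites: pd.DataFrame, window: int, step: int) -> pd.DataFrame:
    """Unweighted mean of site frequencies per sliding window.

    Windows are [w, w + window) anchored every ``step`` bp per chromosome;
    windows with no covered site are omitted.
    """
    rows = []
    for chrom, chrom_sites in sites.groupby("chrom"):
        covered = chrom_sites[chrom_sites["coverage"] > 0]
        if covered.empty:
            continue
        pos = covered["pos"].to_numpy()
        freq = covered["frequency"].to_numpy(dtype=float)
        lo = (pos.min() - window) // step * step
        hi = pos.max()
        for w_start in range(int(lo), int(hi) + 1, step):
            mask = (pos >= w_start) & (pos < w_start + window)
            if mask.any():
                rows.append((chrom, w_start, w_start + window, float(freq[mask].mean())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_frequency"])


def windowed_relative_methylation(
    ec_sites: pd.DataFrame,
    chr_sites: pd.DataFrame,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
) -> pd.DataFrame:
    """Per-window studentized residuals of ecDNA vs chromosomal methylation.

    Both inputs are site-frequency tables (from :func:`site_frequencies`).
    Window means are computed per fraction, paired on shared windows, and
    the ecDNA means regressed on the chromosomal means; the returned frame
    adds ``residual``, negative where the ecDNA fraction is relatively
    hypomethylated.
    """
    ec_w = _window_means(ec_sites, window, step)
    chr_w = _window_means(chr_sites, window, step)
    merged = ec_w.merge(chr_w, on=["chrom", "start", "end"], suffixes=("_ec", "_chr"))
    if len(merged) < 3:
        raise DegenerateRegressionError(
            f"only {len(merged)} paired windows; regression undefined"
        )
    merged = merged.reset_index(drop=True)
    merged["residual"] = _studentized_residuals(
        merged["mean_frequency_chr"].to_numpy(dtype=float),
        merged["mean_frequency_ec"].to_numpy(dtype=float),
    )
    return merged


# ---------------------------------------------------------------------------
# Peak filtering and differential testing
# ---------------------------------------------------------------------------

def peak_score(norm_coverage: float, width: float) -> float:
    """log2(normcov / width * 500 + 1): width-adjusted, scaled, log coverage."""
    if width <= 0:
        raise ValueError("peak width must be positive")
    return math.log2(norm_coverage / width * 500.0 + 1.0)


def filter_peaks(peaks: pd.DataFrame, min_score: float = PEAK_SCORE_MIN) -> pd.DataFrame:
    """Keep accessible peaks with log-normalized coverage score strictly above 9.

    Expects columns chrom, start, end, norm_coverage; adds ``score``.
    """
    out = peaks.copy()
    widths = out["end"] - out["start"]
    if (widths <= 0).any():
        raise ValueError("peak with non-positive width")
    out["score"] = np.log2(out["norm_coverage"] / widths * 500.0 + 1.0)
    return out[out["score"] > min_score].reset_index(drop=True)


@dataclass
class DiffRegionResult:
    chrom: str
    start: int
    end: int
    n_sites: int
    mean_residual: float
    z: float
    p_value: float
    p_adjusted: float = math.nan
    significant: bool = False


def differential_peak_test(
    ec_sites: pd.DataFrame,
    chr_sites: pd.DataFrame,
    peaks: pd.DataFrame,
    min_coverage: int = MIN_SITE_COVERAGE,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> list[DiffRegionResult]:
    """Per-peak differential methylation via standardized regression residuals.

    CpG sites with coverage above ``min_coverage`` in both fractions and
    overlapping a (pre-filtered) peak are regressed (ecDNA on chromosomal
    per-site frequencies); each peak's z compares its mean site residual to
    the residual distribution over all qualifying sites.  P-values are
    two-sided normal, BH-adjusted across peaks; peaks without any
    qualifying CpG are omitted.
    """
    merged = ec_sites.merge(
        chr_sites, on=["chrom", "pos"], suffixes=("_ec", "_chr")
    )
    merged = merged[
        (merged["coverage_ec"] > min_coverage) & (merged["coverage_chr"] > min_coverage)
    ].reset_index(drop=True)

    in_peak = np.zeros(len(merged), dtype=bool)
    peak_idx: list[np.ndarray] = []
    for peak in peaks.itertuples(index=False):
        mask = (
            (merged["chrom"] == peak.chrom)
            & (merged["pos"] >= peak.start)
            & (merged["pos"] < peak.end)
        ).to_numpy()
        peak_idx.append(mask)
        in_peak |= mask

    qualifying = merged[in_peak].reset_index(drop=True)
    if len(qualifying) < 2:
        raise DegenerateRegressionError("fewer than 2 qualifying CpG sites")
    resid = _studentized_residuals(
        qualifying["frequency_chr"].to_numpy(dtype=float),
        qualifying["frequency_ec"].to_numpy(dtype=float),
    )
    resid_by_key = dict(zip(zip(qualifying["chrom"], qualifying["pos"]), resid))

    m = float(np.mean(resid))
    sd = float(np.std(resid, ddof=1))

    results: list[DiffRegionResult] = []
    for peak, mask in zip(peaks.itertuples(index=False), peak_idx):
        keys = list(zip(merged.loc[mask, "chrom"], merged.loc[mask, "pos"]))
        peak_resid = np.array([resid_by_key[k] for k in keys if k in resid_by_key])
        if peak_resid.size == 0:
            continue  # omitted, caller can compare lengths for the warning
        x = float(peak_resid.mean())
        se = sd / math.sqrt(peak_resid.size)
        z = (x - m) / se if se > 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(DiffRegionResult(
            chrom=str(peak.chrom), start=int(peak.start), end=int(peak.end),
            n_sites=int(peak_resid.size), mean_residual=x, z=z, p_value=p,
        ))

    if results:
        raw = [r.p_value for r in results]
        _rej, adj, _a, _b = multipletests(raw, method="fdr_bh")
        for r, p_adj in zip(results, adj):
            r.p_adjusted = float(min(p_adj, 1.0))
            r.significant = r.p_adjusted < alpha
    return results


# ---------------------------------------------------------------------------
# Single-molecule co-occurrence
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceMatrix:
    sites: np.ndarray          # ordered CpG positions
    meth: np.ndarray           # P(both methylated | both categorized)
    unmeth: np.ndarray
    denominators: np.ndarray   # reads categorized at both sites

    def defined(self) -> np.ndarray:
        return self.denominators > 0


def cooccurrence_matrices(calls: pd.DataFrame,
                          threshold: float = CATEGORIZE_THRESHOLD) -> CooccurrenceMatrix:
    """Pairwise single-molecule methylation concordance at a locus.

    For sites i, j: ``meth[i, j]`` is the number of reads on which both are
    methylated divided by the number of reads on which both could be
    categorized (ambiguous calls drop out of the denominator); ``unmeth``
    analogously.  Matrices are symmetric; entries with zero denominator are
    NaN.  Diagonal entries give the within-site methylated/unmethylated
    concordance (they sum to 1 where covered).
    """
    cat = categorize(calls, threshold)
    sites = np.sort(cat["pos"].unique())
    site_index = {p: i for i, p in enumerate(sites)}
    reads = cat["read_id"].unique()
    read_index = {r: i for i, r in enumerate(reads)}

    M = np.zeros((len(reads), len(sites)))
    U = np.zeros((len(reads), len(sites)))
    for row in cat.itertuples(index=False):
        i, j = read_index[row.read_id], site_index[row.pos]
        if row.category == METHYLATED:
            M[i, j] = 1.0
        elif row.category == UNMETHYLATED:
            U[i, j] = 1.0
    C = M + U  # categorized indicator

    denom = C.T @ C
    with np.errstate(invalid="ignore", divide="ignore"):
        meth = np.where(denom > 0, (M.T @ M) / np.where(denom > 0, denom, 1), np.nan)
        unmeth = np.where(denom > 0, (U.T @ U) / np.where(denom > 0, denom, 1), np.nan)
    return CooccurrenceMatrix(sites=sites, meth=meth, unmeth=unmeth,
                              denominators=denom.astype(int))


# ---------------------------------------------------------------------------
# Export helpers
# ---------------------------------------------------------------------------

def write_site_summaries(sites: pd.DataFrame, path) -> None:
    """bedMethyl-like TSV: chrom, start, end, coverage, frequency(%)."""
    out = sites.copy()
    out["start"] = out["pos"]
    out["end"] = out["pos"] + 1
    out["pct"] = (out["frequency"] * 100).round(2)
    out[["chrom", "start", "end", "coverage", "pct"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_diff_results(results: Sequence[DiffRegionResult], path) -> None:
    pd.DataFrame([vars(r) for r in results]).to_csv(path, sep="\t", index=False)
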