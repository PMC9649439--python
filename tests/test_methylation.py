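"""Strand harmonization, categorization, residual statistics and co-occurrence."""

import math

import numpy as np
import pandas as pd
import pytest

from ecdna_catch.methylation import (
    AMBIGUOUS,
    METHYLATED,
    UNMETHYLATED,
    DegenerateRegressionError,
    categorize_call,
    cooccurrence_matrices,
    differential_peak_test,
    filter_peaks,
    harmonize_strands,
    peak_score,
    site_frequencies,
    windowed_relative_methylation,
)


def calls_df(rows):
    return pd.DataFrame(rows, columns=["read_id", "chrom", "strand", "pos", "p_meth"])


class TestHarmonization:
    def test_plus_strand_offset_by_one(self):
        df = calls_df([("r1", "chr7", "+", 100, 0.9)])
        assert harmonize_strands(df)["pos"].iloc[0] == 101

    def test_minus_strand_unchanged(self):
        df = calls_df([("r1", "chr7", "-", 101, 0.9)])
        assert harmonize_strands(df)["pos"].iloc[0] == 101

    def test_dyad_collapses_to_one_site(self):
        df = calls_df([("r1", "chr7", "+", 100, 0.9), ("r2", "chr7", "-", 101, 0.9)])
        assert harmonize_strands(df)["pos"].nunique() == 1

    def test_unknown_strand_code_rejected(self):
        df = calls_df([("r1", "chr7", "*", 100, 0.9)])
        with pytest.raises(ValueError, match="strand"):
            harmonize_strands(df)


class TestCategorization:
    @pytest.mark.parametrize("p, expected", [
        (0.8, METHYLATED),
        (0.25, UNMETHYLATED),    # 1 - 0.25 = 0.75 > 0.7
        (0.5, AMBIGUOUS),
        (0.7, AMBIGUOUS),        # strictly above 0.7 required
        (0.3, AMBIGUOUS),
    ])
    def test_threshold(self, p, expected):
        assert categorize_call(p) == expected


class TestSiteFrequencies:
    def test_counts_and_frequency(self):
        rows = [(f"r{i}", "chr7", "-", 100, 0.9) for i in range(7)]
        rows += [(f"s{i}", "chr7", "-", 100, 0.1) for i in range(3)]
        sites = site_frequencies(calls_df(rows))
        assert sites["coverage"].iloc[0] == 10
        assert sites["frequency"].iloc[0] == pytest.approx(0.7)

    def test_all_ambiguous_site_is_undefined(self):
        rows = [("r1", "chr7", "-", 100, 0.5), ("r2", "chr7", "-", 100, 0.6)]
        sites = site_frequencies(calls_df(rows))
        assert sites["coverage"].iloc[0] == 0
        assert math.isnan(sites["frequency"].iloc[0])

    def test_binomial_recovery_of_planted_frequency(self):
        rng = np.random.default_rng(5)
        meth = rng.random(200) < 0.2
        rows = [(f"r{i}", "chr7", "-", 500, 0.9 if m else 0.1)
                for i, m in enumerate(meth)]
        sites = site_frequencies(calls_df(rows))
        assert sites["frequency"].iloc[0] == pytest.approx(0.2, abs=0.08)


def sites_frame(positions, freqs, coverage=50, chrom="chr7"):
    freqs = np.asarray(freqs, dtype=float)
    n_meth = np.round(freqs * coverage).astype(int)
    return pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "n_meth": n_meth,
        "n_unmeth": coverage - n_meth,
        "n_ambiguous": 0,
        "coverage": coverage,
        "frequency": freqs,
    })


class TestWindowedResiduals:
    def test_identical_tracks_give_flat_residuals(self):
        pos = np.arange(0, 2000, 25)
        freqs = 0.3 + 0.4 * np.sin(pos / 300.0) ** 2
        ec = sites_frame(pos, freqs)
        win = windowed_relative_methylation(ec, ec.copy())
        # perfect diagonal fit: raw residuals vanish to numerical precision
        assert np.nanmax(np.abs(win["residual"].to_numpy())) < 1e-6

    def test_depressed_window_has_minimum_residual(self):
        pos = np.arange(0, 2000, 10)
        base = np.linspace(0.2, 0.8, len(pos))
        ec = base.copy()
        dip = (pos >= 1000) & (pos < 1100)
        ec[dip] -= 0.5
        win = windowed_relative_methylation(
            sites_frame(pos, np.clip(ec, 0, 1)), sites_frame(pos, base)
        )
        worst = win.loc[win["residual"].idxmin()]
        assert 900 <= worst["start"] <= 1100

    def test_constant_tracks_are_degenerate(self):
        pos = np.arange(0, 500, 10)
        ec = sites_frame(pos, np.full(len(pos), 0.5))
        with pytest.raises(DegenerateRegressionError, match="constant"):
            windowed_relative_methylation(ec, ec.copy())

    def test_no_shared_windows_is_an_error(self):
        ec = sites_frame([100], [0.5], chrom="chr1")
        ch = sites_frame([100], [0.4], chrom="chr2")
        with pytest.raises(DegenerateRegressionError, match="window"):
            windowed_relative_methylation(ec, ch)

    def test_residuals_standardized_on_noisy_linear_data(self):
        rng = np.random.default_rng(9)
        pos = np.arange(0, 30_000, 20)
        base = rng.uniform(0.2, 0.8, len(pos))
        ec = np.clip(base + rng.normal(0, 0.05, len(pos)), 0, 1)
        win = windowed_relative_methylation(sites_frame(pos, ec), sites_frame(pos, base))
        r = win["residual"].to_numpy()
        assert abs(np.mean(r)) < 0.05
        assert abs(np.std(r) - 1.0) < 0.1


class TestPeakFilter:
    def test_closed_form_score(self):
        assert peak_score(2048, 500) == pytest.approx(math.log2(2049), rel=1e-12)

    def test_filter_keeps_strictly_above_nine(self):
        width = 500
        at_boundary = (2**9 - 1) * width / 500.0  # score exactly 9
        peaks = pd.DataFrame({
            "chrom": ["c"] * 3,
            "start": [0, 1000, 2000],
            "end": [width, 1000 + width, 2000 + width],
            "norm_coverage": [2048.0, at_boundary, 0.0],
        })
        kept = filter_peaks(peaks)
        assert kept["start"].tolist() == [0]

    def test_zero_coverage_scores_zero(self):
        assert peak_score(0.0, 500) == 0.0

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            peak_score(10, 0)


class TestDifferentialPeaks:
    def _peaks(self, starts, width=200):
        return pd.DataFrame({
            "chrom": "chr7",
            "start": starts,
            "end": [s + width for s in starts],
            "norm_coverage": [3.0 * width] * len(starts),
        })

    def test_identical_fractions_no_signal(self):
        rng = np.random.default_rng(3)
        pos = np.arange(0, 4000, 20)
        base = rng.uniform(0.2, 0.8, len(pos))
        ec = np.clip(base + rng.normal(0, 0.03, len(pos)), 0, 1)
        peaks = self._peaks(list(range(0, 4000, 400)))
        results = differential_peak_test(
            sites_frame(pos, ec), sites_frame(pos, base), peaks
        )
        assert results
        assert not any(r.significant for r in results)

    def test_planted_hypomethylated_peak_most_negative(self):
        rng = np.random.default_rng(13)
        pos = np.arange(0, 8000, 20)
        base = rng.uniform(0.5, 0.9, len(pos))
        ec = base + rng.normal(0, 0.02, len(pos))
        target = (pos >= 2000) & (pos < 2400)  # 20 CpGs
        ec[target] -= 0.4
        peaks = self._peaks(list(range(0, 8000, 400)), width=400)
        results = differential_peak_test(
            sites_frame(pos, np.clip(ec, 0, 1)), sites_frame(pos, base), peaks
        )
        best = min(results, key=lambda r: r.z)
        assert best.start == 2000
        assert best.significant

    def test_low_coverage_sites_excluded(self):
        pos = np.arange(0, 2000, 20)
        base = np.linspace(0.2, 0.8, len(pos))
        ec = sites_frame(pos, base, coverage=5)  # "above 5" required -> all excluded
        with pytest.raises(DegenerateRegressionError):
            differential_peak_test(ec, sites_frame(pos, base), self._peaks([0, 400]))

    def test_bh_adjustment_is_monotone_and_bounded(self):
        rng = np.random.default_rng(21)
        pos = np.arange(0, 6000, 20)
        base = rng.uniform(0.2, 0.8, len(pos))
        ec = np.clip(base + rng.normal(0, 0.05, len(pos)), 0, 1)
        results = differential_peak_test(
            sites_frame(pos, ec), sites_frame(pos, base),
            self._peaks(list(range(0, 6000, 400))),
        )
        by_raw = sorted(results, key=lambda r: r.p_value)
        adj = [r.p_adjusted for r in by_raw]
        assert all(r.p_adjusted >= r.p_value for r in results)
        assert all(p <= 1.0 for p in adj)
        assert adj == sorted(adj)


class TestCooccurrence:
    def test_all_methylated_pair(self):
        rows = []
        for r in range(3):
            rows += [(f"r{r}", "c", "-", 100, 0.9), (f"r{r}", "c", "-", 200, 0.9)]
        mat = cooccurrence_matrices(calls_df(rows))
        assert mat.meth[0, 1] == pytest.approx(1.0)
        assert mat.unmeth[0, 1] == pytest.approx(0.0)

    def test_hand_counted_mixture(self):
        """Reads (M,M), (M,U), (U,U) at two sites: meth 1/3, unmeth 1/3."""
        rows = [
            ("r1", "c", "-", 100, 0.9), ("r1", "c", "-", 200, 0.9),
            ("r2", "c", "-", 100, 0.9), ("r2", "c", "-", 200, 0.1),
            ("r3", "c", "-", 100, 0.1), ("r3", "c", "-", 200, 0.1),
        ]
        mat = cooccurrence_matrices(calls_df(rows))
        assert mat.meth[0, 1] == pytest.approx(1 / 3)
        assert mat.unmeth[0, 1] == pytest.approx(1 / 3)
        assert mat.denominators[0, 1] == 3

    def test_ambiguous_call_drops_from_denominator(self):
        rows = [
            ("r1", "c", "-", 100, 0.9), ("r1", "c", "-", 200, 0.9),
            ("r2", "c", "-", 100, 0.9), ("r2", "c", "-", 200, 0.5),  # ambiguous at j
        ]
        mat = cooccurrence_matrices(calls_df(rows))
        assert mat.denominators[0, 1] == 1
        assert mat.meth[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_complementarity(self):
        rng = np.random.default_rng(2)
        rows = []
        for r in range(20):
            for pos in (100, 200, 300, 400):
                p = rng.choice([0.9, 0.1, 0.5], p=[0.45, 0.45, 0.1])
                rows.append((f"r{r}", "c", "-", pos, p))
        mat = cooccurrence_matrices(calls_df(rows))
        defined = mat.defined()
        assert np.allclose(mat.meth[defined], mat.meth.T[defined.T])
        assert np.all(mat.meth[defined] + mat.unmeth[defined] <= 1.0 + 1e-12)

    def test_uncovered_pair_is_nan(self):
        rows = [("r1", "c", "-", 100, 0.9), ("r2", "c", "-", 200, 0.9)]
        mat = cooccurrence_matrices(calls_df(rows))
        assert math.isnan(mat.meth[0, 1])
        assert mat.denominators[0, 1] == 0
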