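"""Tests of the mapping statistics: filters, frequencies, windows, the
log-odds statistic, null thresholds and QTL calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bulkmap as bm
from bulkmap import bsa

LOG10_9 = math.log10(9.0)


def _record(chrom="I", pos=100, dl=25, dh=25, al=13, ah=13, gl=60, gh=60):
    return bm.SnpRecord(
        chrom=chrom, pos=pos, ref_allele="A", alt_allele="T",
        ref_count_low=dl - al, alt_count_low=al, depth_low=dl, gq_low=gl,
        ref_count_high=dh - ah, alt_count_high=ah, depth_high=dh, gq_high=gh,
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilterSnps:
    def test_gq_threshold_boundary(self):
        cfg = bsa.FilterConfig()
        assert bm.filter_snps([_record(gl=39)], cfg) == []
        assert bm.filter_snps([_record(gh=39)], cfg) == []
        assert len(bm.filter_snps([_record(gl=40, gh=40)], cfg)) == 1

    def test_depth_equality_passes(self):
        # thresholds are "lower than 22/24", so equality survives
        cfg = bsa.FilterConfig()
        assert len(bm.filter_snps([_record(dl=22, dh=24)], cfg)) == 1
        assert bm.filter_snps([_record(dl=21, dh=24)], cfg) == []
        assert bm.filter_snps([_record(dl=22, dh=23)], cfg) == []

    def test_survivors_match_brute_force_recount(self, rng):
        records = [
            _record(
                pos=10 * (i + 1),
                dl=int(rng.integers(15, 35)),
                dh=int(rng.integers(15, 35)),
                al=0,
                ah=0,
                gl=int(rng.integers(20, 80)),
                gh=int(rng.integers(20, 80)),
            )
            for i in range(100)
        ]
        cfg = bsa.FilterConfig()
        kept = bm.filter_snps(records, cfg)
        brute = [
            r
            for r in records
            if min(r.gq_low, r.gq_high) >= 40
            and r.depth_low >= 22
            and r.depth_high >= 24
        ]
        assert kept == brute
        counts = bsa.filter_counts(records, cfg)
        assert counts["kept"] == len(brute)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        gq_min=st.integers(0, 100),
        dmin_l=st.integers(0, 40),
        dmin_h=st.integers(0, 40),
        bump=st.integers(1, 20),
    )
    def test_raising_any_threshold_is_monotone(self, gq_min, dmin_l, dmin_h, bump):
        rng = np.random.default_rng(7)
        records = [
            _record(
                pos=10 * (i + 1),
                dl=int(rng.integers(10, 40)),
                dh=int(rng.integers(10, 40)),
                al=0,
                ah=0,
                gl=int(rng.integers(0, 100)),
                gh=int(rng.integers(0, 100)),
            )
            for i in range(60)
        ]
        base = bsa.FilterConfig(gq_min=gq_min, depth_min_low=dmin_l, depth_min_high=dmin_h)
        n0 = len(bm.filter_snps(records, base))
        for raised in (
            bsa.FilterConfig(gq_min + bump, dmin_l, dmin_h),
            bsa.FilterConfig(gq_min, dmin_l + bump, dmin_h),
            bsa.FilterConfig(gq_min, dmin_l, dmin_h + bump),
        ):
            assert len(bm.filter_snps(records, raised)) <= n0


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

class TestCbAlleleFrequency:
    @pytest.mark.parametrize(
        "alt,total,expected",
        [(10, 40, 0.25), (0, 25, 0.0), (25, 25, 1.0), (13, 25, 0.52)],
    )
    def test_ratio_of_alt_reads(self, alt, total, expected):
        rec = _record(dl=total, al=alt, dh=total, ah=alt)
        pt = bm.cb_allele_frequency(rec)
        assert pt.freq_low == pytest.approx(expected)
        assert pt.freq_high == pytest.approx(expected)

    def test_zero_total_in_a_bulk_raises(self):
        with pytest.raises(ValueError, match="zero read total"):
            bm.cb_allele_frequency(_record(dl=0, al=0))


# ---------------------------------------------------------------------------
# the log-odds statistic
# ---------------------------------------------------------------------------

class TestLogOdds:
    def test_equal_mean_frequencies_give_zero(self):
        assert bm.log_odds(11, 12, 22, 24) == pytest.approx(0.0, abs=1e-12)

    def test_worked_value_quarter_vs_three_quarters(self):
        # l = 0.25*22 = 5.5, h = 0.75*24 = 18 -> log10((18/6)/(5.5/16.5)) = log10(9)
        assert bm.log_odds(5.5, 18.0, 22, 24) == pytest.approx(LOG10_9, abs=1e-9)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        l=st.floats(0, 22, allow_nan=False),
        h=st.floats(0, 24, allow_nan=False),
    )
    def test_swapping_bulks_negates(self, l, h):
        a = bm.log_odds(l, h, 22, 24)
        b = bm.log_odds(h, l, 24, 22)
        assert a == pytest.approx(-b, abs=1e-12)
        assert math.isfinite(a)

    def test_boundary_values_are_clamped_finite(self):
        assert bm.log_odds(0, 24, 22, 24) == pytest.approx(
            math.log10((23.5 / 0.5) / (0.5 / 21.5)), abs=1e-12
        )

    def test_interior_values_are_untouched_by_clamp(self):
        exact = math.log10((15.0 / 9.0) / (7.0 / 15.0))
        assert bm.log_odds(7.0, 15.0, 22, 24) == pytest.approx(exact, abs=1e-15)

    def test_tiny_bulk_raises(self):
        with pytest.raises(ValueError, match="clamp"):
            bm.log_odds(0.5, 0.5, 1, 24)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

class TestWindowStats:
    def _points(self, spec):
        return [
            bm.FrequencyPoint(chrom=c, pos=p, freq_low=fl, freq_high=fh)
            for c, p, fl, fh in spec
        ]

    def test_tiling_from_position_one(self, design):
        pts = self._points(
            [("I", 100_000, 0.5, 0.5), ("I", 250_000, 0.5, 0.5), ("I", 400_000, 0.5, 0.5)]
        )
        wins = bm.window_stats(pts, design)
        assert [(w.start, w.end, w.n_snps) for w in wins] == [
            (1, 300_001, 2),
            (300_001, 600_001, 1),
        ]

    def test_symmetric_window_scales_to_line_equivalents(self, design):
        pts = self._points([("I", 100, 0.5, 0.5)])
        (w,) = bm.window_stats(pts, design)
        assert (w.l, w.h) == (11.0, 12.0)
        assert w.log_odds == pytest.approx(0.0, abs=1e-12)

    def test_window_means_match_brute_force(self, design, rng):
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=400, replace=False))
        fl = rng.random(400)
        fh = rng.random(400)
        pts = self._points(
            [("I", int(p), float(a), float(b)) for p, a, b in zip(pos, fl, fh)]
        )
        wins = bm.window_stats(pts, design)
        for w in wins:
            sel = (pos >= w.start) & (pos < w.end)
            assert w.n_snps == sel.sum()
            assert w.mean_freq_low == pytest.approx(fl[sel].mean())
            assert w.mean_freq_high == pytest.approx(fh[sel].mean())
            assert w.log_odds == pytest.approx(
                bm.log_odds(w.l, w.h, design.n_low, design.n_high)
            )

    def test_unsorted_input_raises(self, design):
        pts = self._points([("I", 500, 0.5, 0.5), ("I", 100, 0.5, 0.5)])
        with pytest.raises(ValueError, match="sorted"):
            bm.window_stats(pts, design)


# ---------------------------------------------------------------------------
# null thresholds
# ---------------------------------------------------------------------------

class TestNullThresholds:
    def test_alpha_one_degenerates_to_the_median(self, design):
        dist = bm.null_threshold_mc(design, alpha=1.0, trials=10_000, seed=3)
        assert abs(dist.threshold_low) < 0.1
        assert abs(dist.threshold_high) < 0.1
        assert dist.threshold_low <= dist.threshold_high

    def test_mc_thresholds_are_symmetric(self, design):
        dist = bm.null_threshold_mc(design, trials=200_000, seed=4)
        assert dist.threshold_low == pytest.approx(-dist.threshold_high, abs=0.02)

    def test_mc_converges_to_exact(self, design, exact_null):
        dist = bm.null_threshold_mc(design, trials=100_000, seed=5)
        assert dist.threshold_low == pytest.approx(exact_null.threshold_low, abs=0.05)
        assert dist.threshold_high == pytest.approx(exact_null.threshold_high, abs=0.05)

    def test_exact_probability_mass_is_normalised(self, exact_null):
        assert exact_null.pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_tiny_design_matches_hand_enumeration(self):
        # n_l = n_h = 2, clamp 0.5: clamped counts in {0.5, 1, 1.5} with odds
        # {1/3, 1, 3}; the statistic takes 5 values with binomial(2, 1/2) mass
        dist = bm.null_threshold_exact(bm.BulkDesign(n_low=2, n_high=2))
        expected = {
            -LOG10_9: 1 / 16,
            -math.log10(3.0): 1 / 4,
            0.0: 3 / 8,
            math.log10(3.0): 1 / 4,
            LOG10_9: 1 / 16,
        }
        assert len(dist.support) == 5
        for v, p in zip(dist.support, dist.pmf):
            key = min(expected, key=lambda e: abs(e - v))
            assert v == pytest.approx(key, abs=1e-9)
            assert p == pytest.approx(expected[key], abs=1e-12)
        # two-tailed alpha = 0.05: only the extreme atoms (1/16 > 0.025 for
        # the next candidate) survive
        assert dist.threshold_high == pytest.approx(LOG10_9, abs=1e-9)
        assert dist.threshold_low == pytest.approx(-LOG10_9, abs=1e-9)

    def test_exact_thresholds_are_tight_conservative(self, design, exact_null):
        # achieved tail mass <= alpha/2, and the next candidate inward violates
        support, pmf = exact_null.support, exact_null.pmf
        assert exact_null.tail_high <= 0.025
        assert exact_null.tail_low <= 0.025
        i_high = int(np.searchsorted(support, exact_null.threshold_high))
        assert pmf[i_high:].sum() > 0.025  # P(stat >= thr) would break alpha/2
        i_low = int(np.searchsorted(support, exact_null.threshold_low))
        assert pmf[: i_low + 1].sum() > 0.025

    def test_swapped_design_negates_thresholds(self, design, exact_null):
        swapped = bm.null_threshold_exact(bm.BulkDesign(n_low=24, n_high=22))
        assert swapped.threshold_high == pytest.approx(
            -exact_null.threshold_low, abs=1e-9
        )
        assert swapped.threshold_low == pytest.approx(
            -exact_null.threshold_high, abs=1e-9
        )


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------

def _window(chrom, k, lod, window=300_000, design=bm.BulkDesign()):
    l_bar = 0.5  # only log_odds matters for calling
    return bsa.WindowStat(
        chrom=chrom, start=1 + k * window, end=1 + (k + 1) * window, n_snps=5,
        mean_freq_low=l_bar, mean_freq_high=l_bar,
        l=l_bar * design.n_low, h=l_bar * design.n_high, log_odds=lod,
    )


class TestCallQtls:
    def test_no_significant_window_gives_empty_list(self, exact_null):
        wins = [_window("I", k, 0.1) for k in range(5)]
        assert bm.call_qtls(wins, exact_null) == []

    def test_adjacent_same_sign_windows_merge_with_peak(self, exact_null):
        wins = [
            _window("III", 0, 0.0),
            _window("III", 3, 0.8),
            _window("III", 4, 1.4),
            _window("III", 5, 0.9),
            _window("III", 6, 0.0),
        ]
        (iv,) = bm.call_qtls(wins, exact_null)
        assert (iv.start, iv.end) == (1 + 3 * 300_000, 1 + 6 * 300_000)
        assert iv.sign == 1 and iv.n_windows == 3
        assert iv.peak_log_odds == pytest.approx(1.4)
        assert iv.peak_start == 1 + 4 * 300_000

    def test_opposite_signs_do_not_merge(self, exact_null):
        wins = [_window("V", 0, 1.0), _window("V", 1, -1.0)]
        a, b = bm.call_qtls(wins, exact_null)
        assert (a.sign, b.sign) == (1, -1)
        assert a.end == b.start

    def test_runs_bridge_omitted_empty_windows_only(self, exact_null):
        # windows 0 and 2 significant, window 1 absent (no SNPs): one interval
        wins = [_window("II", 0, 1.0), _window("II", 2, 0.9)]
        (iv,) = bm.call_qtls(wins, exact_null)
        assert iv.n_windows == 2 and iv.end - iv.start == 3 * 300_000
        # but an emitted non-significant window in between splits the run
        wins = [_window("II", 0, 1.0), _window("II", 1, 0.0), _window("II", 2, 0.9)]
        assert len(bm.call_qtls(wins, exact_null)) == 2
        # unless max_gap allows bridging it
        assert len(bm.call_qtls(wins, exact_null, max_gap=1)) == 1

    def test_peak_tie_goes_leftmost(self, exact_null):
        wins = [_window("X", 0, 1.1), _window("X", 1, 1.1)]
        (iv,) = bm.call_qtls(wins, exact_null)
        assert iv.peak_start == 1


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

class TestLoessCurve:
    def test_constant_input_reproduced(self):
        x = np.arange(10_000, 1_000_001, 10_000)
        fit = bm.loess_curve(x, np.full(len(x), 0.37))
        assert np.allclose(fit, 0.37, atol=1e-9)

    def test_collinear_input_reproduced_exactly(self):
        x = np.arange(10_000, 1_000_001, 10_000).astype(float)
        y = 2e-7 * x + 0.01
        assert np.allclose(bm.loess_curve(x, y), y, atol=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        x = np.arange(100, dtype=float)
        y = rng.random(100)
        assert np.array_equal(bm.loess_curve(x, y, 0.3), bm.loess_curve(x, y, 0.3))

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least 10"):
            bm.loess_curve(np.arange(5), np.arange(5.0))
        with pytest.raises(ValueError, match="span"):
            bm.loess_curve(np.arange(12), np.arange(12.0), span=0.01)
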