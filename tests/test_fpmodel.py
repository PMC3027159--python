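"""Zero-truncated Poisson fits and the false-positive table."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from xdeg.fpmodel import (
    aggregate_pdeg_bins,
    build_fp_table,
    expected_false_positives,
    filter_outliers,
    fit_bins,
    ztp_mle,
    ztp_sf,
)
from xdeg.orthology import OrthologPair
from xdeg.pdeg import CoverageHistogram


def ztp_mle_oracle(mean):
    """Independent root-finder for mean = lambda / (1 - exp(-lambda))."""
    return optimize.brentq(lambda lam: lam / -np.expm1(-lam) - mean, 1e-12, mean, xtol=1e-12)


def draw_ztp(lam, n, rng):
    """Zero-truncated Poisson sample by rejection of zeros."""
    out = []
    while len(out) < n:
        draws = rng.poisson(lam, size=2 * n)
        out.extend(draws[draws > 0].tolist())
    return out[:n]


def pair(i, ra, rb):
    return OrthologPair(f"a{i}", f"b{i}", ra, rb, 97.0, 500)


class TestZtpMle:
    @pytest.mark.parametrize("mean", [1.2, 1.5, 2.0, 3.7, 10.0])
    def test_matches_independent_root_finder(self, mean):
        # build an integer sample with exactly this mean
        lo, frac = int(mean), mean - int(mean)
        counts = [lo + 1] * int(round(frac * 1000)) + [lo] * int(round((1 - frac) * 1000))
        lam = ztp_mle(counts)
        assert lam == pytest.approx(ztp_mle_oracle(np.mean(counts)), abs=1e-8)

    def test_fitted_distribution_reproduces_sample_mean(self):
        rng = np.random.default_rng(5)
        counts = draw_ztp(2.5, 2000, rng)
        lam = ztp_mle(counts)
        assert lam / -np.expm1(-lam) == pytest.approx(np.mean(counts), abs=1e-8)

    def test_all_ones_boundary(self):
        assert ztp_mle([1, 1, 1, 1]) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ztp_mle([])
        with pytest.raises(ValueError):
            ztp_mle([0, 1, 2])

    def test_bias_shrinks_with_sample_size(self):
        # MLE consistency at lambda = 2 over 200 replicates per size
        rng = np.random.default_rng(42)
        biases = []
        for n in (100, 1000, 10_000):
            est = [ztp_mle(draw_ztp(2.0, n, rng)) for _ in range(200)]
            biases.append(abs(np.mean(est) - 2.0))
        assert biases[0] > biases[2]
        assert biases[2] < 0.01


class TestFilterOutliers:
    def test_plausible_sample_unchanged(self):
        kept, removed = filter_outliers([1, 1, 2, 2, 3])
        assert kept == [1, 1, 2, 2, 3] and removed == []
        # under the fitted ZTP the tail of 3 is far above the cutoff
        assert ztp_sf(3, ztp_mle([1, 1, 2, 2, 3])) > 0.1

    def test_extreme_count_removed_then_boundary_fit(self):
        kept, removed = filter_outliers([1, 1, 1, 1, 50])
        assert removed == [50]
        assert ztp_mle(kept) == 0.0

    def test_constant_sample_unchanged(self):
        kept, removed = filter_outliers([4, 4, 4, 4])
        assert kept == [4, 4, 4, 4] and removed == []

    def test_never_removes_below_two_counts(self):
        kept, removed = filter_outliers([1, 80])
        assert len(kept) >= 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            filter_outliers([])


class TestFitBins:
    def test_parameter_recovery_per_bin(self):
        # pairs whose target counts are ZTP draws at known rates
        rng = np.random.default_rng(2024)
        lams = {2: 0.5, 3: 1.0, 4: 2.0, 5: 4.0}
        pairs = []
        i = 0
        for j, lam in lams.items():
            for c in draw_ztp(lam, 5000, rng):
                pairs.append(pair(i, j, c))
                i += 1
        fits = fit_bins(pairs, conditioning="a", min_bin_n=30)
        by_label = {f.bin_label: f for f in fits if not f.is_open}
        for j, lam in lams.items():
            assert by_label[str(j)].lambda_hat == pytest.approx(lam, abs=0.1)
            assert by_label[str(j)].p0 == pytest.approx(
                math.exp(-by_label[str(j)].lambda_hat)
            )

    def test_small_bins_pooled_into_open_bin(self):
        rng = np.random.default_rng(1)
        pairs = [pair(i, 2, c) for i, c in enumerate(draw_ztp(2.0, 50, rng))]
        pairs += [pair(100 + i, 3, c) for i, c in enumerate(draw_ztp(2.0, 10, rng))]
        pairs += [pair(200 + i, 7, c) for i, c in enumerate(draw_ztp(2.0, 10, rng))]
        fits = fit_bins(pairs, conditioning="a", min_bin_n=30)
        assert [f.bin_label for f in fits] == ["2", ">2"]
        open_fit = fits[-1]
        assert open_fit.is_open and open_fit.n_used + open_fit.n_outliers_removed == 20

    def test_singleton_conditioning_excluded_by_default(self):
        rng = np.random.default_rng(1)
        pairs = [pair(i, 1, c) for i, c in enumerate(draw_ztp(2.0, 50, rng))]
        pairs += [pair(100 + i, 2, c) for i, c in enumerate(draw_ztp(2.0, 50, rng))]
        fits = fit_bins(pairs, conditioning="a", min_bin_n=30)
        assert [f.bin_label for f in fits] == ["2"]
        fits_with_singletons = fit_bins(
            pairs, conditioning="a", min_bin_n=30, min_conditioning_count=1
        )
        assert [f.bin_label for f in fits_with_singletons] == ["1", "2"]

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        pairs = [pair(i, 2 + i % 3, c) for i, c in enumerate(draw_ztp(1.5, 300, rng))]
        f1 = fit_bins(pairs)
        f2 = fit_bins(pairs)
        assert f1 == f2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_bins([])


class TestExpectedFalsePositives:
    def _fit(self, label, j, lam, is_open=False):
        from xdeg.fpmodel import TruncatedPoissonFit

        return TruncatedPoissonFit(
            bin_label=label, conditioning_j=j, is_open=is_open, target_species="B",
            n_used=100, n_outliers_removed=0, lambda_hat=lam, p0=math.exp(-lam),
            converged=True,
        )

    def test_half_probability_bin(self):
        hist = CoverageHistogram("A", {2: 1000})
        fp, total = expected_false_positives(hist, [self._fit("2", 2, math.log(2))])
        assert fp["2"] == pytest.approx(500.0)
        assert total == pytest.approx(500.0)

    def test_large_lambda_gives_vanishing_fp(self):
        hist = CoverageHistogram("A", {2: 1000})
        fp, total = expected_false_positives(hist, [self._fit("2", 2, 50.0)])
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_total_is_sum_of_bins(self):
        hist = CoverageHistogram("A", {2: 100, 3: 50})
        fits = [self._fit("2", 2, 1.0), self._fit("3", 3, 2.0)]
        fp, total = expected_false_positives(hist, fits)
        assert total == pytest.approx(fp["2"] + fp["3"])
        assert fp["2"] == pytest.approx(100 * math.exp(-1))

    def test_open_bin_covers_high_coverage_bins(self):
        hist = CoverageHistogram("A", {2: 100, 9: 5, 30: 1})
        fits = [self._fit("2", 2, 1.0), self._fit(">2", 3, 3.0, is_open=True)]
        fp, _ = expected_false_positives(hist, fits)
        assert fp[">2"] == pytest.approx(6 * math.exp(-3))

    def test_uncovered_bin_rejected(self):
        hist = CoverageHistogram("A", {2: 100, 3: 7})
        with pytest.raises(ValueError, match="no covering fit"):
            expected_false_positives(hist, [self._fit("2", 2, 1.0)])


class TestBuildFpTable:
    def test_expected_de_is_clipped_difference(self):
        table = build_fp_table({"2": 100, "3": 10}, {"2": 30.0, "3": 25.0})
        rows = {r.bin_label: r for r in table.rows}
        assert rows["2"].expected_de == pytest.approx(70.0)
        assert rows["3"].expected_de == 0.0  # clipped
        assert rows["3"].expected_de_raw == pytest.approx(-15.0)

    def test_open_bin_expected_equals_observed(self):
        table = build_fp_table({"2": 100, ">8": 320}, {"2": 30.0, ">8": 5.0})
        rows = {r.bin_label: r for r in table.rows}
        assert rows[">8"].expected_fp == 0.0
        assert rows[">8"].expected_de == 320
        assert [r.bin_label for r in table.rows] == ["2", ">8"]  # open bin last

    def test_observed_total_conserved(self):
        observed = {"2": 10, "3": 20, ">3": 5}
        table = build_fp_table(observed, {"2": 1.0, "3": 2.0})
        assert table.total_observed == sum(observed.values())

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            build_fp_table({"2": 10}, {"3": 1.0})


class TestAggregatePdegBins:
    def test_pooling_matches_fit_bins(self):
        from xdeg.fpmodel import TruncatedPoissonFit

        fits = [
            TruncatedPoissonFit("2", 2, False, "B", 50, 0, 1.0, math.exp(-1), True),
            TruncatedPoissonFit(">2", 3, True, "B", 50, 0, 2.0, math.exp(-2), True),
        ]
        agg = aggregate_pdeg_bins({2: 7, 3: 2, 12: 1}, fits)
        assert agg == {"2": 7, ">2": 3}
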