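"""The DNL scan and its building blocks."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from dnlscreen import (
    DNLParams,
    Peak,
    Spectrum,
    estimate_snr,
    fit_noise_regression,
    predict_peak,
    predict_second,
    scan_spectrum,
    snr_trace,
    sort_peaks,
)
from _oracles import hand_scan, ols_by_grid_refinement


def spectrum_of(abundances, mz=None):
    mz = mz or [100.0 + 10 * i for i in range(len(abundances))]
    return Spectrum("t", peaks=[Peak(m, a) for m, a in zip(mz, abundances)])


class TestParams:
    def test_defaults(self):
        p = DNLParams()
        assert (p.delta, p.snr_min, p.n_min) == (0.5, 2.0, 8)

    @pytest.mark.parametrize(
        "kwargs", [{"delta": -0.1}, {"snr_min": 0.0}, {"n_min": -1}]
    )
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            DNLParams(**kwargs)


class TestSortPeaks:
    def test_sorts_ascending_by_abundance(self):
        assert [p.abundance for p in sort_peaks(spectrum_of([5, 1, 3]))] == [1, 3, 5]

    def test_ties_broken_by_mz(self):
        s = spectrum_of([2, 2], mz=[300.0, 100.0])
        assert [p.mz for p in sort_peaks(s)] == [100.0, 300.0]

    def test_non_positive_abundances_dropped(self):
        assert [p.abundance for p in sort_peaks(spectrum_of([0, -1, 4]))] == [4]


class TestBuildingBlocks:
    @pytest.mark.parametrize(
        "first, delta, expected", [(100, 0.5, 150), (100, 0, 100), (7, 1.0, 14)]
    )
    def test_predict_second(self, first, delta, expected):
        assert predict_second(first, delta) == pytest.approx(expected)

    def test_predict_second_requires_positive_abundance(self):
        with pytest.raises(ValueError):
            predict_second(0.0, 0.5)

    @pytest.mark.parametrize(
        "prefix, slope, intercept",
        [
            ([2, 4], 2.0, 0.0),
            ([1, 2, 4], 1.5, -2.0 / 3.0),  # frozen from the grid-refinement oracle
            ([5, 5, 5, 5], 0.0, 5.0),
        ],
    )
    def test_fit_noise_regression(self, prefix, slope, intercept):
        fit = fit_noise_regression(prefix)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.n_points == len(prefix)

    def test_fit_requires_two_points(self):
        with pytest.raises(ValueError):
            fit_noise_regression([3.0])

    @pytest.mark.parametrize(
        "prefix, k, expected",
        [([2, 4], 3, 6.0), ([5, 5, 5, 5], 5, 5.0), ([1, 2, 4], 4, 16.0 / 3.0)],
    )
    def test_predict_peak_extrapolates_one_rank(self, prefix, k, expected):
        assert predict_peak(fit_noise_regression(prefix), k) == pytest.approx(expected)

    def test_predict_peak_rejects_wrong_rank(self):
        with pytest.raises(ValueError):
            predict_peak(fit_noise_regression([2, 4]), 5)

    @pytest.mark.parametrize(
        "observed, predicted, expected", [(300, 150, 2.0), (7.5, 7.5, 1.0), (100, 150, 2 / 3)]
    )
    def test_estimate_snr(self, observed, predicted, expected):
        assert estimate_snr(observed, predicted) == pytest.approx(expected)

    def test_estimate_snr_rejects_non_positive_prediction(self):
        with pytest.raises(ValueError):
            estimate_snr(10.0, 0.0)


class TestScan:
    def test_worked_example_every_intermediate(self, worked_example):
        """[10,12,14,16,100]: noise line 2i+8, signal only at rank 5."""
        result = scan_spectrum(worked_example)
        assert result.n_total == 5
        assert result.snr_trace == pytest.approx((0.8, 1.0, 1.0, 100 / 18))
        assert result.first_signal_index == 5
        assert result.noise_level == pytest.approx(18.0)
        assert result.signal_count == 1
        assert result.signal_threshold == pytest.approx(100.0)

    def test_constant_spectrum_is_all_noise(self):
        result = scan_spectrum(spectrum_of([9.0] * 5))
        assert result.signal_count == 0
        assert result.first_signal_index is None
        assert result.noise_level is None
        assert result.snr_trace == pytest.approx((1 / 1.5, 1.0, 1.0, 1.0))

    @pytest.mark.parametrize("abundances", [[], [4.0], [0.0, -2.0]])
    def test_fewer_than_two_positive_peaks_is_all_noise(self, abundances):
        result = scan_spectrum(spectrum_of(abundances))
        assert result.signal_count == 0
        assert result.snr_trace == ()

    def test_gaussian_noise_spectrum_classified_all_noise(self):
        rng = np.random.default_rng(11)
        result = scan_spectrum(spectrum_of(rng.normal(1000, 100, size=100)))
        assert result.signal_count == 0
        assert result.n_total == 100

    def test_ties_at_signal_boundary_all_count_as_signal(self):
        result = scan_spectrum(spectrum_of([10, 11, 12, 13, 200, 200, 300]))
        assert result.signal_threshold == pytest.approx(200.0)
        assert result.signal_count == 3

    def test_agrees_with_literal_rescan(self):
        """Incremental fits must match an lstsq-based re-execution."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(2, 40))
            abundances = np.sort(rng.uniform(1, 5000, size=n))
            result = scan_spectrum(spectrum_of(abundances))
            k, noise, count, trace = hand_scan(abundances)
            assert result.first_signal_index == k
            assert result.signal_count == count
            assert result.snr_trace == pytest.approx(trace, rel=1e-9)
            if noise is not None:
                assert result.noise_level == pytest.approx(noise, rel=1e-9)

    def test_snr_trace_covers_all_ranks_without_early_stop(self, worked_example):
        assert snr_trace(worked_example) == pytest.approx([0.8, 1.0, 1.0, 100 / 18])
        spiked = spectrum_of([10, 12, 14, 16, 100, 101])
        assert len(snr_trace(spiked)) == 5
        assert snr_trace(spectrum_of([7.0])) == []

    def test_incremental_fit_identical_to_standalone_fit(self):
        """The scan's running-sum OLS equals fit_noise_regression bitwise."""
        rng = np.random.default_rng(3)
        abundances = np.sort(rng.uniform(10, 100, size=30))
        trace = snr_trace(spectrum_of(abundances))
        for k in range(3, 31):
            fit = fit_noise_regression(list(abundances[: k - 1]))
            predicted = predict_peak(fit, k)
            assert trace[k - 2] == abundances[k - 1] / predicted


class TestOracleEquivalence:
    def test_ols_matches_grid_refinement_on_random_prefixes(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            y = np.sort(rng.uniform(0.5, 2000.0, size=n))
            fit = fit_noise_regression(list(y))
            slope, intercept = ols_by_grid_refinement(y)
            scale = max(1.0, float(np.abs(y).max()))
            assert fit.slope == pytest.approx(slope, rel=1e-6, abs=1e-6 * scale)
            assert fit.intercept == pytest.approx(intercept, rel=1e-6, abs=1e-6 * scale)

    def test_ols_matches_polyfit(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            y = rng.uniform(0.5, 2000.0, size=n)
            fit = fit_noise_regression(list(y))
            slope, intercept = np.polyfit(np.arange(1, n + 1), y, 1)
            assert fit.slope == pytest.approx(slope, rel=1e-9, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)


positive_abundances = st.lists(
    st.floats(min_value=0.1, max_value=1e6, allow_nan=False, allow_infinity=False),
    min_size=2,
    max_size=40,
)


class TestInvariants:
    @settings(max_examples=60, derandomize=True)
    @given(abundances=positive_abundances, c=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, abundances, c):
        """SNRs are abundance ratios, so uniform rescaling changes nothing
        but the noise level, which scales linearly."""
        # knife-edge spectra with an SNR exactly at the threshold are
        # legitimately decided by the last float bit; exclude them
        assume(all(abs(v - 2.0) > 1e-9 for v in snr_trace(spectrum_of(abundances))))
        base = scan_spectrum(spectrum_of(abundances))
        scaled = scan_spectrum(spectrum_of([a * c for a in abundances]))
        assert scaled.first_signal_index == base.first_signal_index
        assert scaled.signal_count == base.signal_count
        assert scaled.snr_trace == pytest.approx(base.snr_trace, rel=1e-9)
        if base.noise_level is not None:
            assert scaled.noise_level == pytest.approx(base.noise_level * c, rel=1e-9)

    @settings(max_examples=60, derandomize=True)
    @given(abundances=positive_abundances, seed=st.integers(0, 2**16))
    def test_permutation_invariance(self, abundances, seed):
        s = spectrum_of(abundances)
        shuffled_peaks = list(s.peaks)
        np.random.default_rng(seed).shuffle(shuffled_peaks)
        base = scan_spectrum(s)
        perm = scan_spectrum(Spectrum("t", peaks=shuffled_peaks))
        assert perm == base

    @settings(max_examples=60, derandomize=True)
    @given(abundances=positive_abundances)
    def test_signal_count_non_increasing_in_snr_min(self, abundances):
        s = spectrum_of(abundances)
        counts = [
            scan_spectrum(s, DNLParams(snr_min=t)).signal_count
            for t in (1.0, 1.5, 2.0, 3.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)

    @settings(max_examples=60, derandomize=True)
    @given(abundances=positive_abundances)
    def test_noise_predictions_stay_positive(self, abundances):
        """Guarantees the SNR denominator: for sorted positive input the
        extrapolated noise abundance is positive at every rank."""
        s = spectrum_of(abundances)
        trace = snr_trace(s)
        assert all(np.isfinite(trace))
        assert all(v > 0 for v in trace)
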