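"""The dynamic noise level (DNL) scan.

A tandem mass spectrum of usable quality is assumed to consist of noise
peaks whose abundances all lie below those of its signal peaks, with at
least one noise peak present.  Sorting the peak abundances ascending,
``I_1 <= I_2 <= ... <= I_N``, the noise abundances then form the leading
prefix, and — because Gaussian order statistics grow near-linearly in
their middle range — that prefix is well described by a straight line in
the rank index ``i``.

The scan exploits this: peak 1 is taken as noise axiomatically; for each
subsequent rank ``k`` the abundance expected *if peak k were also noise*
is extrapolated from the ranks below it (a factor ``1 + delta`` above
``I_1`` when ``k = 2``, the ordinary-least-squares line through
``I_1..I_{k-1}`` evaluated at ``k`` otherwise), and the ratio of the
observed to the predicted abundance is the peak's estimated
signal-to-noise ratio.  The first rank whose SNR exceeds ``snr_min``
is the first signal peak; the prediction there is the spectrum's noise
level, and every peak at or above that observed abundance counts as
signal.  A spectrum with fewer than ``n_min`` signal peaks is screened
out (see :mod:`dnlscreen.screening`).

The incremental scan and :func:`fit_noise_regression` accumulate the
regression sums in the same left-to-right order, so the slope and
intercept used at step ``k`` equal the standalone full-prefix OLS fit
bitwise, not merely to rounding.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from .mgf_io import Peak, Spectrum

__all__ = [
    "DNLParams",
    "RegressionFit",
    "ScanResult",
    "sort_peaks",
    "predict_second",
    "fit_noise_regression",
    "predict_peak",
    "estimate_snr",
    "scan_spectrum",
    "snr_trace",
]


@dataclass(frozen=True)
class DNLParams:
    """The three tunables of the DNL screen.

    delta
        Fractional headroom allowed between the two lowest peaks before
        peak 2 counts as signal; 0.5 by default.
    snr_min
        Minimum observed/predicted abundance ratio for a peak to be
        called signal; 2 by default.
    n_min
        Minimum number of signal peaks for a spectrum to be retained;
        8 by default.
    """

    delta: float = 0.5
    snr_min: float = 2.0
    n_min: int = 8

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.snr_min <= 0:
            raise ValueError(f"snr_min must be > 0, got {self.snr_min}")
        if self.n_min < 0:
            raise ValueError(f"n_min must be >= 0, got {self.n_min}")


@dataclass(frozen=True)
class RegressionFit:
    """OLS line ``I_i = slope * i + intercept`` through a noise prefix."""

    slope: float
    intercept: float
    n_points: int

    def predict(self, k: int) -> float:
        return self.slope * k + self.intercept


@dataclass(frozen=True)
class ScanResult:
    """Outcome of one DNL scan.

    ``sorted_peaks`` is the positive-abundance peak list in scan order
    (abundance ascending, m/z breaking ties).  ``snr_trace`` holds the
    estimated SNR for each scanned rank ``k = 2..``; with early stopping
    it ends at the first signal peak.  ``first_signal_index`` is that
    rank (1-based), ``noise_level`` the predicted abundance there, and
    ``signal_count`` the number of peaks at or above the first signal
    peak's observed abundance.  All three are absent/zero when the whole
    spectrum is noise.
    """

    sorted_peaks: tuple[Peak, ...]
    snr_trace: tuple[float, ...]
    first_signal_index: Optional[int]
    noise_level: Optional[float]
    signal_count: int
    n_total: int

    def __post_init__(self) -> None:
        if (self.first_signal_index is None) != (self.noise_level is None):
            raise ValueError("first_signal_index and noise_level must co-occur")
        if (self.first_signal_index is None) != (self.signal_count == 0):
            raise ValueError("signal_count must be 0 iff no signal peak found")
        if self.signal_count > self.n_total:
            raise ValueError("signal_count cannot exceed n_total")

    @property
    def signal_threshold(self) -> Optional[float]:
        """Observed abundance of the first signal peak; peaks >= it are signal."""
        if self.first_signal_index is None:
            return None
        return self.sorted_peaks[self.first_signal_index - 1].abundance


def sort_peaks(spectrum: Spectrum) -> list[Peak]:
    """Positive-abundance peaks sorted by abundance, then m/z (stable)."""
    return sorted(
        (p for p in spectrum.peaks if p.abundance > 0),
        key=lambda p: (p.abundance, p.mz),
    )


def predict_second(first_abundance: float, delta: float) -> float:
    """Noise prediction for rank 2: ``(1 + delta) * I_1``."""
    if first_abundance <= 0:
        raise ValueError(f"first abundance must be > 0, got {first_abundance}")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    return (1.0 + delta) * first_abundance


def fit_noise_regression(prefix: Sequence[float]) -> RegressionFit:
    """OLS fit of abundances ``I_1..I_m`` against ranks ``1..m``.

    Closed-form normal-equations solution; the rank sums ``sum(i)`` and
    ``sum(i^2)`` are exact integers.  Requires at least two points — the
    two lowest peaks are related by ``predict_second`` instead.
    """
    m = len(prefix)
    if m < 2:
        raise ValueError(f"regression needs >= 2 points, got {m}")
    sum_y = 0.0
    sum_xy = 0.0
    for i, y in enumerate(prefix, start=1):
        sum_y += y
        sum_xy += i * y
    return _solve_ols(m, sum_y, sum_xy)


def _solve_ols(m: int, sum_y: float, sum_xy: float) -> RegressionFit:
    sum_x = m * (m + 1) // 2
    sum_xx = m * (m + 1) * (2 * m + 1) // 6
    denom = m * sum_xx - sum_x * sum_x
    slope = (m * sum_xy - sum_x * sum_y) / denom
    intercept = (sum_y - slope * sum_x) / m
    return RegressionFit(slope=slope, intercept=intercept, n_points=m)


def predict_peak(fit: RegressionFit, k: int) -> float:
    """Extrapolate the fitted noise line one rank past the prefix."""
    if k != fit.n_points + 1:
        raise ValueError(
            f"prediction rank {k} must be n_points + 1 = {fit.n_points + 1}"
        )
    return fit.predict(k)


def estimate_snr(observed: float, predicted: float) -> float:
    """Estimated SNR of a peak: observed over predicted-if-noise abundance."""
    if predicted <= 0:
        raise ValueError(f"predicted abundance must be > 0, got {predicted}")
    return observed / predicted


def _scan_steps(abundances: Sequence[float], delta: float) -> Iterator[tuple[int, float, float]]:
    """Yield ``(k, predicted, snr)`` for ranks 2..N over sorted abundances.

    For ascending positive input the prediction is provably positive at
    every rank: the OLS slope over a non-decreasing sequence is >= 0 and
    the fitted value at the last prefix rank is >= the prefix mean.
    """
    sum_y = abundances[0]
    sum_xy = abundances[0]
    for k in range(2, len(abundances) + 1):
        if k == 2:
            predicted = predict_second(abundances[0], delta)
        else:
            predicted = _solve_ols(k - 1, sum_y, sum_xy).predict(k)
        yield k, predicted, estimate_snr(abundances[k - 1], predicted)
        sum_y += abundances[k - 1]
        sum_xy += k * abundances[k - 1]


def scan_spectrum(spectrum: Spectrum, params: DNLParams = DNLParams()) -> ScanResult:
    """Run the DNL scan, stopping at the first signal peak.

    The comparison with ``snr_min`` is strict, so a peak exactly at the
    threshold is still noise.  Spectra with fewer than two positive
    peaks are all-noise by definition.
    """
    peaks = sort_peaks(spectrum)
    n_total = len(peaks)
    abundances = [p.abundance for p in peaks]

    trace: list[float] = []
    first_signal: Optional[int] = None
    noise_level: Optional[float] = None
    if n_total >= 2:
        for k, predicted, snr in _scan_steps(abundances, params.delta):
            trace.append(snr)
            if snr > params.snr_min:
                first_signal, noise_level = k, predicted
                break

    if first_signal is None:
        signal_count = 0
    else:
        threshold = abundances[first_signal - 1]
        signal_count = n_total - bisect_left(abundances, threshold)

    return ScanResult(
        sorted_peaks=tuple(peaks),
        snr_trace=tuple(trace),
        first_signal_index=first_signal,
        noise_level=noise_level,
        signal_count=signal_count,
        n_total=n_total,
    )


def snr_trace(spectrum: Spectrum, params: DNLParams = DNLParams()) -> list[float]:
    """Per-rank estimated SNR for all ranks 2..N, with no early stop.

    Diagnostic companion to :func:`scan_spectrum`: every rank is treated
    as noise-so-far regardless of its SNR, which is how the full trace
    of a noise-only spectrum is inspected.
    """
    peaks = sort_peaks(spectrum)
    if len(peaks) < 2:
        return []
    abundances = [p.abundance for p in peaks]
    return [snr for _, _, snr in _scan_steps(abundances, params.delta)]
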