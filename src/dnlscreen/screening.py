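"""Retain/filter decisions, denoising, and batch screening of MGF files.

A spectrum is retained when its DNL signal-peak count reaches ``n_min``
(the comparison "below the threshold" is strict, so a spectrum exactly
at ``n_min`` is kept).  Batch screening streams an MGF file spectrum by
spectrum, routes each one to the retained or rejected sink, and
accumulates a report with the dataset-level noise-level and signal-count
distributions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from .core import DNLParams, ScanResult, scan_spectrum
from .mgf_io import MGFParseError, Spectrum, read_mgf, write_mgf

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningDecision",
    "ScreeningReport",
    "screen_spectrum",
    "denoise_spectrum",
    "screen_dataset",
]

#: Width of the noise-level histogram bins, in log10(intensity) units.
NOISE_LEVEL_BIN_WIDTH = 0.1


@dataclass(frozen=True)
class ScreeningDecision:
    """Per-spectrum outcome of the screen."""

    identifier: str
    retained: bool
    signal_count: int
    noise_level: Optional[float]
    n_total: int


@dataclass
class ScreeningReport:
    """Batch tallies plus the two dataset-level distributions.

    The noise-level histogram bins log10(noise level) at 0.1 width and
    excludes all-noise spectra (which have no noise level); the
    signal-count histogram is at integer resolution over all spectra.
    """

    total_spectra: int = 0
    retained: int = 0
    filtered: int = 0
    skipped_malformed: int = 0
    params: DNLParams = field(default_factory=DNLParams)
    _noise_bins: dict[int, int] = field(default_factory=dict)
    _signal_bins: dict[int, int] = field(default_factory=dict)

    def add(self, decision: ScreeningDecision) -> None:
        self.total_spectra += 1
        if decision.retained:
            self.retained += 1
        else:
            self.filtered += 1
        if decision.noise_level is not None and decision.noise_level > 0:
            b = math.floor(math.log10(decision.noise_level) / NOISE_LEVEL_BIN_WIDTH)
            self._noise_bins[b] = self._noise_bins.get(b, 0) + 1
        self._signal_bins[decision.signal_count] = (
            self._signal_bins.get(decision.signal_count, 0) + 1
        )

    @property
    def noise_level_histogram(self) -> list[tuple[float, int]]:
        """``(lower log10-intensity bin edge, count)`` pairs, ascending."""
        return [
            (b * NOISE_LEVEL_BIN_WIDTH, self._noise_bins[b])
            for b in sorted(self._noise_bins)
        ]

    @property
    def signal_count_histogram(self) -> list[tuple[int, int]]:
        """``(signal count, number of spectra)`` pairs, ascending."""
        return [(n, self._signal_bins[n]) for n in sorted(self._signal_bins)]

    def to_dict(self) -> dict:
        return {
            "total_spectra": self.total_spectra,
            "retained": self.retained,
            "filtered": self.filtered,
            "skipped_malformed": self.skipped_malformed,
            "params": {
                "delta": self.params.delta,
                "snr_min": self.params.snr_min,
                "n_min": self.params.n_min,
            },
            "noise_level_histogram": [list(p) for p in self.noise_level_histogram],
            "signal_count_histogram": [list(p) for p in self.signal_count_histogram],
        }

    def to_json(self, sink: Union[str, Path, TextIO]) -> None:
        if hasattr(sink, "write"):
            json.dump(self.to_dict(), sink, indent=2)
        else:
            with open(sink, "w", encoding="utf-8") as handle:
                json.dump(self.to_dict(), handle, indent=2)


def screen_spectrum(
    scan: ScanResult, params: DNLParams, identifier: str = ""
) -> ScreeningDecision:
    """Retain iff the scan found at least ``n_min`` signal peaks."""
    return ScreeningDecision(
        identifier=identifier,
        retained=scan.signal_count >= params.n_min,
        signal_count=scan.signal_count,
        noise_level=scan.noise_level,
        n_total=scan.n_total,
    )


def denoise_spectrum(spectrum: Spectrum, scan: ScanResult) -> Spectrum:
    """Spectrum reduced to its signal peaks, in original peak order.

    Signal membership is abundance >= the observed abundance of the
    first signal peak; an all-noise scan yields an empty peak list.
    Precursor metadata is preserved.
    """
    threshold = scan.signal_threshold
    if threshold is None:
        return spectrum.with_peaks([])
    return spectrum.with_peaks(p for p in spectrum.peaks if p.abundance >= threshold)


def screen_dataset(
    source: Union[str, Path, TextIO, Iterable[Spectrum]],
    params: DNLParams = DNLParams(),
    retained_sink: Union[str, Path, TextIO, None] = None,
    rejected_sink: Union[str, Path, TextIO, None] = None,
    denoise: bool = False,
    decisions: Optional[list[ScreeningDecision]] = None,
) -> ScreeningReport:
    """Screen every spectrum of an MGF file (or spectrum iterable).

    Retained spectra go to *retained_sink*, the rest to *rejected_sink*
    (either may be omitted).  With ``denoise=True`` the retained copies
    keep only their signal peaks; rejected spectra are always written
    verbatim.  Malformed MGF blocks are skipped with a warning and
    counted in the report.  Pass a list as *decisions* to collect the
    per-spectrum outcomes (e.g. for evaluation).

    Memory use is bounded by one spectrum plus the report histograms.
    """
    report = ScreeningReport(params=params)

    def on_skip(exc: MGFParseError) -> None:
        report.skipped_malformed += 1

    if isinstance(source, (str, Path)) or hasattr(source, "read"):
        spectra = read_mgf(source, errors="skip", on_skip=on_skip)
    else:
        spectra = iter(source)

    with _maybe_open(retained_sink) as kept, _maybe_open(rejected_sink) as rejected:
        for spectrum in spectra:
            scan = scan_spectrum(spectrum, params)
            decision = screen_spectrum(scan, params, identifier=spectrum.identifier)
            report.add(decision)
            if decisions is not None:
                decisions.append(decision)
            logger.debug(
                "%s: %d/%d signal peaks -> %s",
                decision.identifier,
                decision.signal_count,
                decision.n_total,
                "retained" if decision.retained else "filtered",
            )
            if decision.retained:
                if kept is not None:
                    out = denoise_spectrum(spectrum, scan) if denoise else spectrum
                    write_mgf([out], kept)
            elif rejected is not None:
                write_mgf([spectrum], rejected)
    return report


class _maybe_open:
    """Open a path for writing, pass a handle through, or yield None."""

    def __init__(self, sink):
        self._sink = sink
        self._handle = None
        self._owned = False

    def __enter__(self):
        if self._sink is None:
            return None
        if hasattr(self._sink, "write"):
            return self._sink
        self._handle = open(self._sink, "w", encoding="utf-8", newline="\n")
        self._owned = True
        return self._handle

    def __exit__(self, *exc):
        if self._owned:
            self._handle.close()
        return False
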