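"""Seeded spectrum simulators for testing the DNL screen end to end.

Two spectrum classes are generated, mirroring the statistical structure
the screening algorithm assumes rather than fragment-ion physics:

* *noise-only* spectra — peak abundances drawn from a Gaussian
  (default mean 1000, sd 100, truncated at a floor of 1 intensity
  unit).  With the mean at least five standard deviations above zero
  the sorted order statistics are nearly linear in rank, so a correct
  scan should call every peak noise.
* *peptide-like* spectra — the same noise floor plus planted signal
  peaks drawn uniformly in ``[noise_max * m, noise_max * 2m]`` with
  multiplier ``m`` (default 2.5), guaranteeing by construction that
  every signal abundance exceeds every noise abundance.

m/z values are drawn uniformly over 200-2000 Th and carry no
information; they exist so fixtures look like, and serialize as, real
MGF data.  Identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .mgf_io import LabelTable, Peak, Spectrum, write_labels, write_mgf

__all__ = [
    "SyntheticSpec",
    "simulate_noise_spectrum",
    "simulate_peptide_spectrum",
    "simulate_labelled_dataset",
]

#: Smallest abundance a truncated noise draw may take (keeps every
#: generated peak positive, so none is dropped by the scan's positivity
#: filter and peak counts stay exact).
ABUNDANCE_FLOOR = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one simulated spectrum."""

    n_noise: int = 100
    n_signal: int = 0
    noise_mean: float = 1000.0
    noise_sd: float = 100.0
    signal_multiplier: float = 2.5
    mz_range: tuple[float, float] = (200.0, 2000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_noise < 1:
            raise ValueError("need at least one noise peak")
        if self.n_signal < 0:
            raise ValueError("n_signal must be >= 0")
        if self.noise_sd <= 0 or self.noise_mean <= 0:
            raise ValueError("noise mean and sd must be positive")
        if self.noise_mean < 5 * self.noise_sd:
            raise ValueError(
                "noise_mean must be >= 5 * noise_sd so truncation stays negligible "
                "and sorted noise abundances remain near-linear in rank"
            )
        if self.signal_multiplier <= 1:
            raise ValueError("signal_multiplier must be > 1")
        low, high = self.mz_range
        if not 0 < low < high:
            raise ValueError(f"invalid mz_range {self.mz_range}")


def _draw_mz(rng: np.random.Generator, n: int, mz_range: tuple[float, float]) -> np.ndarray:
    low, high = mz_range
    mz = rng.uniform(low, high, size=n)
    # collisions are measure-zero for float draws, but keep the guarantee hard
    while len(np.unique(mz)) < n:
        _, idx = np.unique(mz, return_index=True)
        dup = np.setdiff1d(np.arange(n), idx)
        mz[dup] = rng.uniform(low, high, size=len(dup))
    return mz


def _assemble(
    abundances: np.ndarray,
    signal_mask: np.ndarray,
    rng: np.random.Generator,
    spec: SyntheticSpec,
    identifier: str,
) -> tuple[Spectrum, np.ndarray]:
    mz = _draw_mz(rng, len(abundances), spec.mz_range)
    order = np.argsort(mz)
    peaks = [Peak(float(m), float(a)) for m, a in zip(mz[order], abundances[order])]
    spectrum = Spectrum(
        identifier=identifier,
        precursor_mz=float(rng.uniform(*spec.mz_range)),
        precursor_charge=[2],
        peaks=peaks,
    )
    return spectrum, signal_mask[order]


def simulate_noise_spectrum(
    spec: SyntheticSpec, identifier: str = "synthetic-noise"
) -> tuple[Spectrum, np.ndarray]:
    """A noise-only spectrum and its (all-False) ground-truth signal mask."""
    if spec.n_signal != 0:
        raise ValueError("noise spectrum requires n_signal = 0")
    rng = np.random.default_rng(spec.seed)
    abundances = np.maximum(
        rng.normal(spec.noise_mean, spec.noise_sd, size=spec.n_noise), ABUNDANCE_FLOOR
    )
    return _assemble(
        abundances, np.zeros(spec.n_noise, dtype=bool), rng, spec, identifier
    )


def simulate_peptide_spectrum(
    spec: SyntheticSpec, identifier: str = "synthetic-peptide"
) -> tuple[Spectrum, np.ndarray]:
    """A peptide-like spectrum and its ground-truth signal mask.

    Signal abundances are planted strictly above the realized noise
    maximum, so every generated spectrum satisfies the screen's
    signal-above-noise assumption by construction.  ``n_signal = 0``
    falls back to the noise-only generator.
    """
    if spec.n_signal == 0:
        return simulate_noise_spectrum(spec, identifier)
    rng = np.random.default_rng(spec.seed)
    noise = np.maximum(
        rng.normal(spec.noise_mean, spec.noise_sd, size=spec.n_noise), ABUNDANCE_FLOOR
    )
    noise_max = float(noise.max())
    signal = rng.uniform(
        noise_max * spec.signal_multiplier,
        noise_max * 2 * spec.signal_multiplier,
        size=spec.n_signal,
    )
    abundances = np.concatenate([noise, signal])
    mask = np.concatenate(
        [np.zeros(spec.n_noise, dtype=bool), np.ones(spec.n_signal, dtype=bool)]
    )
    return _assemble(abundances, mask, rng, spec, identifier)


def simulate_labelled_dataset(
    n_good: int,
    n_bad: int,
    out_mgf: Union[str, Path],
    out_labels: Union[str, Path],
    template: Optional[SyntheticSpec] = None,
    n_signal_good: int = 20,
    seed: int = 0,
) -> LabelTable:
    """Write a labelled MGF + TSV pair of good and bad spectra.

    Good spectra are peptide-like (``n_signal_good`` planted signal
    peaks, labelled TP); bad spectra are noise-only (labelled
    unidentified).  Per-spectrum seeds derive from *seed*, so the
    output files are byte-identical across runs.
    """
    if n_good + n_bad < 2:
        raise ValueError("need at least 2 spectra in total")
    if template is None:
        template = SyntheticSpec()
    child_seeds = np.random.default_rng(seed).integers(
        0, 2**31, size=n_good + n_bad
    )

    spectra: list[Spectrum] = []
    category: dict[str, str] = {}
    for i in range(n_good):
        spec = replace(
            template, n_signal=n_signal_good, seed=int(child_seeds[i])
        )
        spectrum, _ = simulate_peptide_spectrum(spec, identifier=f"sim|good|{i:05d}")
        spectra.append(spectrum)
        category[spectrum.identifier] = "TP"
    for j in range(n_bad):
        spec = replace(template, n_signal=0, seed=int(child_seeds[n_good + j]))
        spectrum, _ = simulate_noise_spectrum(spec, identifier=f"sim|bad|{j:05d}")
        spectra.append(spectrum)
        category[spectrum.identifier] = "unidentified"

    labels = LabelTable(category=category)
    write_mgf(spectra, out_mgf)
    write_labels(labels, out_labels)
    return labels
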