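# Methods

## Model and procedure

`dnlscreen` treats each tandem mass spectrum independently. Peaks with
non-positive abundance are discarded (some MGF exporters emit
zero-intensity entries, and the SNR ratio is undefined for them); the
remainder are sorted by abundance ascending, ties broken by m/z
ascending so results are deterministic across platforms and input
orderings.

Two structural assumptions underlie the scan: (1) in a usable spectrum,
signal peaks are more abundant than noise peaks, so after sorting the
noise peaks form a prefix; (2) at least one noise peak exists, so rank 1
may be called noise axiomatically. Under a unimodal noise abundance
distribution the sorted noise abundances are the sample order
statistics, which are close to linear in rank away from the extreme
tails — this is what licenses the straight-line noise model
I_i = α·i + β in the rank index.

The scan then walks ranks k = 2..N. The expected abundance of rank k
*if it were noise* is

- k = 2: Î₂ = (1 + δ)·I₁ — with a single noise point no line can be
  fitted, so the second peak is allowed a fractional headroom δ above
  the first;
- k > 2: the ordinary least-squares line through the k−1 ranks already
  called noise, evaluated at k (Î_k = α̂·k + β̂, normal-equations
  solution).

The estimated SNR of rank k is I_k/Î_k. The first rank with SNR
*strictly greater than* SNR_min is the first signal peak; Î_k there is
reported as the spectrum's noise level. Signal membership is then by
observed abundance: every peak with abundance ≥ the first signal peak's
observed abundance is signal, including exact ties. A spectrum whose
signal-peak count n falls below n_min is filtered ("below" is strict,
so n = n_min retains).

Degenerate inputs are defined, not errors: spectra with fewer than two
positive peaks are all-noise (signal count 0, empty trace, no noise
level), as are spectra where no rank ever exceeds SNR_min.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| δ (`delta`) | 0.5 | dimensionless | headroom between ranks 1 and 2; only matters for the k = 2 step, so its influence fades in spectra with more than a couple of noise peaks |
| `snr_min` | 2.0 | dimensionless | minimum observed/predicted abundance ratio to call a peak signal; lower = more aggressive signal calling |
| `n_min` | 8 | peaks | minimum signal peaks to retain a spectrum; the ROC sweep varies exactly this integer |

## Numerical choices

- The OLS fit is the closed-form normal-equations solution; the rank
  sums Σi and Σi² are computed as exact integers. During the scan the
  abundance sums are accumulated incrementally in the same
  left-to-right order used by the standalone `fit_noise_regression`, so
  the incremental and full-prefix fits agree bitwise, not just to
  rounding.
- For positive ascending input the prediction Î_k is provably positive
  (the OLS slope over a non-decreasing sequence is non-negative, and the
  fitted value at the last prefix rank is at least the prefix mean), so
  the SNR denominator can never vanish; this is additionally asserted
  over randomized suites.
- SNR comparisons are strict (`>`), matching the scan's decision rule;
  spectra whose SNR lands exactly on the threshold to the last float bit
  are knife-edge by construction and are excluded from the
  scale-invariance property test only.
- ROC AUC is the trapezoid over all sweep points sorted by
  (1 − specificity, sensitivity), with no deduplication of tied x
  values. For an integer-valued statistic this equals the Mann-Whitney
  probability P(good > bad) + ½·P(tie), which the tests verify by
  exhaustive pair counting; keeping only the max y at tied x would
  overestimate the area.
- Sensitivity and specificity are reported as absent (`None`/JSON
  `null`) when their denominator class is empty rather than coerced to
  a number.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *abundance-distribution structure* the
algorithm consumes, nothing more:

- **Noise-only spectra**: abundances drawn from a Gaussian, default
  mean 1000 and sd 100 (intensity units). The mean/sd ratio of 10 keeps
  truncation at the floor of 1 intensity unit negligible and the sorted
  order statistics near-linear, the regime where the scan should call
  everything noise; the constructor refuses mean < 5·sd. The defaults
  are this package's documented choice for "Gaussian noise" and are
  configurable.
- **Peptide-like spectra**: the same noise floor plus `n_signal` peaks
  drawn uniformly in [noise_max·m, noise_max·2m] with multiplier
  m = 2.5, so every signal abundance exceeds every noise abundance by
  construction and clears SNR_min = 2 robustly. Labelled datasets plant
  20 signal peaks per good spectrum by default.
- m/z values are uniform over 200–2000 Th, sorted and deduplicated;
  they are cosmetic (the scan uses only abundances) but make fixtures
  serialize as realistic MGF.

Not emulated: fragment-ion physics (b/y ladders, isotope envelopes,
charge states), correlated or heavy-tailed noise, intensity-dependent
detector effects, and chimeric spectra. Passing the synthetic suite
therefore demonstrates that the implementation is faithful to the
algorithm and that the algorithm separates the constructed classes; it
does not by itself quantify performance on instrument data, where the
signal-above-noise assumption only holds approximately.

Seeding: every generator takes an explicit seed; labelled datasets
derive per-spectrum seeds from the master seed, so output files are
byte-identical across runs.

## Evaluation conventions

Ground-truth categories follow database-search practice: TP (match from
the true database), FP (match from a decoy database), unidentified (no
significant match). The "bad" class the screen should remove is
FP ∪ unidentified. Charge stratification (singly vs doubly/triply
charged precursors) is carried in the label table, not inferred from
the MGF CHARGE line, because the stratum reflects how a spectrum was
searched. The ROC sweep runs n_min = 0 (nothing filtered, the (0,0)
corner) through one past the largest observed signal count (everything
filtered, (1,1)).

## Problem sizes

The self-contained studies use 100-peak spectra, 200 replicate seeds
for the noise-only replication, 1000 random prefixes for the
regression-oracle comparison, and 100 + 100 spectra for the labelled
recovery study — sizes at which every reported quantity is recomputed
from scratch in seconds.

## Design choices where the design was open

- Spectrum identity between MGF and label table is by TITLE string; a
  missing TITLE is synthesized as `index=<position>` so joins remain
  possible in merged files.
- The reader keeps non-positive-abundance peaks (staying faithful to
  the file); the scan drops them. Denoised output is opt-in — default
  screening writes retained spectra with their original peak lists,
  since screening and denoising are separate concerns.
- Batch screening skips malformed MGF blocks with a warning and counts
  them, rather than aborting a long run; strict per-line errors remain
  the default for the plain reader.
- Report histograms: noise level binned at 0.1 in log10(intensity)
  (noise levels span orders of magnitude); signal counts at integer
  resolution. Spectra with no noise level are excluded from the former.

## Known limitations

- The noise model is linear in rank; strongly multimodal or
  heavy-tailed noise can push early-rank SNR above threshold and
  truncate the noise prefix.
- A spectrum whose signal peaks are interleaved in abundance with noise
  (violating assumption 1) has no correct answer under this model; the
  scan returns the first threshold crossing.
- Parameters are global: no per-charge-state δ/SNR_min/n_min.
- No mzML/mzXML support; MGF is the only on-disk format.
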