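"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the straight-line
fit is found by brute-force grid refinement of the squared error, not by
any closed-form solution.
"""

from __future__ import annotations

import numpy as np


def ols_by_grid_refinement(y, iterations: int = 60, grid: int = 15):
    """Minimize sum((slope*i + intercept - y_i)^2) by shrinking grid search.

    Searched in centered coordinates (slope, level at the mean rank),
    where the squared error separates per coordinate, so the grid argmin
    brackets each true minimizer and a 2x shrink per round converges
    geometrically.  No normal equations anywhere.
    """
    y = np.asarray(y, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float)
    xc = x - x.mean()
    slope_c, level_c = 0.0, float(y.mean())
    scale = 2.0 * max(1.0, float(np.abs(y).max()))
    half_s = half_b = scale
    for _ in range(iterations):
        slopes = np.linspace(slope_c - half_s, slope_c + half_s, grid)
        levels = np.linspace(level_c - half_b, level_c + half_b, grid)
        S, B = np.meshgrid(slopes, levels)
        sse = ((S[..., None] * xc + B[..., None] - y) ** 2).sum(axis=-1)
        i = np.unravel_index(int(np.argmin(sse)), sse.shape)
        slope_c, level_c = float(S[i]), float(B[i])
        half_s *= 0.5
        half_b *= 0.5
    return slope_c, level_c - slope_c * float(x.mean())


def hand_scan(abundances, delta=0.5, snr_min=2.0):
    """Re-execute the DNL scan literally, via numpy lstsq, no shortcuts.

    Returns (first_signal_index, noise_level, signal_count, trace) for a
    pre-sorted positive abundance list.
    """
    a = list(map(float, abundances))
    n = len(a)
    trace = []
    for k in range(2, n + 1):
        if k == 2:
            pred = (1 + delta) * a[0]
        else:
            x = np.arange(1, k, dtype=float)
            A = np.column_stack([x, np.ones_like(x)])
            (slope, intercept), *_ = np.linalg.lstsq(A, np.array(a[: k - 1]), rcond=None)
            pred = slope * k + intercept
        snr = a[k - 1] / pred
        trace.append(snr)
        if snr > snr_min:
            count = sum(1 for v in a if v >= a[k - 1])
            return k, pred, count, trace
    return None, None, 0, trace


def auc_by_pair_counting(good_counts, bad_counts):
    """Mann-Whitney AUC: P(good > bad) + 0.5 * P(good == bad)."""
    wins = ties = 0
    for g in good_counts:
        for b in bad_counts:
            if g > b:
                wins += 1
            elif g == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(good_counts) * len(bad_counts))
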