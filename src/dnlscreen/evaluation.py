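"""Sensitivity/specificity and ROC analysis of the screen.

Ground truth comes from database-search outcomes: spectra identified
with true-positive matches (TP) are the "good" class; spectra with
decoy (FP) matches or no significant match are the "bad" class the
screen should remove.

sensitivity  = correctly filtered bad spectra / all bad spectra
specificity  = 1 - falsely filtered TP spectra / all TP spectra

Sweeping the minimum-signal-peak threshold ``n_min`` over the integers
traces the ROC curve of the integer-valued signal-count statistic;
``n_min = 0`` filters nothing (the (0, 0) corner) and any ``n_min``
past the largest observed count filters everything (the (1, 1) corner).
The AUC is the trapezoid area over the swept points, which for an
integer statistic equals the Mann-Whitney probability that a good
spectrum outranks a bad one (ties counted half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .mgf_io import CATEGORIES, LabelTable
from .screening import ScreeningDecision

logger = logging.getLogger(__name__)

__all__ = ["EvalResult", "ROCCurve", "evaluate", "roc_over_nmin", "category_tally"]

#: Categories forming the "bad" class the screen is meant to remove.
BAD_CATEGORIES = ("FP", "unidentified")


@dataclass(frozen=True)
class EvalResult:
    """Confusion counts per category plus the two headline ratios.

    ``counts`` maps category -> ``{"filtered": int, "retained": int}``.
    Either ratio is ``None`` when its denominator is empty.
    """

    counts: dict[str, dict[str, int]]
    sensitivity: Optional[float]
    specificity: Optional[float]

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass(frozen=True)
class ROCCurve:
    """ROC points ``(1 - specificity, sensitivity)`` over the n_min sweep."""

    points: tuple[tuple[float, float], ...]
    thresholds: tuple[int, ...]
    auc: float

    def to_dict(self) -> dict:
        return {
            "points": [list(p) for p in self.points],
            "thresholds": list(self.thresholds),
            "auc": self.auc,
        }


def _join_labels(
    identifiers: Iterable[str], labels: LabelTable
) -> None:
    missing = [i for i in identifiers if i not in labels]
    if missing:
        shown = ", ".join(repr(i) for i in missing[:10])
        more = "" if len(missing) <= 10 else f" (and {len(missing) - 10} more)"
        raise ValueError(f"decisions without labels: {shown}{more}")


def evaluate(
    decisions: Sequence[ScreeningDecision], labels: LabelTable
) -> EvalResult:
    """Score retain/filter decisions against search-outcome labels.

    Every decision must have a label (fatal otherwise, listing the
    identifiers); labelled spectra with no decision are ignored with a
    warning.
    """
    _join_labels((d.identifier for d in decisions), labels)
    seen_ids = {d.identifier for d in decisions}
    unseen = [i for i in labels.category if i not in seen_ids]
    if unseen:
        logger.warning("%d labelled spectra have no screening decision", len(unseen))

    counts = {cat: {"filtered": 0, "retained": 0} for cat in CATEGORIES}
    for d in decisions:
        cat = labels.category[d.identifier]
        counts[cat]["retained" if d.retained else "filtered"] += 1

    bad_total = sum(sum(counts[c].values()) for c in BAD_CATEGORIES)
    bad_filtered = sum(counts[c]["filtered"] for c in BAD_CATEGORIES)
    tp_total = sum(counts["TP"].values())
    tp_filtered = counts["TP"]["filtered"]

    sensitivity = bad_filtered / bad_total if bad_total else None
    specificity = 1.0 - tp_filtered / tp_total if tp_total else None
    return EvalResult(counts=counts, sensitivity=sensitivity, specificity=specificity)


ScoredSpectra = Iterable[Union[ScreeningDecision, tuple[str, int]]]


def _signal_counts(scored: ScoredSpectra) -> list[tuple[str, int]]:
    pairs = []
    for item in scored:
        if isinstance(item, ScreeningDecision):
            pairs.append((item.identifier, item.signal_count))
        else:
            ident, count = item
            pairs.append((ident, int(count)))
    return pairs


def roc_over_nmin(
    scored: ScoredSpectra,
    labels: LabelTable,
    charge_class: Optional[str] = None,
    sweep_max: Optional[int] = None,
) -> ROCCurve:
    """ROC curve of the signal-count statistic over an ``n_min`` sweep.

    *scored* is any mix of :class:`ScreeningDecision` objects and
    ``(identifier, signal_count)`` pairs.  With *charge_class* set, only
    spectra labelled with that precursor-charge stratum contribute.
    The sweep runs ``n_min = 0 .. max observed signal count + 1``
    (or to *sweep_max* if given); each point applies the retain rule
    ``signal_count >= n_min``.
    """
    pairs = _signal_counts(scored)
    if charge_class is not None:
        labels = labels.subset(charge_class)
        pairs = [(i, n) for i, n in pairs if i in labels]
    _join_labels((i for i, _ in pairs), labels)

    bad = np.array(
        [n for i, n in pairs if labels.category[i] in BAD_CATEGORIES], dtype=float
    )
    good = np.array(
        [n for i, n in pairs if labels.category[i] == "TP"], dtype=float
    )
    if len(bad) < 1 or len(good) < 1:
        raise ValueError(
            f"ROC needs both classes populated: {len(good)} TP, {len(bad)} FP/unidentified"
        )

    top = int(max(bad.max(), good.max())) + 1 if sweep_max is None else sweep_max
    thresholds = list(range(0, top + 1))
    points = []
    for n_min in thresholds:
        sens = float(np.mean(bad < n_min))
        one_minus_spec = float(np.mean(good < n_min))
        points.append((one_minus_spec, sens))

    xy = sorted(points)
    auc = float(np.trapezoid([y for _, y in xy], [x for x, _ in xy]))
    return ROCCurve(points=tuple(points), thresholds=tuple(thresholds), auc=auc)


def category_tally(
    decisions: Sequence[ScreeningDecision], labels: LabelTable
) -> dict[str, dict]:
    """Filtered/retained counts and fractions per search-outcome category.

    Fractions are ``None`` for categories with no spectra.
    """
    result = evaluate(decisions, labels)
    tally: dict[str, dict] = {}
    for cat in CATEGORIES:
        filtered = result.counts[cat]["filtered"]
        retained = result.counts[cat]["retained"]
        total = filtered + retained
        tally[cat] = {
            "filtered": filtered,
            "retained": retained,
            "fraction_filtered": filtered / total if total else None,
            "fraction_retained": retained / total if total else None,
        }
    return tally
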