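"""Scoring predictions against an activity log, and threshold exploration.

Validation is second-by-second: predicted labels are paired with the
ground-truth activity wherever a whole second falls inside a logged
interval, and per-activity one-vs-rest sensitivity and specificity are
tabulated from the paired stream.  Complex activities (basketball-style
play, playground circuits) are summarised instead by the composition of
predicted labels within their intervals.

For threshold exploration, class-conditional feature distributions are
pooled across recordings and smoothed with a Gaussian kernel density;
crossing points between a pair of class densities are candidate decision
thresholds.  Candidates are reported, never applied automatically — the
calibrated presets were chosen by inspection of such curves together with
the known adult thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .classify import LabelSeries
from .errors import AlignmentError, ValidationError
from .io import ActivityLog


def align(
    pred: LabelSeries,
    log: ActivityLog,
    lead_in: float = 0.0,
) -> List[Tuple[str, str]]:
    """Pair ground truth with predictions on whole seconds.

    A second ``[s, s+1)`` is scored when it lies entirely inside a log
    interval (after discarding ``lead_in`` seconds from the start of every
    interval) and inside the prediction span.  Seconds in protocol gaps or
    transitions are excluded by construction.
    """
    pairs: List[Tuple[str, str]] = []
    n = len(pred)
    for e in log.entries:
        start = e.start + lead_in
        if e.end - start <= 0:
            continue
        s0 = math.ceil(start - 1e-9)
        s1 = math.floor(e.end + 1e-9)  # seconds s0 .. s1-1
        for s in range(s0, s1):
            k = int(round(s - pred.t0))
            if 0 <= k < n:
                pairs.append((e.label, pred.labels[k]))
    if not pairs:
        raise AlignmentError("activity log and prediction do not overlap")
    return pairs


@dataclass(frozen=True)
class ConfusionSummary:
    """One-vs-rest confusion counts per activity over paired seconds."""

    counts: Mapping[str, Tuple[int, int, int, int]]  # activity -> (TP, FN, TN, FP)

    @property
    def activities(self) -> Tuple[str, ...]:
        return tuple(self.counts)

    def sensitivity(self, activity: str) -> float:
        tp, fn, _, _ = self.counts[activity]
        return 100.0 * tp / (tp + fn) if tp + fn else float("nan")

    def specificity(self, activity: str) -> float:
        _, _, tn, fp = self.counts[activity]
        return 100.0 * tn / (tn + fp) if tn + fp else float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Per-activity table with percentages rounded to one decimal."""
        rows = []
        for act, (tp, fn, tn, fp) in self.counts.items():
            rows.append(
                {
                    "activity": act,
                    "TP": tp,
                    "FN": fn,
                    "TN": tn,
                    "FP": fp,
                    "sensitivity_pct": round(self.sensitivity(act), 1),
                    "specificity_pct": round(self.specificity(act), 1),
                }
            )
        return pd.DataFrame(rows).set_index("activity")

    def to_dict(self) -> Dict[str, Dict[str, float]]:
        out: Dict[str, Dict[str, float]] = {}
        for act, (tp, fn, tn, fp) in self.counts.items():
            out[act] = {
                "TP": tp,
                "FN": fn,
                "TN": tn,
                "FP": fp,
                "sensitivity_pct": round(self.sensitivity(act), 1),
                "specificity_pct": round(self.specificity(act), 1),
            }
        return out


def confusion(
    pairs: Sequence[Tuple[str, str]],
    undefined_as_negative: bool = True,
) -> ConfusionSummary:
    """Tabulate one-vs-rest confusion counts from (truth, predicted) pairs.

    ``undefined`` predictions count as negative for every activity — they
    cost sensitivity for the true activity but never specificity — unless
    ``undefined_as_negative`` is disabled, in which case those seconds are
    dropped.
    """
    if not pairs:
        raise ValidationError("confusion requires at least one pair")
    if not undefined_as_negative:
        pairs = [(t, p) for t, p in pairs if p != "undefined"]
        if not pairs:
            raise ValidationError("all pairs had undefined predictions")
    activities = sorted({t for t, _ in pairs} | {p for _, p in pairs if p != "undefined"})
    counts: Dict[str, Tuple[int, int, int, int]] = {}
    for act in activities:
        tp = sum(1 for t, p in pairs if t == act and p == act)
        fn = sum(1 for t, p in pairs if t == act and p != act)
        tn = sum(1 for t, p in pairs if t != act and p != act)
        fp = sum(1 for t, p in pairs if t != act and p == act)
        counts[act] = (tp, fn, tn, fp)
    return ConfusionSummary(counts=counts)


def composition(
    pred: LabelSeries,
    log: ActivityLog,
    activity: str,
    lead_in: float = 0.0,
) -> Dict[str, float]:
    """Percentage of each predicted label within one activity's intervals.

    Used for complex activities (e.g. ball games, playground circuits) whose
    ground truth is a mixture; proportions are reported to one decimal and
    sum to 100 up to rounding.
    """
    if activity not in {e.label for e in log.entries}:
        raise KeyError(f"activity {activity!r} not present in the log")
    sub = ActivityLog(entries=tuple(e for e in log.entries if e.label == activity))
    pairs = align(pred, sub, lead_in=lead_in)
    preds = [p for _, p in pairs]
    total = len(preds)
    out = {}
    for label in sorted(set(preds)):
        out[label] = round(100.0 * preds.count(label) / total, 1)
    return out


@dataclass(frozen=True)
class DensityCurve:
    """Kernel density estimate of one feature for one activity class."""

    feature: str
    class_name: str
    grid: np.ndarray
    density: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_value": self.grid, "density": self.density, "class": self.class_name}
        )


def pooled_density(
    values_by_class: Mapping[str, Iterable[float]],
    feature: str = "feature",
    grid_n: int = 512,
    bandwidth: Optional[float] = None,
    min_frames: int = 30,
) -> Tuple[List[DensityCurve], List[float]]:
    """Class-conditional Gaussian kernel densities plus crossing candidates.

    Exactly two class groupings are pooled; the Gaussian kernel uses the
    rule-of-thumb (Scott) bandwidth unless ``bandwidth`` (a KDE factor) is
    given.  Crossing candidates are the grid points where the ordering of
    the two densities flips; they are exploration aids for threshold
    choice, not applied automatically.
    """
    if len(values_by_class) != 2:
        raise ValidationError("pooled_density expects exactly two class groupings")
    arrays = {}
    for cls, vals in values_by_class.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < min_frames:
            raise ValidationError(
                f"class {cls!r} has {arr.size} frames; at least {min_frames} required"
            )
        if np.ptp(arr) == 0:
            raise ValidationError(
                f"class {cls!r} has zero variance; use a histogram instead"
            )
        arrays[cls] = arr
    lo = min(a.min() for a in arrays.values())
    hi = max(a.max() for a in arrays.values())
    pad = 0.1 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_n)
    curves = []
    dens = {}
    for cls, arr in arrays.items():
        kde = gaussian_kde(arr, bw_method=bandwidth)
        d = kde(grid)
        dens[cls] = d
        curves.append(DensityCurve(feature=feature, class_name=cls, grid=grid, density=d))
    c1, c2 = list(dens)
    diff = dens[c1] - dens[c2]
    crossings: List[float] = []
    sign = np.sign(diff)
    for i in range(1, grid_n):
        if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]:
            # linear interpolation of the zero of the density difference
            x0, x1 = grid[i - 1], grid[i]
            y0, y1 = diff[i - 1], diff[i]
            crossings.append(float(x0 - y0 * (x1 - x0) / (y1 - y0)))
    return curves, crossings


def split_subjects(
    subjects: Sequence[Tuple[object, str]], seed: int
) -> Tuple[List[object], List[object]]:
    """Stratified half split of (subject, age_group) pairs.

    Within each age group half the subjects are drawn at random for the
    development set (the extra one on odd counts); the rest form the
    validation set.  Deterministic for a given seed.
    """
    if not subjects:
        raise ValidationError("no subjects to split")
    groups: Dict[str, List[object]] = {}
    for subj, grp in subjects:
        groups.setdefault(grp, []).append(subj)
    for grp, members in groups.items():
        if not members:
            raise ValidationError(f"age group {grp!r} is empty")
    rng = np.random.default_rng(seed)
    development: List[object] = []
    validation: List[object] = []
    for grp in groups:  # insertion order: deterministic
        members = groups[grp]
        perm = rng.permutation(len(members))
        n_dev = (len(members) + 1) // 2
        development.extend(members[i] for i in perm[:n_dev])
        validation.extend(members[i] for i in perm[n_dev:])
    return development, validation
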