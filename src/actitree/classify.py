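"""Decision-tree activity classification with label smoothing.

The tree has five binary conditions and identifies six activity types from
the per-window features.  The root splits on the longitudinal standard
deviation ``sd_long``: above the movement threshold the window is dynamic
(biking when the forward pitch is elevated, otherwise running or walking by
``sd_long``); below it the window is stationary (sitting when the thigh
inclination is high, otherwise moving/shuffling or standing still by
``sd_max``).  Every condition uses strict ``>``; equality takes the false
branch.

Two threshold presets are shipped: ``child``, calibrated on preschoolers,
children and adolescents, and ``adult``, the original adult calibration.
They share the 0.1 g root threshold and differ in the other four nodes.

Raw per-second labels are noisy at activity transitions; a per-activity
median filter (the default), or a sliding majority vote, smooths them.  The
per-activity filter can assert several activities for one second; such
multi-assignments are resolved by priority: lying/sitting beat everything,
biking beats locomotion, and walking/running beat standing/moving.  An
optional trunk sensor relabels sitting seconds as lying when the back is
inclined beyond 65 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import AlignmentError, ConfigurationError, ValidationError
from .features import FeatureFrame, compute_features
from .io import (
    RAW_DEVICE,
    WORKING_FS,
    DeviceOrientation,
    TriaxialRecording,
    remap_to_canonical,
    resample,
)

#: Output vocabulary of the classifier.
LABELS = ("sit", "stand", "move", "walk", "run", "bike", "lie", "undefined")

#: Fixed tie-break order (highest priority first) used when supports tie.
_PRIORITY_ORDER = ("lie", "sit", "bike", "walk", "run", "stand", "move")

#: Priority groups for multi-assignment resolution; earlier groups win.
_PRIORITY_GROUPS = (("lie", "sit"), ("bike",), ("walk", "run"), ("stand", "move"))


@dataclass(frozen=True)
class ThresholdSet:
    """The five decision-node constants plus the lying back-angle rule.

    Units: ``sd_move``, ``sd_run``, ``sd_still`` in g; ``theta_bike``,
    ``inc_sit``, ``back_lie`` in degrees.
    """

    sd_move: float
    theta_bike: float
    sd_run: float
    inc_sit: float
    sd_still: float
    back_lie: float

    def __post_init__(self) -> None:
        for name in ("sd_move", "theta_bike", "sd_run", "inc_sit", "sd_still", "back_lie"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"threshold {name} must be strictly positive")
        if not self.sd_run > self.sd_move:
            raise ValidationError("sd_run must exceed sd_move")

    def replace(self, **overrides) -> "ThresholdSet":
        return replace(self, **overrides)


#: Calibration for preschoolers, children and adolescents.
CHILD = ThresholdSet(
    sd_move=0.1, theta_bike=22.5, sd_run=0.65, inc_sit=47.5, sd_still=0.13, back_lie=65.0
)
#: Original adult calibration, for comparison runs.
ADULT = ThresholdSet(
    sd_move=0.1, theta_bike=24.0, sd_run=0.72, inc_sit=45.0, sd_still=0.1, back_lie=65.0
)

PRESETS = {"child": CHILD, "adult": ADULT}


@dataclass(frozen=True)
class LabelSeries:
    """One activity label per second, starting at ``t0`` seconds."""

    labels: Tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        unknown = sorted(set(labels) - set(LABELS))
        if unknown:
            raise ValidationError(f"unknown labels {unknown}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SmoothingConfig:
    """Label-smoothing settings.

    ``mode`` is ``per_activity_median`` (binary median filter per activity,
    the original method), ``majority`` (sliding modal label) or ``none``.
    ``window_s`` must be odd so the window centres on a second.
    """

    mode: str = "per_activity_median"
    window_s: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("per_activity_median", "majority", "none"):
            raise ConfigurationError(f"unknown smoothing mode {self.mode!r}")
        if self.window_s < 1 or self.window_s % 2 == 0:
            raise ConfigurationError("window_s must be an odd positive integer")


def classify_frame(f: FeatureFrame, th: ThresholdSet) -> str:
    """Assign one activity label to a feature frame via the decision tree."""
    if f.sd_long > th.sd_move:  # dynamic branch
        if f.theta_deg > th.theta_bike:
            return "bike"
        return "run" if f.sd_long > th.sd_run else "walk"
    # stationary branch
    if f.inc_deg > th.inc_sit:
        return "sit"
    return "move" if f.sd_max > th.sd_still else "stand"


def classify_frames(
    frames: Sequence[FeatureFrame], th: ThresholdSet, t0: Optional[float] = None
) -> LabelSeries:
    """Frame-by-frame classification of a feature sequence (no smoothing)."""
    if t0 is None:
        t0 = frames[0].t if frames else 0.0
    return LabelSeries(tuple(classify_frame(f, th) for f in frames), t0=t0)


def _window_bounds(i: int, n: int, half: int) -> Tuple[int, int]:
    # shrunken windows at the edges
    return max(0, i - half), min(n, i + half + 1)


def per_activity_support(
    series: LabelSeries, window_s: int
) -> Dict[str, np.ndarray]:
    """Fraction of each label inside the (edge-shrunken) smoothing window."""
    n = len(series)
    half = window_s // 2
    arr = np.array(series.labels)
    support: Dict[str, np.ndarray] = {}
    for label in set(series.labels):
        ind = (arr == label).astype(float)
        out = np.empty(n)
        for i in range(n):
            lo, hi = _window_bounds(i, n, half)
            out[i] = ind[lo:hi].mean()
        support[label] = out
    return support


def smooth_labels(
    series: LabelSeries, cfg: SmoothingConfig, return_assignments: bool = False
):
    """Smooth a raw label stream.

    ``per_activity_median`` median-filters each activity's binary indicator
    stream (a label is asserted at a second when it holds a strict majority
    of its window); the possibly-overlapping assertions are then resolved by
    :func:`resolve_multilabel`.  ``majority`` replaces each second with the
    modal label of its window (ties keep the raw label when it is among the
    modes).  Edge windows shrink symmetrically.  With
    ``return_assignments=True`` the per-second asserted sets are returned
    alongside the series.
    """
    n = len(series)
    if cfg.mode == "none" or n == 0:
        return (series, [set((l,)) for l in series.labels]) if return_assignments else series

    half = cfg.window_s // 2
    arr = np.array(series.labels)

    if cfg.mode == "majority":
        out: List[str] = []
        for i in range(n):
            lo, hi = _window_bounds(i, n, half)
            window = arr[lo:hi]
            labels, counts = np.unique(window, return_counts=True)
            top = counts.max()
            modes = set(labels[counts == top])
            if arr[i] in modes:
                out.append(arr[i])
            else:
                out.append(next(l for l in _PRIORITY_ORDER + ("undefined",) if l in modes))
        smoothed = LabelSeries(tuple(out), t0=series.t0)
        if return_assignments:
            return smoothed, [set((l,)) for l in smoothed.labels]
        return smoothed

    # per_activity_median
    support = per_activity_support(series, cfg.window_s)
    assigned: List[Set[str]] = [set() for _ in range(n)]
    for label, frac in support.items():
        if label == "undefined":
            continue
        for i in range(n):
            lo, hi = _window_bounds(i, n, half)
            if frac[i] > 0.5:  # strict majority of ones in the window
                assigned[i].add(label)
    resolved = resolve_multilabel(assigned, support=support, t0=series.t0)
    if return_assignments:
        return resolved, assigned
    return resolved


def resolve_multilabel(
    assigned: Sequence[Set[str]],
    support: Optional[Dict[str, np.ndarray]] = None,
    t0: float = 0.0,
) -> LabelSeries:
    """Reduce per-second label sets to single labels by priority.

    Lying or sitting removes any other activity; biking beats locomotion;
    walking/running beat standing/moving.  When both walking and running
    survive, the one with the larger filtered support at that second wins,
    ties going to walking.  Empty sets become ``undefined``.
    """
    out: List[str] = []
    for i, labels in enumerate(assigned):
        if not labels:
            out.append("undefined")
            continue
        for group in _PRIORITY_GROUPS:
            hits = [l for l in group if l in labels]
            if not hits:
                continue
            if len(hits) == 1 or support is None:
                out.append(next(l for l in _PRIORITY_ORDER if l in hits))
            else:
                sup = {l: support[l][i] if l in support else 0.0 for l in hits}
                best = max(sup.values())
                out.append(next(l for l in _PRIORITY_ORDER if l in hits and sup[l] == best))
            break
        else:  # only 'undefined' members
            out.append("undefined")
    return LabelSeries(tuple(out), t0=t0)


def detect_lying(
    thigh: LabelSeries, trunk_features: Sequence[FeatureFrame], th: ThresholdSet
) -> LabelSeries:
    """Relabel sitting seconds as lying when the back is inclined > ``back_lie``.

    Requires a trunk/back sensor whose feature frames share the thigh's 1-s
    grid.  Only sitting seconds are eligible; every other label is kept.
    """
    if len(trunk_features) != len(thigh):
        raise AlignmentError(
            f"trunk features ({len(trunk_features)}) and thigh labels "
            f"({len(thigh)}) are not on the same 1-s grid"
        )
    out = [
        "lie" if (label == "sit" and tf.inc_deg > th.back_lie) else label
        for label, tf in zip(thigh.labels, trunk_features)
    ]
    return LabelSeries(tuple(out), t0=thigh.t0)


def write_labels(path, series: LabelSeries) -> None:
    """Write a label series as CSV with columns second_index,label."""
    import csv
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["second_index", "label"])
        for i, label in enumerate(series.labels):
            w.writerow([int(series.t0) + i, label])


def read_labels(path) -> LabelSeries:
    """Read a label series written by :func:`write_labels`."""
    import csv
    from pathlib import Path

    rows = list(csv.reader(Path(path).read_text(encoding="utf-8").splitlines()))
    if rows and rows[0] and rows[0][0] == "second_index":
        rows = rows[1:]
    if not rows:
        raise ValidationError(f"{path}: empty label file")
    t0 = float(rows[0][0])
    return LabelSeries(tuple(r[1] for r in rows), t0=t0)


def classify_recording(
    rec: TriaxialRecording,
    orientation: Optional[DeviceOrientation] = None,
    th: ThresholdSet = CHILD,
    cfg: SmoothingConfig = SmoothingConfig(),
    resample_method: str = "polyphase",
) -> LabelSeries:
    """Full pipeline: orient, resample to 30 Hz, extract features, classify,
    smooth and resolve.  Returns one label per second.

    Canonical-frame recordings may omit ``orientation``; raw device
    recordings require it.
    """
    if rec.frame == RAW_DEVICE:
        if orientation is None:
            raise ConfigurationError("raw device recording requires an orientation")
        rec = remap_to_canonical(rec, orientation)
    if rec.fs < WORKING_FS:
        raise ValidationError(
            f"recording rate {rec.fs:g} Hz is below the {WORKING_FS:g} Hz working rate"
        )
    if rec.fs > WORKING_FS:
        rec = resample(rec, WORKING_FS, method=resample_method)
    frames = compute_features(rec)
    raw = classify_frames(frames, th, t0=frames[0].t - 1.0)
    return smooth_labels(raw, cfg)
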