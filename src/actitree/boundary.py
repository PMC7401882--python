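"""Empirical recovery of decision boundaries by bisection.

The configured thresholds are not read back from the
:class:`~actitree.classify.ThresholdSet`; instead each node's boundary is
located by bisecting the relevant feature through the public classifier,
holding the other features deep inside a fixed region.  This verifies that
the implemented tree actually switches labels at the printed constants
(and is the natural audit for any custom threshold override).
"""

from __future__ import annotations

from typing import Callable, Dict

from .classify import CHILD, LabelSeries, ThresholdSet, classify_frame, detect_lying
from .features import FeatureFrame, compute_features
from .synthetic import gen_static


def bisect_flip(
    predicate: Callable[[float], bool],
    lo: float,
    hi: float,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> float:
    """Locate the flip point of a monotone boolean predicate on [lo, hi].

    ``predicate(lo)`` and ``predicate(hi)`` must differ; the returned value
    is within ``tol`` of the true switching point.
    """
    p_lo = predicate(lo)
    if predicate(hi) == p_lo:
        raise ValueError("predicate does not flip on the given interval")
    it = 0
    while hi - lo > tol and it < max_iter:
        mid = 0.5 * (lo + hi)
        if predicate(mid) == p_lo:
            lo = mid
        else:
            hi = mid
        it += 1
    return 0.5 * (lo + hi)


def _frame(sd_long=0.0, sd_ap=0.0, sd_lat=0.0, inc=0.0, theta=0.0) -> FeatureFrame:
    return FeatureFrame(
        t=0.0,
        sd_long=sd_long,
        sd_ap=sd_ap,
        sd_lat=sd_lat,
        sd_max=max(sd_long, sd_ap, sd_lat),
        inc_deg=inc,
        theta_deg=theta,
        mean_vec=(1.0, 0.0, 0.0),
    )


def movement_boundary(th: ThresholdSet = CHILD, tol: float = 1e-9) -> float:
    """Root node: sd_long (g) above which a low-angle frame leaves 'stand'."""
    return bisect_flip(
        lambda x: classify_frame(_frame(sd_long=x, inc=10.0, theta=0.0), th) != "stand",
        0.0, 0.5, tol=tol,
    )


def biking_boundary(th: ThresholdSet = CHILD, tol: float = 1e-9) -> float:
    """Dynamic branch: theta (deg) at which walking flips to biking at
    sd_long = 0.3 g."""
    return bisect_flip(
        lambda x: classify_frame(_frame(sd_long=0.3, theta=x), th) == "bike",
        0.0, 60.0, tol=tol,
    )


def running_boundary(th: ThresholdSet = CHILD, tol: float = 1e-9) -> float:
    """Dynamic branch: sd_long (g) at which walking flips to running."""
    return bisect_flip(
        lambda x: classify_frame(_frame(sd_long=x, theta=0.0), th) == "run",
        0.2, 1.5, tol=tol,
    )


def sitting_boundary(th: ThresholdSet = CHILD, tol: float = 1e-9) -> float:
    """Stationary branch: inc (deg) at which standing flips to sitting at
    sd_long = sd_max = 0.02 g."""
    return bisect_flip(
        lambda x: classify_frame(_frame(sd_long=0.02, sd_ap=0.02, inc=x), th) == "sit",
        0.0, 90.0, tol=tol,
    )


def moving_boundary(th: ThresholdSet = CHILD, tol: float = 1e-9) -> float:
    """Stationary branch: sd_max (g) at which standing flips to moving."""
    return bisect_flip(
        lambda x: classify_frame(
            _frame(sd_long=0.02, sd_lat=x, inc=10.0), th
        ) == "move",
        0.02, 0.5, tol=tol,
    )


def lying_boundary(th: ThresholdSet = CHILD, tol: float = 1e-6) -> float:
    """Back inclination (deg) above which a sitting second becomes lying.

    The trunk feature is produced through the real feature pipeline from a
    noiseless static trunk signal at the candidate back pitch.
    """
    thigh = LabelSeries(("sit",), t0=0.0)

    def relabels(pitch: float) -> bool:
        trunk = gen_static(pitch, 0.0, 2.0, fs=30.0, seed=0)
        frames = compute_features(trunk)[:1]
        return detect_lying(thigh, frames, th).labels[0] == "lie"

    return bisect_flip(relabels, 0.0, 90.0, tol=tol)


def node_boundaries(th: ThresholdSet = CHILD, tol: float = 1e-9) -> Dict[str, float]:
    """All six empirically recovered boundaries of a threshold set."""
    return {
        "sd_move": movement_boundary(th, tol),
        "theta_bike": biking_boundary(th, tol),
        "sd_run": running_boundary(th, tol),
        "inc_sit": sitting_boundary(th, tol),
        "sd_still": moving_boundary(th, tol),
        "back_lie": lying_boundary(th, max(tol, 1e-7)),
    }
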