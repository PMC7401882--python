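"""Per-window signal features for thigh-posture classification.

Four features drive the decision tree, each computed on a 2-s window with
50 % overlap so that one feature frame is emitted per second:

* ``sd_long`` — standard deviation of the longitudinal acceleration (g),
  the primary movement-intensity feature;
* ``sd_max`` — the maximum of the three per-axis standard deviations (g),
  separating standing still from shuffling;
* ``inc_deg`` — thigh inclination from vertical in degrees,
  ``arccos(m_long / ||m||)`` of the window-mean acceleration ``m``;
* ``theta_deg`` — sagittal forward/backward pitch in degrees,
  ``arcsin(m_ant / ||m||)``, forward positive; persistently elevated while
  pedalling, near zero on average during gait.

Standard deviations use the population (N) denominator.  Windows whose mean
acceleration magnitude falls below 0.1 g give unreliable angle estimates;
their angles are set to 0 and the frame is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import FrameError, TooShortError, ValidationError
from .io import CANONICAL, WORKING_FS, TriaxialRecording

#: Window length in seconds.
WINDOW_S = 2.0
#: Fractional overlap between consecutive windows.
OVERLAP = 0.5
#: Below this window-mean magnitude (g) the angles are considered undefined.
MIN_MEAN_NORM_G = 0.1


@dataclass(frozen=True)
class FeatureFrame:
    """Signal features of one analysis window, centred at time ``t`` (s)."""

    t: float
    sd_long: float
    sd_ap: float
    sd_lat: float
    sd_max: float
    inc_deg: float
    theta_deg: float
    mean_vec: tuple[float, float, float]
    undefined_angles: bool = False


def window_plan(
    n_samples: int,
    fs: float,
    win_s: float = WINDOW_S,
    overlap: float = OVERLAP,
) -> List[tuple[int, int]]:
    """Start/end sample indices of every full analysis window.

    Windows hold exactly ``win_s * fs`` samples and advance by
    ``win_s * fs * (1 - overlap)`` samples; a trailing partial window is
    discarded, so the count is ``floor((n - w) / h) + 1``.
    """
    w_f = win_s * fs
    h_f = win_s * fs * (1.0 - overlap)
    if abs(w_f - round(w_f)) > 1e-9 or abs(h_f - round(h_f)) > 1e-9:
        raise ValidationError(
            f"window ({w_f}) and hop ({h_f}) must be whole sample counts"
        )
    w, h = int(round(w_f)), int(round(h_f))
    if h < 1:
        raise ValidationError("hop must be at least one sample")
    if n_samples < w:
        raise TooShortError(
            f"recording of {n_samples} samples is shorter than one "
            f"{w}-sample window"
        )
    count = (n_samples - w) // h + 1
    return [(i * h, i * h + w) for i in range(count)]


def compute_features(
    rec: TriaxialRecording,
    win_s: float = WINDOW_S,
    overlap: float = OVERLAP,
) -> List[FeatureFrame]:
    """Compute one :class:`FeatureFrame` per analysis window.

    The recording must already be in the canonical anatomical frame; the
    geometry of the angle features is meaningless in the device frame.  At
    the default 30 Hz working rate with 2-s windows and 50 % overlap the
    frames are spaced exactly 1 s apart.
    """
    if rec.frame != CANONICAL:
        raise FrameError(
            "features require the canonical frame; call remap_to_canonical first"
        )
    plan = window_plan(rec.n_samples, rec.fs, win_s=win_s, overlap=overlap)
    frames: List[FeatureFrame] = []
    for start, end in plan:
        win = rec.samples[start:end]
        m = win.mean(axis=0)
        sd = win.std(axis=0, ddof=0)  # population SD over the window
        norm = float(np.linalg.norm(m))
        if norm < MIN_MEAN_NORM_G:
            inc = 0.0
            theta = 0.0
            undefined = True
        else:
            inc = float(np.degrees(np.arccos(np.clip(m[0] / norm, -1.0, 1.0))))
            theta = float(np.degrees(np.arcsin(np.clip(m[1] / norm, -1.0, 1.0))))
            undefined = False
        frames.append(
            FeatureFrame(
                t=(start + end) / 2.0 / rec.fs,
                sd_long=float(sd[0]),
                sd_ap=float(sd[1]),
                sd_lat=float(sd[2]),
                sd_max=float(sd.max()),
                inc_deg=inc,
                theta_deg=theta,
                mean_vec=(float(m[0]), float(m[1]), float(m[2])),
                undefined_angles=undefined,
            )
        )
    return frames


def features_to_frame(frames: Sequence[FeatureFrame]) -> pd.DataFrame:
    """Tabulate feature frames for export (columns in g and degrees)."""
    return pd.DataFrame(
        {
            "t_s": [f.t for f in frames],
            "sd_long_g": [f.sd_long for f in frames],
            "sd_ap_g": [f.sd_ap for f in frames],
            "sd_lat_g": [f.sd_lat for f in frames],
            "sd_max_g": [f.sd_max for f in frames],
            "inc_deg": [f.inc_deg for f in frames],
            "theta_deg": [f.theta_deg for f in frames],
            "flag_undefined": [f.undefined_angles for f in frames],
        }
    )


def working_rate_check(rec: TriaxialRecording) -> None:
    """Raise unless the recording is at the method's 30 Hz working rate."""
    if abs(rec.fs - WORKING_FS) > 1e-9:
        raise ValidationError(
            f"features are defined at {WORKING_FS:g} Hz; got {rec.fs:g} Hz "
            "(resample first or pass win_s/overlap explicitly)"
        )
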