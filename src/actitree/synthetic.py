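"""Kinematic synthetic-signal generator for pipeline verification.

Real child recordings are not distributable, so the pipeline is exercised
with synthetic thigh signals built from a simple kinematic model: the thigh
is a rigid segment whose sagittal pitch follows a prescribed trajectory,
gravity (1 g) is projected onto the canonical axes, and additive white
noise stands in for impacts and tissue artefact.  The generator's purpose
is to place each activity's windowed features in its characteristic region
of feature space — it does not attempt biomechanically faithful child
accelerometry, device jitter, or attachment slippage.

Three signal families cover the structured protocol:

* static postures (sitting, standing, lying) — constant pitch plus noise;
* locomotion (walking, running) — pendular pitch about vertical at a gait
  cadence, with impact noise calibrated so the realised longitudinal SD
  hits a target intensity;
* biking — pitch oscillating around an elevated saddle angle, giving a
  persistently forward-pitched thigh with moderate longitudinal SD.

All randomness flows from a single seed through ``numpy`` generators; no
global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .errors import CalibrationError, ValidationError
from .io import CANONICAL, ActivityLog, LogEntry, TriaxialRecording

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


#: Upper edge (Hz) of the synthetic noise band.  Impact/artefact energy is
#: kept below the 15 Hz Nyquist of the 30 Hz working rate so that the
#: anti-aliased downsample preserves the calibrated signal SDs.
NOISE_BAND_HZ = 12.0


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, sd: float, cutoff: float = NOISE_BAND_HZ
) -> np.ndarray:
    """Zero-mean noise of SD ``sd`` band-limited to [0, cutoff] Hz."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if cutoff < fs / 2 and n > 30:
        from scipy import signal as _sig

        sos = _sig.butter(4, cutoff, fs=fs, output="sos")
        white = _sig.sosfiltfilt(sos, white)
        white = white / white.std()
    return sd * white


def _project(pitch_rad: np.ndarray) -> np.ndarray:
    """Gravity projected onto (longitudinal, anterior, lateral) for a thigh
    pitched forward by ``pitch_rad`` in the sagittal plane."""
    return np.column_stack(
        [np.cos(pitch_rad), np.sin(pitch_rad), np.zeros_like(pitch_rad)]
    )


def gen_static(
    pitch_deg: float,
    noise_sd: float,
    duration: float,
    fs: float = 100.0,
    seed: RngLike = 0,
    lateral_noise_sd: float = 0.0,
) -> TriaxialRecording:
    """Static posture: constant sagittal pitch plus per-axis white noise.

    ``pitch_deg`` is the thigh angle from vertical (0 upright standing,
    ~85 sitting, >90 reclined).  ``lateral_noise_sd`` adds extra lateral
    noise to emulate shuffling/fidgeting in an upright posture, which
    raises ``sd_max`` without raising ``sd_long``.
    """
    if not 0 <= pitch_deg <= 180:
        raise ValidationError("pitch_deg must be within [0, 180]")
    rng = _rng(seed)
    n = int(round(duration * fs))
    p = np.radians(pitch_deg)
    base = _project(np.full(n, p))
    samples = base + np.column_stack(
        [_band_noise(rng, n, fs, noise_sd) for _ in range(3)]
    )
    if lateral_noise_sd > 0:
        samples[:, 2] += _band_noise(rng, n, fs, lateral_noise_sd)
    return TriaxialRecording(fs=fs, samples=samples, frame=CANONICAL)


def gen_locomotion(
    swing_amp_deg: float,
    cadence: float,
    target_sd_long: float,
    duration: float,
    fs: float = 100.0,
    seed: RngLike = 0,
    cross_axis_ratio: float = 0.6,
    lean_deg: float = 0.0,
) -> TriaxialRecording:
    """Gait: pendular thigh pitch about vertical plus calibrated impact noise.

    The pitch swings sinusoidally (``swing_amp_deg`` degrees at ``cadence``
    Hz) around a forward lean of ``lean_deg``; gravity projection alone
    yields little longitudinal variance, so zero-mean impact noise is added
    to the longitudinal axis, scaled so the realised longitudinal SD lands
    within 10 % of ``target_sd_long``.  Cross-axis noise at
    ``cross_axis_ratio`` of that scale keeps the other SDs realistic.  The
    mean forward pitch over a stride stays near the (small) lean, well
    below the pedalling angle — the signature separating gait from biking.
    """
    if target_sd_long <= 0.1:
        raise ValidationError("target_sd_long must exceed 0.1 g (dynamic branch)")
    if swing_amp_deg <= 0 or cadence <= 0:
        raise CalibrationError(
            "degenerate gait: swing amplitude and cadence must be positive"
        )
    rng = _rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phi = np.radians(lean_deg) + np.radians(swing_amp_deg) * np.sin(
        2 * np.pi * cadence * t
    )
    base = _project(phi)
    base_sd = float(base[:, 0].std())
    if base_sd > 1.1 * target_sd_long:
        raise CalibrationError(
            f"gravity projection alone gives sd_long {base_sd:.3f} g, "
            f"beyond the {target_sd_long:.3f} g target"
        )
    extra_var = max(target_sd_long**2 - base_sd**2, 0.0)
    noise_sd = float(np.sqrt(extra_var))
    samples = base.copy()
    samples[:, 0] += _band_noise(rng, n, fs, noise_sd)
    samples[:, 1] += _band_noise(rng, n, fs, cross_axis_ratio * noise_sd)
    samples[:, 2] += _band_noise(rng, n, fs, cross_axis_ratio * noise_sd)
    return TriaxialRecording(fs=fs, samples=samples, frame=CANONICAL)


def gen_biking(
    saddle_pitch_deg: float,
    cadence: float,
    duration: float,
    fs: float = 100.0,
    seed: RngLike = 0,
    swing_amp_deg: float = 15.0,
    noise_sd: float = 0.15,
) -> TriaxialRecording:
    """Pedalling: pitch oscillating around an elevated saddle angle.

    The thigh stays pitched forward by ``saddle_pitch_deg`` on average while
    the crank cycle adds a ±``swing_amp_deg`` oscillation; pedalling/road
    noise (``noise_sd``) keeps the longitudinal SD above the movement
    threshold.  A shallow saddle pitch (as on a pedal-less running bike)
    produces gait-like windows — forward angle below the biking threshold —
    and is classified as locomotion, not biking.
    """
    if saddle_pitch_deg <= 0:
        raise ValidationError("saddle_pitch_deg must be positive")
    rng = _rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phi = np.radians(saddle_pitch_deg + swing_amp_deg * np.sin(2 * np.pi * cadence * t))
    samples = _project(phi) + np.column_stack(
        [_band_noise(rng, n, fs, noise_sd) for _ in range(3)]
    )
    return TriaxialRecording(fs=fs, samples=samples, frame=CANONICAL)


@dataclass(frozen=True)
class ActivityScenario:
    """One protocol activity and the kinematic parameters that realise it.

    ``kind`` selects the signal family; unused parameters are ignored
    (e.g. ``cadence`` for a static posture).  ``trunk_pitch_deg`` drives the
    optional back-sensor signal (static by construction).
    """

    label: str
    duration: float
    kind: str = "static"  # static | locomotion | biking
    pitch_deg: float = 0.0  # thigh pitch (static) or saddle pitch (biking)
    swing_amp_deg: float = 0.0
    cadence: float = 0.0
    noise_sd: float = 0.02
    lateral_noise_sd: float = 0.0
    target_sd_long: Optional[float] = None
    trunk_pitch_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("scenario duration must be positive")
        if self.kind not in ("static", "locomotion", "biking"):
            raise ValidationError(f"unknown scenario kind {self.kind!r}")
        if min(self.cadence, self.noise_sd, self.lateral_noise_sd) < 0:
            raise ValidationError("cadence and noise parameters must be >= 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered list of scenarios with quiet-standing gaps in between."""

    scenarios: Tuple[ActivityScenario, ...]
    gap_s: float = 5.0
    seed: int = 0
    fs: float = 100.0
    with_trunk: bool = False

    @property
    def total_duration(self) -> float:
        gaps = self.gap_s * max(len(self.scenarios) - 1, 0)
        return sum(s.duration for s in self.scenarios) + gaps


def _gen_scenario(sc: ActivityScenario, fs: float, rng: np.random.Generator):
    if sc.kind == "static":
        return gen_static(
            sc.pitch_deg, sc.noise_sd, sc.duration, fs=fs, seed=rng,
            lateral_noise_sd=sc.lateral_noise_sd,
        )
    if sc.kind == "locomotion":
        if sc.target_sd_long is None:
            raise ValidationError(f"scenario {sc.label!r}: locomotion needs target_sd_long")
        return gen_locomotion(
            sc.swing_amp_deg, sc.cadence, sc.target_sd_long, sc.duration, fs=fs, seed=rng
        )
    return gen_biking(
        sc.pitch_deg, sc.cadence, sc.duration, fs=fs, seed=rng,
        swing_amp_deg=sc.swing_amp_deg or 15.0, noise_sd=sc.noise_sd,
    )


def gen_protocol(
    spec: ProtocolSpec,
) -> Tuple[TriaxialRecording, ActivityLog, Optional[TriaxialRecording]]:
    """Generate the full protocol recording, its ground-truth log, and an
    optional time-aligned trunk recording.

    Scenarios are concatenated in order with quiet-standing gaps; every log
    boundary coincides with a scenario boundary to the sample.  Output is
    deterministic for a given ``spec.seed``.
    """
    if not spec.scenarios:
        raise ValidationError("protocol has no scenarios")
    streams = np.random.SeedSequence(spec.seed).spawn(2 * len(spec.scenarios))
    chunks: List[np.ndarray] = []
    trunk_chunks: List[np.ndarray] = []
    entries: List[LogEntry] = []
    t = 0.0
    for i, sc in enumerate(spec.scenarios):
        rng = np.random.default_rng(streams[2 * i])
        rec = _gen_scenario(sc, spec.fs, rng)
        chunks.append(rec.samples)
        entries.append(LogEntry(label=sc.label, start=t, end=t + sc.duration))
        if spec.with_trunk:
            trunk = gen_static(
                sc.trunk_pitch_deg, 0.02, sc.duration, fs=spec.fs,
                seed=np.random.default_rng(streams[2 * i + 1]),
            )
            trunk_chunks.append(trunk.samples)
        t += sc.duration
        if spec.gap_s > 0 and i < len(spec.scenarios) - 1:
            gap_rng = np.random.default_rng(
                np.random.SeedSequence((spec.seed, 10_000 + i))
            )
            gap = gen_static(5.0, 0.02, spec.gap_s, fs=spec.fs, seed=gap_rng)
            chunks.append(gap.samples)
            if spec.with_trunk:
                trunk_chunks.append(
                    gen_static(5.0, 0.02, spec.gap_s, fs=spec.fs, seed=gap_rng).samples
                )
            t += spec.gap_s
    rec = TriaxialRecording(fs=spec.fs, samples=np.vstack(chunks), frame=CANONICAL)
    trunk_rec = (
        TriaxialRecording(fs=spec.fs, samples=np.vstack(trunk_chunks), frame=CANONICAL)
        if spec.with_trunk
        else None
    )
    return rec, ActivityLog(entries=tuple(entries)), trunk_rec


def table_protocol(
    seed: int = 0, fs: float = 100.0, with_trunk: bool = False
) -> ProtocolSpec:
    """Bundled preset emulating the structured school/preschool protocol:
    sitting, sitting while playing, standing while playing, slow and brisk
    walking, running, a playground-style mixture, biking, and sitting again.

    Durations are desk-scale (90–120 s per activity) rather than the full
    field-protocol lengths; intensities are chosen so each activity's
    features sit well inside its decision region under the child preset.
    """
    scenarios = (
        ActivityScenario("sit", 90, "static", pitch_deg=85, noise_sd=0.02,
                         trunk_pitch_deg=20),
        ActivityScenario("sit", 90, "static", pitch_deg=80, noise_sd=0.04,
                         trunk_pitch_deg=25),
        ActivityScenario("stand", 90, "static", pitch_deg=8, noise_sd=0.03,
                         trunk_pitch_deg=5),
        ActivityScenario("walk", 120, "locomotion", swing_amp_deg=15, cadence=1.5,
                         target_sd_long=0.3, trunk_pitch_deg=8),
        ActivityScenario("walk", 120, "locomotion", swing_amp_deg=20, cadence=1.9,
                         target_sd_long=0.45, trunk_pitch_deg=8),
        ActivityScenario("run", 120, "locomotion", swing_amp_deg=25, cadence=2.5,
                         target_sd_long=0.9, trunk_pitch_deg=12),
        ActivityScenario("playground", 120, "locomotion", swing_amp_deg=20,
                         cadence=1.8, target_sd_long=0.5, trunk_pitch_deg=10),
        ActivityScenario("bike", 120, "biking", pitch_deg=45, cadence=1.5,
                         swing_amp_deg=15, noise_sd=0.15, trunk_pitch_deg=15),
        ActivityScenario("sit", 90, "static", pitch_deg=85, noise_sd=0.02,
                         trunk_pitch_deg=20),
    )
    return ProtocolSpec(
        scenarios=scenarios, gap_s=5.0, seed=seed, fs=fs, with_trunk=with_trunk
    )


def development_corpus(
    seed: int = 0,
    n_subjects: int = 16,
    duration: float = 30.0,
    fs: float = 30.0,
) -> Dict[str, List["FeatureFrame"]]:
    """Pooled per-activity feature frames emulating a development group.

    Each virtual subject performs every activity once with self-selected
    parameters drawn from child-plausible ranges (sitting pitch 55–110 deg
    with fidget noise, standing 0–40 deg, standing-while-playing with
    lateral shuffle, slow-to-brisk walking at longitudinal SD 0.16–0.55 g,
    running at 0.7–1.2 g, pedalling at saddle pitch 28–60 deg).  Pooling
    across subjects yields broad, overlapping class-conditional feature
    distributions whose density crossings fall near the calibrated
    thresholds — the geometry the visual threshold choice was based on.

    Returns a mapping from activity name (``sit``, ``stand``,
    ``stand_play``, ``walk``, ``run``, ``bike``) to that activity's pooled
    feature frames.  Signals are generated directly at the 30 Hz working
    rate.
    """
    from .features import compute_features

    ss = np.random.SeedSequence(seed)
    out: Dict[str, List] = {}

    def add(act: str, rec: TriaxialRecording) -> None:
        out.setdefault(act, []).extend(compute_features(rec))

    for _ in range(n_subjects):
        r = np.random.default_rng(ss.spawn(1)[0])
        add("sit", gen_static(float(r.uniform(55, 110)), float(r.uniform(0.02, 0.09)),
                              duration, fs=fs, seed=r))
        add("stand", gen_static(float(r.uniform(0, 40)), float(r.uniform(0.02, 0.05)),
                                duration, fs=fs, seed=r))
        add("stand_play", gen_static(float(r.uniform(0, 25)), 0.04, duration, fs=fs,
                                     seed=r, lateral_noise_sd=float(r.uniform(0.05, 0.11))))
        add("walk", gen_locomotion(float(r.uniform(8, 16)), float(r.uniform(1.4, 2.0)),
                                   float(r.uniform(0.16, 0.55)), duration, fs=fs, seed=r,
                                   lean_deg=float(r.uniform(0, 12))))
        add("run", gen_locomotion(float(r.uniform(20, 30)), float(r.uniform(2.2, 3.0)),
                                  float(r.uniform(0.7, 1.2)), duration, fs=fs, seed=r,
                                  lean_deg=float(r.uniform(0, 12))))
        add("bike", gen_biking(float(r.uniform(28, 60)), float(r.uniform(1.0, 2.0)),
                               duration, fs=fs, seed=r, swing_amp_deg=10.0))
    return out
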