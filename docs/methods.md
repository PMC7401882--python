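# Methods

## The classification model

`actitree` implements posture and activity-type classification from a single
thigh-worn triaxial accelerometer for preschoolers, children and
adolescents. The method assumes the sensor is fixed to the anterior thigh,
so that in quiet upright standing the longitudinal axis reads about +1 g,
and that the device's placement is declared, letting a signed axis
permutation map raw device axes onto a canonical anatomical frame
(longitudinal toward the knee, anterior, lateral).

Raw data (typically 100 Hz, ±8 g) is resampled to a 30 Hz working rate.
Four features are computed on 2-s windows with 50 % overlap, giving one
feature frame — and hence one classified second — per second:

* `SD_x` (`sd_long`): within-window standard deviation of the longitudinal
  acceleration (g); the movement-intensity feature.
* `SD_max` (`sd_max`): maximum of the three per-axis SDs (g); separates
  standing still from shuffling.
* `Inc` (`inc_deg`): thigh inclination from vertical,
  `arccos(m_long/‖m‖)` of the window-mean acceleration `m`, in degrees.
* `Θ` (`theta_deg`): sagittal forward/backward angle,
  `arcsin(m_ant/‖m‖)`, forward positive, in degrees.

A five-node decision tree assigns one of six labels per second:

```
sd_long > sd_move ?
├─ yes (dynamic):   theta > theta_bike ? bike
│                   : sd_long > sd_run ? run : walk
└─ no (stationary): inc > inc_sit ? sit
                    : sd_max > sd_still ? move : stand
```

Two immutable presets are shipped (units g / degrees):

| node        | child | adult |
|-------------|-------|-------|
| `sd_move`   | 0.10  | 0.10  |
| `theta_bike`| 22.5  | 24.0  |
| `sd_run`    | 0.65  | 0.72  |
| `inc_sit`   | 47.5  | 45.0  |
| `sd_still`  | 0.13  | 0.10  |
| `back_lie`  | 65.0  | 65.0  |

Every condition is a strict `>`; equality takes the false branch. This
single convention makes the decision boundaries well-defined, so a
bisection on any feature recovers the configured constant to arbitrary
precision (the basis of the boundary audit in `actitree.boundary`).

The raw per-second stream is then smoothed. The default mode filters each
activity's binary indicator stream with a sliding median (window 5 s,
configurable, odd; a label is asserted where it holds a strict majority;
edge windows shrink). Because several activities can be asserted for one
second, overlaps are resolved by priority: lying/sitting remove everything
else; biking beats locomotion; walking/running beat standing/moving. When
walking and running both survive, the one with the larger filtered support
wins, ties going to walking. Seconds asserted by no activity are labelled
`undefined` rather than inheriting a neighbour — they are rare (transition
edges) and auditable downstream. A `majority` mode (sliding modal label)
and `none` are also available.

With an optional trunk/back sensor on the same 1-s grid, sitting seconds
whose trunk inclination exceeds 65° are relabelled lying. Single-sensor
runs never emit `lie`. Stair-walking detection, bout aggregation and
energy-expenditure estimation are out of scope.

### Angle conventions and degenerate windows

The angle formulas are the package's own construction (the geometry is
standard, but several conventions would be consistent with the thresholds):
`Inc` is the angle between the window-mean acceleration and the
longitudinal axis, and `Θ` is the signed arcsine of the normalised anterior
component. This reproduces the expected geometry — standing Inc ≈ 0,
sitting Inc ≈ 90, pedalling Θ persistently above 22.5°, gait Θ near zero —
and matches the signs of the printed thresholds. Windows whose mean
acceleration magnitude falls below 0.1 g (free-fall-like content) have
unreliable angles; they carry angle 0 for classification but are flagged in
the feature export. SDs use the population (N) denominator over the
60-sample window; the difference from N−1 is under 1 %.

### Resampling

100→30 Hz is a non-integer ratio; the default is anti-aliased polyphase
rational resampling (`scipy.signal.resample_poly`, 3/10). A `naive`
nearest-index decimation mode without anti-aliasing is provided for
replicating pipelines that decimated directly. Upsampling is rejected.

## Evaluation machinery

Predictions are scored second-by-second against a timestamped activity
log: a second is paired with its ground-truth activity when it lies wholly
inside a logged interval (protocol gaps and transitions are excluded by
construction), optionally discarding a lead-in (e.g. 60 s) from each
interval. Per-activity one-vs-rest sensitivity and specificity are
tabulated; `undefined` predictions count as negatives for every activity,
costing sensitivity but never specificity (configurable). Complex
activities (ball games, playground circuits) are summarised by the
composition of predicted labels inside their intervals.

For threshold exploration, class-conditional feature values pooled across
recordings are smoothed with a Gaussian KDE (Scott's rule-of-thumb
bandwidth by default) and the crossing points between a class pair's
densities are reported as candidate thresholds. Candidates are never
applied automatically: the shipped presets reflect a visual choice
informed by such curves together with the adult constants, and automated
criteria (ROC and similar) are known to land far from them.
`split_subjects` provides the stratified half-split (development gets the
extra subject on odd counts) used to separate calibration from validation.

## The synthetic-signal generator

Real child recordings are not distributable, so verification uses a
kinematic simulator: the thigh is a rigid segment with a prescribed
sagittal pitch trajectory; gravity (1 g) is projected onto the canonical
axes; additive zero-mean noise stands in for impacts and tissue artefact.
Noise is band-limited to 12 Hz (4th-order zero-phase Butterworth) so the
anti-aliased downsample to 30 Hz preserves calibrated signal SDs.

* **Static postures** — constant pitch plus noise; optional extra lateral
  noise emulates shuffling (raising `sd_max` but not `sd_long`).
* **Locomotion** — sinusoidal pitch swing at a gait cadence around a small
  forward lean, with longitudinal impact noise solved so the realised
  `sd_long` lands within 10 % of a target intensity (cross-axis noise at
  0.6× that scale). Stride-mean pitch stays near the lean, so `Θ` stays
  far below the biking threshold.
* **Biking** — pitch oscillating around an elevated saddle angle; a
  shallow saddle angle (a pedal-less running bike) produces gait-like
  windows that classify as walking/running, reproducing the known
  confusion for that activity.

`table_protocol` bundles a structured protocol emulation (sitting, sitting
at play, standing at play, slow and brisk walking, running, a
playground-style mixture, biking, sitting) with quiet-standing gaps.
Durations are 90–120 s per activity — enough for several hundred interior
seconds per class while the whole suite runs in seconds. All randomness
descends from a single seed via `numpy.random.SeedSequence`; no global
state is touched, and identical seeds give bit-identical recordings.

`development_corpus` emulates a development group: each virtual subject
performs every activity with self-selected parameters drawn from
child-plausible ranges (sitting pitch 55–110° with fidget noise up to
0.09 g, standing 0–40°, lateral shuffle 0.05–0.11 g, walking at
longitudinal SD 0.16–0.55 g with 0–12° lean, running at 0.7–1.2 g,
pedalling at saddle pitch 28–60°). Pooling across subjects yields broad,
overlapping class-conditional distributions whose KDE crossings fall
within 20 % of the calibrated thresholds — the geometry the visual
threshold choice was based on. Narrow single-scenario classes do not have
this property: their crossings collapse toward the tighter class.

What the simulator does **not** capture: genuine gait harmonics and
double-support timing, non-sagittal thigh motion, fast free-living activity
transitions, basketball/swing dynamics, device jitter, mounting slippage
and temperature drift. Passing tests therefore demonstrate that the
pipeline implements the method's rules and recovers its constants and its
qualitative behaviour — not field accuracy on real children, which can
only be established against real annotated recordings.

## Numerical choices and edge cases

* Windows are aligned to sample 0; the count is `floor((N−W)/H)+1` and a
  trailing partial window is discarded. Recordings shorter than one window
  are rejected.
* Threshold equality takes the false branch everywhere (see above).
* Smoothing edge windows shrink; binary assertion needs a strict majority,
  so even-length edge windows with a tie do not assert.
* `resolve_multilabel` is order-independent; ties inside a priority group
  break by a fixed order (lie, sit, bike, walk, run, stand, move).
* Recording CSVs round-trip bit-exactly (floats written with `repr`).
* KDE crossing candidates are linear interpolations of the density
  difference's sign changes; a zero-variance class is rejected with a
  pointer to histogram inspection.
* The lead-in trim drops entries whose remaining duration is non-positive;
  an empty log is a legal result.

## Known limitations

Lying detection requires a second (trunk) sensor and its accuracy is not
validated here. The `Θ`-based biking rule fails by design on pedal-less
running bikes. Thresholds are calibrated for children when using the
`child` preset; free-living performance with frequent transitions is
expected to be lower than structured-protocol figures. The simulator's
limitations are listed above.
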