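# Methods

## Problem setting

Collar tags on dairy cows broadcast Bluetooth Low Energy advertisements at
5 Hz; fixed receiving stations mounted 3–5 m up on barn structures record
the received signal strength (RSS, dB) of every packet they hear.  The task
is to recover each cow's position over time from these noisy RSS streams,
at the accuracy scale useful for behaviour monitoring (metres, not
centimetres).  `barntrack` implements the full processing chain and a
synthetic barn/telemetry generator so every stage can be verified without
hardware.

## Signal model

RSS is modelled with the standard log-distance path-loss form

    RSS(D) = −10·n·log10(D) + A0

with path-loss exponent `n` and 1 m reference level `A0` (dB).  The pooled
open-space calibration shipped as the system default is `n = 0.84`,
`A0 = −48.77 dB`.  The exponent is far below the free-space value 2 — a
consequence of ground reflection and antenna pattern at the mounting
heights — and is used as-is; its practical effect is a very flat RSS–range
curve (≈ 13 dB across a 40 m barn), which is the root cause of the method's
metre-scale (not centimetre-scale) accuracy.  The base of the logarithm is
10, the standard convention for this model.  Fitting is ordinary least
squares of RSS on `−10·log10(D)` with intercept; the reported coefficient
uncertainties are OLS standard errors.

Real devices deviate from the pooled curve.  The generator reproduces the
measured deviation structure as

    RSS = model(D) + tag_offset + station_offset + orientation + ε

* `tag_offset` — one draw per tag, Gaussian, STD 2.7 dB (device/antenna
  and mounting differences between tags);
* `station_offset` — one draw per station, Gaussian, STD 4.14 dB;
* `orientation` — `(amp/2)·cos(heading − bearing-to-station)`, a smooth
  single-harmonic stand-in for the empirical orientation pattern, with
  peak-to-peak amplitude 6 dB in the barn regime (≈ 17 dB in open space);
  the heading follows the walking direction while moving and is redrawn
  uniformly at each rest;
* `ε` — per-sample Gaussian noise, STD 4 dB (the in-barn RSS distribution
  is close to Gaussian).

Offsets are constant for a whole recording — the worst case for any method
that uses absolute signal levels, and precisely the nuisance the shifted
error function targets.

## Filtering and folding

Raw streams are smoothed per (tag, station) with a centred time-window
moving mean or median, or a constant-velocity Kalman filter on the RSS
level (state `[rss, slope]`, `F = [[1, Δt], [0, 1]]`, `H = [1, 0]`,
`Q = q·I`, `R = 1`, `Δt = 0.2 s`; initialised at the first observation with
identity covariance).  Centred (not trailing) windows are used because the
processing is offline, which halves the lag bias; windows truncate at
stream edges.  The pipeline default is the mean filter with a 10 s window —
filter choice has little effect downstream because the Viterbi stage
absorbs the residual jitter.  Filtering runs at 5 Hz first; the streams are
then folded into aligned, non-overlapping 5 s windows (per-station mean),
the time step of the trajectory model.  The fold origin is the batch's
first timestamp rounded down to a whole interval.  Stations with no sample
in a window are simply absent from that window's heard-set.

## Localization

The barn floor is discretised into mapping points on a regular grid
(default 1 m; 0.5 m for the small waiting yard), and the model RSS of every
point–station pair is precomputed into a lookup table from 3-D distances
with the tag at 1.5 m collar height (distances clamped below at 0.1 m to
avoid the log singularity).  For a window with heard-station set S the
localization error at point k is

    Err_k = Σ_{i∈S} (RSS_mes,i − N_mes − (RSS_map[k,i] − N_pm,k))²,

with `N_mes` the mean measured RSS over S and `N_pm,k` the mean model RSS
over the *same* S at point k.  Subtracting both means compares relative
signal patterns, cancelling any constant common offset exactly; evaluating
`N_pm,k` over the heard subset (rather than all stations) is what makes
this invariance exact under partial reception.  The unshifted variant
(absolute levels) is available behind a flag for comparison.  Windows heard
by fewer than 3 stations are underdetermined in 2-D and contribute no RSS
evidence.

Point probabilities are reciprocal errors, `P_k ∝ 1/max(Err_k, 1e-9)`,
normalised per window (normalisation does not affect the decoded path).
Movement between windows is a Markov chain over mapping points: staying has
unnormalised weight 1; a hop to a point within 3 m whose straight passage
crosses no obstacle has weight `1/(1 + dist)`; everything else is 0; rows
are then normalised.  Obstacles are 2-D floor-plane structures: open
polylines block passages, closed polygons additionally exclude the grid
points they cover; a passage that merely touches an obstacle counts as
blocked (conservative).  The most probable trajectory is decoded with the
Viterbi algorithm in the log domain.  Structural zeros of the transition
matrix are kept at log 0 = −inf rather than floored, so a decoded track
provably never crosses a wall or exceeds the step limit; emission
probabilities are floored at 1e-300 to avoid underflow on day-long tracks.
Ties break toward the lowest point index everywhere, making every decode
bit-reproducible.

## Synthetic trajectories and references

Cow movement is simulated as a Markov walk on the mapping points with stay
probability 0.95 per 5 s step (cows walk less than ~5% of the time); the
move mass is spread over reachable neighbours with the same `1/(1+dist)`
weighting as the decoder.  The tag changes grid position exactly at window
boundaries — no within-window interpolation — so a noise-free simulation
decodes to the true point in every window, giving a sharp exact-model
consistency check.  `walk_speed` in `MotionSpec` is nominal (heading
semantics only).  Reference events mimic how ground truth is registered in
a real barn: a point dwelled for at least 5 s becomes one event.
Evaluation matches each event to the decoded point holding the majority of
the 5 s windows inside the event interval and reports the plane Euclidean
distance; summaries use the sample STD (n−1) convention, and the
per-cow statistics pool all event errors.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen once as realistic small
versions of the study conditions: the packaged synthetic barn (9.8 × 39 m,
1 m grid, ≈ 440 points, 10 stations ≈ 10 m apart); range-experiment
recovery over 50 simulated campaigns of 15 distances × 600 samples; the
shifted-vs-unshifted comparison over 20 paired herd simulations of 12 tags
× 1000 s (200 simulated minutes per seed, the herd size of the full-barn
accuracy experiment); and the station-density comparison between that barn
and a 4 × 5 m waiting-yard arrangement (0.5 m grid, 7 stations ≈ 2 m
apart) over 20 seeds of 3000 s each.

## Design choices and numerical conventions

* Single pooled propagation model for all devices; per-device calibrated
  models were deliberately rejected as impractical for commercial barns.
* Row-wise transition-matrix normalisation (rows are outgoing-probability
  distributions).
* Uniform initial state distribution for the decoder.
* Grid indices are row-major and deterministic for a given configuration.
* A station coincident with a mapping point is clamped to 0.1 m range.
* RSS values are treated as dB on the scale the stations report; no unit
  conversion is performed.

## Known limitations

* The generator uses constant device offsets and a single-harmonic
  orientation pattern; real deviations fluctuate with posture, occlusion
  by the cow's body, and multipath, and are not independent across
  stations.  Passing the synthetic checks therefore demonstrates
  correctness of the pipeline and the direction of the method's benefits,
  not the absolute accuracy obtainable in a specific barn.
* Because rows of the transition matrix are normalised, boundary and
  corner points (fewer neighbours) get a higher self-transition
  probability than interior points.  When emissions are nearly flat —
  heavy offset noise, distant stations — the decoded path is drawn toward
  such points.  This is a property of the published transition rules, not
  of the implementation; it is visible in synthetic occupancy maps as
  excess mass near walls.
* No per-BLE-channel treatment, no adaptive Kalman filter, no
  orientation-as-variable fitting and no 3-D obstacle modelling.
* The absolute error levels measured on the synthetic barn (≈ 3–10 m
  depending on noise structure and station density) are produced by the
  simulation conditions above; they are not a re-measurement of any real
  herd.
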