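# barntrack

Indoor localization of dairy cows from Bluetooth Low Energy received
signal strength (RSS).  Collar tags advertise at 5 Hz; cheap receiving
stations on the barn structure log the RSS of every packet.  `barntrack`
turns those logs into cow trajectories, occupancy maps and zone-time
budgets — the inputs for behaviour monitoring (queues at the milking
robot, feeding time, preferred lying places) at metre-scale accuracy.

## Method

* **Propagation model** — log-distance path loss,
  `RSS(D) = −10·n·log10(D) + A0`, fitted by OLS; the pooled default is
  `n = 0.84`, `A0 = −48.77 dB`.
* **Filtering** — per-(tag, station) smoothing (moving mean/median or a
  constant-velocity Kalman filter), then folding into 5 s observation
  windows by per-station averaging.
* **Grid localization** — the barn is discretised into mapping points
  `(x_k, y_k)` (~1 m pitch) with a precomputed lookup table
  `RSS_map[k, i]` of model RSS per point and station.  Each window is
  scored at every point with the shift-invariant error

  `Err_k = Σ_i (RSS_mes,i − N_mes − (RSS_map[k,i] − N_pm,k))²`,

  where the means `N_mes`, `N_pm,k` are taken over the stations actually
  heard — constant per-device RSS offsets cancel exactly.
* **Trajectory smoothing** — a hidden Markov model over mapping points:
  emission `P_k ∝ 1/Err_k`, transitions limited to 3 m per step, zeroed
  across obstacles and weighted `1/(1+dist)`; the track is the Viterbi
  path, so it can never jump across a wall.
* **Simulator** — synthetic barns, dwell-dominated cow movement and noisy
  RSS with the measured variability structure (per-tag offsets 2.7 dB,
  per-station offsets 4.14 dB, ~6 dB orientation pattern, 4 dB sample
  noise), so the whole chain is testable without hardware.

See `docs/methods.md` for the full model description and numerical
conventions.

## Worked example

Simulate two cows for half an hour in the packaged synthetic barn, decode
their tracks, and score them against the simulated ground-truth events:

```sh
python -c "from barntrack.io import synthetic_barn, write_map_config; \
           write_map_config(synthetic_barn(), 'barn.yaml')"
barntrack simulate --map barn.yaml --cows 2 --hours 0.5 --seed 1 \
          --out-rss rss.csv --out-ref ref.csv
barntrack localize --map barn.yaml --rss rss.csv --out track.csv
barntrack evaluate --track track.csv --ref ref.csv --map barn.yaml \
          --report report.json
```

which prints

```
wrote 180000 RSS records for 2 tag(s) to rss.csv
decoded 2 track(s) -> track.csv
mean error 3.61 ± 1.92 m over 35 events -> report.json
```

`3.61 ± 1.92 m` is the pooled mean ± sample STD of the per-event
localization errors (Euclidean distance between the majority decoded
point of each dwell event and its true location); `report.json` also
holds per-cow statistics, the cumulative error curve and the zone-time
distribution.  Fitting the propagation model to a simulated open-space
range experiment:

```sh
barntrack fit-propagation --rss range.csv
# n = 0.860 ± 0.013, A0 = -48.61 ± 0.113 dB, R² = 0.330
```

The library mirrors scikit-learn conventions where the operations are
estimator-shaped: `PathLossRegressor` (fit/predict for the path-loss
curve) and `GridLocalizer` (fit precomputes the lookup table and
transition matrix, predict decodes tracks from a raw log), with
`get_params`/`set_params` and trailing-underscore fitted attributes.

```python
from barntrack import GridLocalizer
from barntrack.io import synthetic_barn, read_rss_log

barn = synthetic_barn()
tracks = GridLocalizer(barn_map=barn).fit().predict(read_rss_log("rss.csv"))
```

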