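# tgpmove

Continuous-time animal movement inference from GPS telemetry with **treed
Gaussian processes** (TGPs): fit a Bayesian treed GP independently to each
projected coordinate of a telemetry track, draw posterior predictive
trajectories at any temporal resolution Δt, and transform those samples
into movement descriptors — displacement, turn angle, residence time,
contact probability — with credible intervals at the individual and
population level.

It is aimed at movement ecologists and wildlife managers who have
irregular GPS fixes (every 0.5–2 h, with gaps and dropped fixes) and want
statistically comparable movement summaries without building a bespoke
movement model.

## The model

Telemetry fixes are two coordinate series, easting `y1(t)` and northing
`y2(t)` in projected meters. Each series gets an independent treed GP on
time: a Bayesian CART partition of the study period into intervals, with a
stationary GP in each interval,

    y | β, σ² ~ N(Fβ, σ²(C + g I)),   C_ij = exp(−|t_i − t_j|^p / d),

where `F = [1, t]` is a linear mean, `d` the correlation range, `g` the
nugget absorbing GPS error, and `p` the power-exponential exponent. The
mean coefficients and process variance are conjugate and integrated out
analytically, so each leaf's marginal likelihood and predictive are
Student-t. The partition itself is sampled by reversible-jump MCMC
(grow / prune / change / swap moves), letting the model place abrupt
regime changes — a resting bird that suddenly relocates 14 km — exactly
where the data demand them, instead of smoothing over them as a single
stationary GP must.

From K retained MCMC states the package draws K aligned trajectory samples
`s_t^k` on a Δt grid. Any deterministic function of a trajectory —
`d_{t1,t2} = √((s1,t1−s1,t2)² + (s2,t1−s2,t2)²)`, the law-of-cosines turn
angle, `r = Σ_t 1[s_t ∈ A]·Δt`, contact indicators — applied per sample
yields posterior samples of that *derived quantity* (MCMC equivariance),
and averaging across animals within each sample index k yields
population-level posteriors. See `docs/methods.md` for the full model,
priors, conventions and limitations.

## Worked example

```python
import numpy as np
from tgpmove import (ChainConfig, TimeGrid, WindowSpec, displacement,
                     fit_track, predict_trajectories, summarize,
                     window_transform)
from tgpmove.synthetic_data import default_changepoint, simulate_track
from tgpmove.trajectory import HOUR

# a two-regime synthetic track: localized foraging, then fast roaming
track, truth = simulate_track(default_changepoint(seed=4), "bird_01")
print(f"{track.n} fixes spanning {(track.times[-1]-track.times[0])/HOUR:.1f} h")

config = ChainConfig(n_iter=4000, burn_in=1000, thin=3, seed=4)
fit = fit_track(track, config)                      # one chain per coordinate

grid = TimeGrid.over_track(track, dt=HOUR)          # Δt = 1 h
traj = predict_trajectories(fit, grid, np.random.default_rng(4))
print(f"trajectories: K={traj.k} samples x M={traj.m} hourly locations")

splits = np.mean([s.tree.n_leaves > 1 for s in fit.chain_x.states])
print(f"posterior P(>=1 regime change), easting chain: {splits:.2f}")

disp = displacement(traj)                           # K x (M-1) meters
hourly = window_transform(disp, WindowSpec.hours(1), grid.dt, "sum", "mean")
daily = window_transform(disp, WindowSpec.days(1), grid.dt, "sum", "mean")
for name, q in (("average hourly displacement", hourly),
                ("average daily distance", daily)):
    s = summarize(q)
    print(f"{name}: {s.loc[0,'mean']:.0f} m "
          f"(95% CI {s.loc[0,'lower']:.0f}-{s.loc[0,'upper']:.0f})")
```

Output:

```
197 fixes spanning 99.8 h
trajectories: K=1000 samples x M=100 hourly locations
posterior P(>=1 regime change), easting chain: 1.00
average hourly displacement: 388 m (95% CI 270-552)
average daily distance: 8942 m (95% CI 6117-12888)
```

The chain retains K = (4000 − 1000)/3 = 1000 states. The posterior puts
all its mass on trees with at least one split — it has found the regime
change — and the derived quantities arrive with equal-tailed 95% credible
intervals computed from the 1000 aligned samples, not from a plug-in point
estimate.

## Command line

The same pipeline is scriptable from a shell, one artifact per stage:

```sh
tgpmove simulate --seed 1 --out fixtures/            # synthetic tracks + regions
tgpmove fit     --config run.yaml --telemetry fixtures/changepoint.csv --out fits/
tgpmove predict --config run.yaml --fits fits/ --dt 1.0 --out preds/
tgpmove derive  --config run.yaml --trajectories preds/ \
                --regions fixtures/regions.geojson --out derived/
tgpmove aggregate --config run.yaml --trajectories preds/ --out pop/
tgpmove report  --config run.yaml --fits fits/ --trajectories preds/ --out qc/
```

Telemetry is headered CSV (Movebank-style column names recognized),
regions are GeoJSON polygons in the track's projected CRS, trajectories
persist as long-format CSV (`animal, k, timestamp, x, y`), and every
output directory records the resolved configuration, its hash, and the
seed. Runs with the same config and seed are bit-identical.

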