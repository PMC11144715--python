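"""Per-animal workflow: standardize a track, fit one treed-GP chain per
coordinate, and draw aligned posterior predictive trajectories on a Δt grid.

Easting and northing are modeled independently (the standard assumption for
continuous-time telemetry models); the two chains are run with distinct
seeded substreams and their retained states are paired by sample index k, so
the k-th easting draw and the k-th northing draw form one joint trajectory
sample.  All downstream derived quantities consume these aligned samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gp_core import GPPriorConfig, posterior_predictive, draw_predictive
from .treed_model import (
    ChainConfig,
    PosteriorChain,
    assign_leaves,
    run_chain,
    _LeafLikCache,
)

logger = logging.getLogger(__name__)

HOUR = 3600.0  # seconds


@dataclass(frozen=True)
class TelemetryTrack:
    """One animal's ordered GPS fixes.

    times are absolute seconds (e.g. POSIX); x/y are projected easting and
    northing in meters.  Times must be strictly increasing with >= 4 fixes.
    """

    animal_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    source: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if t.size < 4:
            raise ValueError(f"track {self.animal_id}: need >= 4 fixes, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"track {self.animal_id}: times must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError(f"track {self.animal_id}: coordinates must be finite")
        if x.shape != t.shape or y.shape != t.shape:
            raise ValueError("times, x and y must have equal length")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ScalingInfo:
    """Invertible mapping between raw track units and the standardized scale
    (time to [0, 1], each coordinate centered and scaled)."""

    t0: float
    span: float
    x_center: float
    x_scale: float
    y_center: float
    y_scale: float

    def time_to_unit(self, t: np.ndarray) -> np.ndarray:
        return (np.asarray(t, dtype=float) - self.t0) / self.span

    def time_from_unit(self, u: np.ndarray) -> np.ndarray:
        return np.asarray(u, dtype=float) * self.span + self.t0

    def coord_to_unit(self, v: np.ndarray, axis: str) -> np.ndarray:
        c, s = (self.x_center, self.x_scale) if axis == "x" else (self.y_center, self.y_scale)
        return (np.asarray(v, dtype=float) - c) / s

    def coord_from_unit(self, v: np.ndarray, axis: str) -> np.ndarray:
        c, s = (self.x_center, self.x_scale) if axis == "x" else (self.y_center, self.y_scale)
        return np.asarray(v, dtype=float) * s + c


def standardize(track: TelemetryTrack) -> tuple[dict, ScalingInfo]:
    """Map times to [0, 1] and center/scale each coordinate to unit variance.

    A coordinate with zero variance (a stationary animal) falls back to
    scale 1 with a logged warning rather than failing.
    """
    span = float(track.times[-1] - track.times[0])
    if span <= 0:
        raise ValueError("track has zero time span")
    scales = {}
    for axis, v in (("x", track.x), ("y", track.y)):
        s = float(np.std(v))
        if s == 0.0:
            logger.warning("track %s: constant %s coordinate; scale fallback to 1",
                           track.animal_id, axis)
            s = 1.0
        scales[axis] = s
    info = ScalingInfo(t0=float(track.times[0]), span=span,
                       x_center=float(np.mean(track.x)), x_scale=scales["x"],
                       y_center=float(np.mean(track.y)), y_scale=scales["y"])
    std = {
        "times": info.time_to_unit(track.times),
        "x": info.coord_to_unit(track.x, "x"),
        "y": info.coord_to_unit(track.y, "y"),
    }
    return std, info


@dataclass(frozen=True)
class TimeGrid:
    """Uniform prediction grid: M timestamps spaced Δt apart (absolute seconds)."""

    times: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if t.size > 1 and not np.allclose(np.diff(t), self.dt):
            raise ValueError("grid spacing must equal dt")

    @property
    def m(self) -> int:
        return self.times.size

    @property
    def dt_hours(self) -> float:
        return self.dt / HOUR

    @classmethod
    def over_track(cls, track: TelemetryTrack, dt: float,
                   start: float | None = None,
                   end: float | None = None) -> "TimeGrid":
        """Grid from the first to the last covered timestamp, inclusive."""
        t0 = track.times[0] if start is None else float(start)
        t1 = track.times[-1] if end is None else float(end)
        n = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
        return cls(times=t0 + dt * np.arange(n), dt=dt)


@dataclass(frozen=True)
class TrajectoryPosteriorSamples:
    """K aligned posterior predictive trajectories on an M-point grid.

    samples has shape (K, M, 2) in meters ([..., 0] = easting, [..., 1] =
    northing); times are absolute seconds.  The sample index k is the
    alignment key across coordinates and animals.
    """

    animal_id: str
    samples: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 3 or s.shape[2] != 2 or s.shape[1] != self.grid.m:
            raise ValueError("samples must have shape (K, M, 2) matching the grid")
        if not np.all(np.isfinite(s)):
            raise ValueError("trajectory samples must be finite")

    @property
    def k(self) -> int:
        return self.samples.shape[0]

    @property
    def m(self) -> int:
        return self.samples.shape[1]

    def to_dataframe(self):
        """Long-format table (animal, k, timestamp, x, y)."""
        import pandas as pd

        K, M, _ = self.samples.shape
        return pd.DataFrame({
            "animal": self.animal_id,
            "k": np.repeat(np.arange(K), M),
            "timestamp": np.tile(self.grid.times, K),
            "x": self.samples[:, :, 0].ravel(),
            "y": self.samples[:, :, 1].ravel(),
        })


@dataclass(frozen=True)
class TrackFit:
    """Fitted per-coordinate chains plus the scaling used to fit them."""

    track: TelemetryTrack
    chain_x: PosteriorChain
    chain_y: PosteriorChain
    scaling: ScalingInfo
    std_data: dict = field(repr=False)

    @property
    def k(self) -> int:
        return self.chain_x.n_retained


def fit_track(track: TelemetryTrack, config: ChainConfig,
              prior: GPPriorConfig | None = None) -> TrackFit:
    """Fit independent treed-GP chains to the easting and northing series.

    The two chains use distinct substreams spawned deterministically from
    ``config.seed``, so refitting with the same seed is bit-identical.
    """
    prior = prior or GPPriorConfig()
    std, scaling = standardize(track)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    chain_x = run_chain(std["times"], std["x"], config, prior,
                        rng=np.random.default_rng(seeds[0]))
    chain_y = run_chain(std["times"], std["y"], config, prior,
                        rng=np.random.default_rng(seeds[1]))
    return TrackFit(track=track, chain_x=chain_x, chain_y=chain_y,
                    scaling=scaling, std_data=std)


def _draw_coordinate(chain: PosteriorChain, times_std: np.ndarray,
                     values_std: np.ndarray, grid_std: np.ndarray,
                     prior: GPPriorConfig, rng: np.random.Generator,
                     include_nugget: bool) -> np.ndarray:
    """(K, M) matrix: one joint predictive draw per retained state.

    Within one state, grid points inside the same leaf are drawn jointly from
    the leaf's full predictive covariance, so each k is a coherent path;
    cross-leaf continuity is deliberately not enforced (abrupt transitions
    at partition boundaries are what the treed model is for).
    """
    cache = _LeafLikCache(times_std, values_std, prior)
    K = chain.n_retained
    M = grid_std.size
    out = np.empty((K, M))
    pred_cache: dict = {}
    for k, state in enumerate(chain.states):
        ids = assign_leaves(state.tree, grid_std)
        for leaf_id, rec in enumerate(state.tree.leaves()):
            mask = ids == leaf_id
            if not mask.any():
                continue
            key = (rec.lo, rec.hi, rec.node.hyper.d, rec.node.hyper.g)
            dist = pred_cache.get(key)
            if dist is None:
                leaf = cache.leaf_data(rec.lo, rec.hi)
                dist = posterior_predictive(leaf, rec.node.hyper, prior,
                                            grid_std[mask],
                                            include_nugget=include_nugget)
                if len(pred_cache) > 10_000:
                    pred_cache.clear()
                pred_cache[key] = dist
            out[k, mask] = draw_predictive(dist, rng)
    return out


def predict_trajectories(fit: TrackFit, grid: TimeGrid,
                         rng: np.random.Generator,
                         prior: GPPriorConfig | None = None,
                         include_nugget: bool = False,
                         allow_extrapolation: bool = False
                         ) -> TrajectoryPosteriorSamples:
    """Draw K aligned posterior predictive trajectories on the grid.

    One draw per retained state per grid point; the k-th easting draw pairs
    with the k-th northing draw.  Results are in meters and absolute time.
    By default the predictive targets the latent path (nugget excluded).
    """
    scaling = fit.scaling
    if grid.m == 0:
        return TrajectoryPosteriorSamples(
            animal_id=fit.track.animal_id,
            samples=np.empty((fit.k, 0, 2)), grid=grid)
    gstd = scaling.time_to_unit(grid.times)
    if not allow_extrapolation and (gstd.min() < -1e-9 or gstd.max() > 1 + 1e-9):
        raise ValueError("grid extends beyond the fitted time span "
                         "(pass allow_extrapolation=True to override)")
    gstd = np.clip(gstd, 0.0, 1.0)
    prior = prior or GPPriorConfig()
    xs = _draw_coordinate(fit.chain_x, fit.std_data["times"], fit.std_data["x"],
                          gstd, prior, rng, include_nugget)
    ys = _draw_coordinate(fit.chain_y, fit.std_data["times"], fit.std_data["y"],
                          gstd, prior, rng, include_nugget)
    samples = np.stack([scaling.coord_from_unit(xs, "x"),
                        scaling.coord_from_unit(ys, "y")], axis=-1)
    return TrajectoryPosteriorSamples(animal_id=fit.track.animal_id,
                                      samples=samples, grid=grid)


def predictive_log_score(fit: TrackFit, times: np.ndarray, x: np.ndarray,
                         y: np.ndarray, prior: GPPriorConfig | None = None
                         ) -> float:
    """Posterior predictive log density of held-out fixes (nugget included).

    Computes ``log (1/K) sum_k p_k(held-out | state k)`` per coordinate and
    returns the sum over both coordinates, in raw (meter) units.  Used to
    compare the treed model against the forced-stationary baseline.
    """
    from scipy.special import logsumexp

    from .gp_core import posterior_predictive

    prior = prior or GPPriorConfig()
    times = np.asarray(times, dtype=float)
    tstd = np.clip(fit.scaling.time_to_unit(times), 0.0, 1.0)
    total = 0.0
    for axis, chain, obs in (("x", fit.chain_x, x), ("y", fit.chain_y, y)):
        vstd = fit.scaling.coord_to_unit(np.asarray(obs, dtype=float), axis)
        cache = _LeafLikCache(fit.std_data["times"], fit.std_data[axis], prior)
        pred_cache: dict = {}
        lps = np.empty(chain.n_retained)
        for k, state in enumerate(chain.states):
            ids = assign_leaves(state.tree, tstd)
            lp = 0.0
            for leaf_id, rec in enumerate(state.tree.leaves()):
                mask = ids == leaf_id
                if not mask.any():
                    continue
                key = (rec.lo, rec.hi, rec.node.hyper.d, rec.node.hyper.g)
                hit = pred_cache.get(key)
                if hit is None:
                    dist = posterior_predictive(
                        cache.leaf_data(rec.lo, rec.hi), rec.node.hyper,
                        prior, tstd[mask], include_nugget=True)
                    hit = (dist, dist.logpdf(vstd[mask]))
                    pred_cache[key] = hit
                lp += hit[1]
            lps[k] = lp
        scale = fit.scaling.x_scale if axis == "x" else fit.scaling.y_scale
        total += float(logsumexp(lps) - np.log(chain.n_retained)
                       - times.size * np.log(scale))
    return total


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the autocovariance with Geyer's initial-positive-sequence
    truncation, capped at the sample size.

    A constant input carries no autocorrelation information and by
    convention returns the sample size (logged).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    v = x - x.mean()
    var = float(v @ v) / n
    if var <= 1e-24 * max(1.0, float(x[0]) ** 2):  # numerically constant
        logger.warning("constant input to effective_sample_size; returning n")
        return float(n)
    # autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(v, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence on paired sums
    tau = -1.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        m += 1
    tau = max(tau, 1.0 / n)
    return float(min(n / tau, n))


@dataclass(frozen=True)
class ConvergenceReport:
    """Chain diagnostics: log-joint traces, per-grid-point ESS, pass/fail."""

    animal_id: str
    trace_x: np.ndarray
    trace_y: np.ndarray
    ess_x: dict[float, float]
    ess_y: dict[float, float]
    ess_threshold: float
    passed: bool


def convergence_report(fit: TrackFit, traj: TrajectoryPosteriorSamples,
                       grid_indices: np.ndarray | None = None,
                       ess_threshold: float | None = None) -> ConvergenceReport:
    """ESS of the predicted location at selected grid points plus the
    per-coordinate log joint traces.

    The default threshold is K, the retained sample count — i.e. the
    predictive draws at a location should be effectively independent.
    """
    K = traj.k
    if ess_threshold is None:
        ess_threshold = float(K)
    if grid_indices is None:
        grid_indices = np.unique(np.linspace(0, traj.m - 1, 5).astype(int))
    ess_x = {float(traj.grid.times[i]): effective_sample_size(traj.samples[:, i, 0])
             for i in grid_indices}
    ess_y = {float(traj.grid.times[i]): effective_sample_size(traj.samples[:, i, 1])
             for i in grid_indices}
    worst = min(list(ess_x.values()) + list(ess_y.values()))
    return ConvergenceReport(
        animal_id=traj.animal_id,
        trace_x=fit.chain_x.log_joint, trace_y=fit.chain_y.log_joint,
        ess_x=ess_x, ess_y=ess_y, ess_threshold=ess_threshold,
        passed=bool(worst >= ess_threshold))
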