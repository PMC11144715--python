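"""Synthetic telemetry generator with the structure real tracks exhibit:
distinct movement regimes with abrupt transitions, GPS noise, and
irregular / missing fixes — plus the ground truth needed for recovery tests.

The latent path is a concatenation of mean-reverting (Ornstein-Uhlenbeck)
segments, one per movement regime, each axis independent:

    dX = -(X - mu) / tau dt + sqrt(2 / tau) * sd dW

with attractor ``mu``, reversion timescale ``tau`` (hours) and stationary
standard deviation ``sd`` (meters).  The position is continuous across regime
boundaries (dynamics switch, the animal does not teleport) except in the
abrupt-relocation stress case, which emulates an unobserved fast transit.
The OU family is deliberately *not* the treed-GP model class, so recovery
tests against it are not circular.

Observed fixes are the latent path at jittered nominal intervals, thinned by
a missing-fix probability, plus isotropic Gaussian GPS noise (default 15 m,
typical of wildlife GPS collars).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .trajectory import HOUR, TelemetryTrack

#: epoch for synthetic timestamps (arbitrary spring season start)
T_EPOCH = 1460678400.0  # 2016-04-15T00:00:00Z


@dataclass(frozen=True)
class RegimeSpec:
    """One movement regime: OU dynamics around an attractor.

    duration_h: regime length in hours; attractor: (easting, northing) in
    meters; tau_h: reversion timescale in hours; sd_m: stationary standard
    deviation in meters.
    """

    duration_h: float
    attractor: tuple[float, float]
    tau_h: float
    sd_m: float

    def __post_init__(self) -> None:
        if min(self.duration_h, self.tau_h, self.sd_m) <= 0:
            raise ValueError("duration, tau and sd must all be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Telemetry simulation settings emulating 0.5-2 h GPS fix schedules."""

    regimes: tuple[RegimeSpec, ...]
    fix_interval_h: float = 1.0
    jitter_frac: float = 0.1
    missing_prob: float = 0.05
    noise_sd_m: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "regimes", tuple(self.regimes))
        if len(self.regimes) < 1:
            raise ValueError("need at least one regime")
        if not (0 <= self.missing_prob < 1):
            raise ValueError("missing_prob must lie in [0, 1)")
        if self.noise_sd_m < 0 or self.fix_interval_h <= 0:
            raise ValueError("noise_sd_m must be >= 0 and fix_interval_h > 0")
        if not (0 <= self.jitter_frac < 1):
            raise ValueError("jitter_frac must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Latent path on a fine grid plus the true regime change times."""

    times: np.ndarray          # absolute seconds
    x: np.ndarray
    y: np.ndarray
    change_times: np.ndarray   # absolute seconds of regime boundaries

    def at(self, t: np.ndarray) -> np.ndarray:
        """Latent (x, y) linearly interpolated at times t; shape (len(t), 2)."""
        return np.stack([np.interp(t, self.times, self.x),
                         np.interp(t, self.times, self.y)], axis=-1)


def _ou_exact(x0: float, mu: float, tau_s: float, sd: float, dts: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Exact OU transition sampling over step lengths dts (seconds)."""
    n = dts.size
    out = np.empty(n + 1)
    out[0] = x0
    decay = np.exp(-dts / tau_s)
    step_sd = sd * np.sqrt(1.0 - decay ** 2)
    eps = rng.standard_normal(n)
    for i in range(n):
        out[i + 1] = mu + (out[i] - mu) * decay[i] + step_sd[i] * eps[i]
    return out


def _simulate_latent(regimes: tuple[RegimeSpec, ...], rng: np.random.Generator,
                     fine_dt_h: float = 0.1,
                     start: tuple[float, float] | None = None
                     ) -> GroundTruth:
    times = [0.0]
    xs = []
    ys = []
    if start is None:
        first = regimes[0]
        start = (first.attractor[0] + first.sd_m * rng.standard_normal(),
                 first.attractor[1] + first.sd_m * rng.standard_normal())
    pos = list(start)
    xs.append(pos[0])
    ys.append(pos[1])
    t_cursor = 0.0
    changes = []
    for ridx, reg in enumerate(regimes):
        n_steps = max(1, int(round(reg.duration_h / fine_dt_h)))
        dts = np.full(n_steps, reg.duration_h / n_steps * HOUR)
        tau_s = reg.tau_h * HOUR
        seg_x = _ou_exact(pos[0], reg.attractor[0], tau_s, reg.sd_m, dts, rng)
        seg_y = _ou_exact(pos[1], reg.attractor[1], tau_s, reg.sd_m, dts, rng)
        seg_t = t_cursor + np.cumsum(dts)
        times.extend(seg_t.tolist())
        xs.extend(seg_x[1:].tolist())
        ys.extend(seg_y[1:].tolist())
        pos = [seg_x[-1], seg_y[-1]]
        t_cursor = seg_t[-1]
        if ridx < len(regimes) - 1:
            changes.append(t_cursor)
    return GroundTruth(times=T_EPOCH + np.asarray(times),
                       x=np.asarray(xs), y=np.asarray(ys),
                       change_times=T_EPOCH + np.asarray(changes))


def _fix_times(total_h: float, config: SimulationConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Jittered nominal fix schedule thinned by missingness (hours from 0)."""
    out = [0.0]
    t = 0.0
    while True:
        jitter = 1.0 + config.jitter_frac * rng.uniform(-1.0, 1.0)
        t += config.fix_interval_h * jitter
        if t >= total_h:
            break
        out.append(t)
    keep = rng.random(len(out)) >= config.missing_prob
    keep[0] = True  # always keep the first fix
    times = np.asarray(out)[keep]
    if times.size < 4:  # pathological configs: keep enough for a valid track
        times = np.asarray(out)[:4]
    return times


def simulate_track(config: SimulationConfig, animal_id: str = "sim"
                   ) -> tuple[TelemetryTrack, GroundTruth]:
    """Simulate one telemetry track and its latent ground truth.

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _simulate_latent(config.regimes, rng)
    total_h = sum(r.duration_h for r in config.regimes)
    fix_h = _fix_times(total_h, config, rng)
    fix_t = T_EPOCH + fix_h * HOUR
    latent = truth.at(fix_t)
    noise = config.noise_sd_m * rng.standard_normal((fix_t.size, 2))
    track = TelemetryTrack(animal_id=animal_id, times=fix_t,
                           x=latent[:, 0] + noise[:, 0],
                           y=latent[:, 1] + noise[:, 1],
                           source="tgpmove-simulated")
    return track, truth


def make_abrupt_relocation_track(config: SimulationConfig | None = None,
                                 jump_distance: float = 14_200.0,
                                 jump_gap_h: float = 2.0,
                                 regime_duration_h: float = 48.0,
                                 animal_id: str = "jumper"
                                 ) -> tuple[TelemetryTrack, GroundTruth]:
    """Stress case: two localized regimes separated by a long unobserved jump.

    The default emulates a documented extreme relocation of 14.2 km between
    GPS fixes 2 h apart.  No fixes fall inside the gap; the latent path
    dashes linearly across it.
    """
    if jump_distance <= 0:
        raise ValueError("jump_distance must be positive")
    base = config or SimulationConfig(
        regimes=(RegimeSpec(duration_h=regime_duration_h, attractor=(0.0, 0.0),
                            tau_h=4.0, sd_m=150.0),),
        fix_interval_h=1.0, seed=0)
    reg1 = base.regimes[0]
    reg2 = replace(reg1, attractor=(reg1.attractor[0] + jump_distance,
                                    reg1.attractor[1]))
    rng = np.random.default_rng(base.seed)

    t1 = _simulate_latent((reg1,), rng)
    # second segment starts at its own attractor (post-transit)
    start2 = (reg2.attractor[0] + reg2.sd_m * rng.standard_normal(),
              reg2.attractor[1] + reg2.sd_m * rng.standard_normal())
    t2 = _simulate_latent((reg2,), rng, start=start2)
    offset = (t1.times[-1] - T_EPOCH) + jump_gap_h * HOUR
    times = np.concatenate([t1.times, t2.times + offset])
    x = np.concatenate([t1.x, t2.x])
    y = np.concatenate([t1.y, t2.y])
    change = t1.times[-1] + 0.5 * jump_gap_h * HOUR
    truth = GroundTruth(times=times, x=x, y=y,
                        change_times=np.asarray([change]))

    seg_h = _fix_times(reg1.duration_h, base, rng)
    fix_h1 = seg_h
    fix_h2 = _fix_times(reg2.duration_h, base, rng)
    fix_t = np.concatenate([
        T_EPOCH + fix_h1 * HOUR,
        t1.times[-1] + jump_gap_h * HOUR + fix_h2 * HOUR,
    ])
    latent = truth.at(fix_t)
    noise = base.noise_sd_m * rng.standard_normal((fix_t.size, 2))
    track = TelemetryTrack(animal_id=animal_id, times=fix_t,
                           x=latent[:, 0] + noise[:, 0],
                           y=latent[:, 1] + noise[:, 1],
                           source="tgpmove-simulated")
    return track, truth


def make_population(n: int, config: SimulationConfig,
                    between_animal_sd: float = 0.0
                    ) -> list[tuple[TelemetryTrack, GroundTruth]]:
    """Simulate n animals with per-animal attractor perturbations.

    Per-animal seeds are spawned deterministically from the master seed, so
    the population is reproducible and each track distinct.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.SeedSequence(config.seed)
    child_seeds = master.spawn(n)
    out = []
    for i, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        shift = between_animal_sd * rng.standard_normal(2)
        regimes = tuple(
            replace(r, attractor=(r.attractor[0] + shift[0],
                                  r.attractor[1] + shift[1]))
            for r in config.regimes)
        # derive a plain-integer per-animal seed (< 2^31) for the track rng
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        cfg = replace(config, regimes=regimes, seed=sub_seed)
        out.append(simulate_track(cfg, animal_id=f"animal_{i:02d}"))
    return out


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def default_single_regime(seed: int = 0, duration_h: float = 96.0
                          ) -> SimulationConfig:
    """One localized regime, ~4 days of hourly fixes."""
    return SimulationConfig(
        regimes=(RegimeSpec(duration_h=duration_h, attractor=(0.0, 0.0),
                            tau_h=6.0, sd_m=300.0),),
        seed=seed)


def default_changepoint(seed: int = 0, duration_h: float = 100.0
                        ) -> SimulationConfig:
    """Two regimes with an abrupt switch: localized then fast-roaming."""
    half = duration_h / 2
    return SimulationConfig(
        regimes=(
            RegimeSpec(duration_h=half, attractor=(0.0, 0.0),
                       tau_h=8.0, sd_m=120.0),
            RegimeSpec(duration_h=half, attractor=(2500.0, 2000.0),
                       tau_h=1.0, sd_m=900.0),
        ),
        fix_interval_h=0.5, seed=seed)


def write_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical test tracks and region polygons as CSV/GeoJSON.

    Emits single-regime, two-regime changepoint, abrupt-relocation and
    11-animal population telemetry files, a grazing-treatment style region
    file, and a JSON sidecar recording the true changepoint time.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def dump(name: str, items: list[tuple[TelemetryTrack, GroundTruth]]) -> Path:
        rows = []
        for track, _ in items:
            for t, xx, yy in zip(track.times, track.x, track.y):
                rows.append({"animal_id": track.animal_id,
                             "timestamp": t, "x": xx, "y": yy})
        path = outdir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    single = simulate_track(default_single_regime(seed), "single")
    change = simulate_track(default_changepoint(seed), "changepoint")
    jump = make_abrupt_relocation_track(
        SimulationConfig(regimes=default_single_regime(seed).regimes[:1],
                         seed=seed))
    pop = make_population(11, default_single_regime(seed),
                          between_animal_sd=2000.0)

    written["single"] = dump("single_regime", [single])
    written["changepoint"] = dump("changepoint", [change])
    written["abrupt"] = dump("abrupt_relocation", [jump])
    written["population"] = dump("population", pop)

    meta = {
        "seed": seed,
        "changepoint_true_time": float(change[1].change_times[0]),
        "abrupt_jump_time": float(jump[1].change_times[0]),
        "epoch": T_EPOCH,
    }
    meta_path = outdir / "fixtures_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    written["meta"] = meta_path

    # two disjoint rectangular "treatments" plus implicit outside
    half = 5000.0
    regions = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": "west"},
             "geometry": {"type": "Polygon", "coordinates": [[
                 [-half, -half], [0.0, -half], [0.0, half],
                 [-half, half], [-half, -half]]]}},
            {"type": "Feature", "properties": {"name": "east"},
             "geometry": {"type": "Polygon", "coordinates": [[
                 [0.0, -half], [half, -half], [half, half],
                 [0.0, half], [0.0, -half]]]}},
        ],
    }
    regions_path = outdir / "regions.geojson"
    regions_path.write_text(json.dumps(regions, indent=2))
    written["regions"] = regions_path
    return written
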