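"""Posterior derived movement quantities computed from aligned trajectory samples.

Every quantity here is a deterministic function applied independently to each
of the K sampled trajectories, so by the equivariance property of MCMC the K
transformed values are themselves samples from the quantity's posterior.
Summaries (means, equal-tailed credible intervals) are therefore computed on
the transformed samples, never on pre-summarized trajectories.

Conventions worth flagging:

* **Turn angle** follows the law-of-cosines interior-angle definition: the
  angle at the middle point of three consecutive locations.  Straight-line
  motion gives pi and a full reversal gives 0 — the *complement* of the
  heading-change convention used in much of the movement literature.  No
  silent conversion is performed.
* Region boundaries count as inside.
* Displacement intervals are attributed to the region of their *starting*
  grid point, consistent with [t, t + Δt) interval semantics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .trajectory import HOUR, TrajectoryPosteriorSamples

logger = logging.getLogger(__name__)

OUTSIDE = "outside"


@dataclass(frozen=True)
class DerivedSamples:
    """K x L matrix of posterior samples of a derived quantity.

    Each row is one aligned MCMC sample; columns index times, windows or
    labels (L = 1 for scalar quantities).  NaN entries are flagged-undefined
    values (e.g. turn angles at zero-displacement triples), never numerical
    failures; their count is reported by :func:`summarize`.
    """

    values: np.ndarray
    units: str
    quantity: str
    animal_id: str | None = None
    columns: np.ndarray | None = None  # timestamps, window starts or labels

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def l(self) -> int:
        return self.values.shape[1]

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass(frozen=True)
class Region:
    """A named polygon (projected meters) for residence / classification."""

    name: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise ValueError(f"region {self.name!r}: invalid or empty geometry")
        if self.geometry.area <= 0:
            raise ValueError(f"region {self.name!r}: zero area")

    def covers_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-polygon with boundary counted as inside."""
        pts = shapely.points(np.asarray(x, dtype=float).ravel(),
                             np.asarray(y, dtype=float).ravel())
        return shapely.covers(self.geometry, pts).reshape(np.shape(x))


@dataclass(frozen=True)
class WindowSpec:
    """A re-summarization window, e.g. one day of hourly values.

    length is a duration in seconds and must be an integer multiple of the
    grid Δt; alignment starts at the grid origin by default.
    """

    length: float
    origin: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("window length must be positive")

    @classmethod
    def days(cls, n: float = 1.0) -> "WindowSpec":
        return cls(length=n * 24 * HOUR)

    @classmethod
    def hours(cls, n: float = 1.0) -> "WindowSpec":
        return cls(length=n * HOUR)


# ---------------------------------------------------------------------------
# base quantities
# ---------------------------------------------------------------------------

def displacement(traj: TrajectoryPosteriorSamples) -> DerivedSamples:
    """Euclidean distance between consecutive grid locations, per sample.

    Returns a K x (M - 1) matrix in meters: ``d = sqrt(dx^2 + dy^2)`` for
    each consecutive grid pair within each sampled trajectory.
    """
    if traj.m < 2:
        raise ValueError("need at least 2 grid points for displacement")
    diffs = np.diff(traj.samples, axis=1)
    vals = np.hypot(diffs[:, :, 0], diffs[:, :, 1])
    return DerivedSamples(values=vals, units="m", quantity="displacement",
                          animal_id=traj.animal_id,
                          columns=traj.grid.times[:-1])


def turn_angle(traj: TrajectoryPosteriorSamples) -> DerivedSamples:
    """Interior angle at the middle point of each consecutive location triple.

    Computed by the law of cosines
    ``a = arccos((d12^2 + d23^2 - d13^2) / (2 d23 d12))`` with the argument
    clamped to [-1, 1]; values lie in [0, pi] radians.  Straight-line motion
    gives pi, a reversal gives 0.  Triples where d12 or d23 is zero are
    flagged undefined (NaN), not raised.
    """
    if traj.m < 3:
        raise ValueError("need at least 3 grid points for turn angles")
    s = traj.samples
    d12 = np.hypot(*(np.moveaxis(s[:, 1:-1] - s[:, :-2], -1, 0)))
    d23 = np.hypot(*(np.moveaxis(s[:, 2:] - s[:, 1:-1], -1, 0)))
    d13 = np.hypot(*(np.moveaxis(s[:, 2:] - s[:, :-2], -1, 0)))
    denom = 2.0 * d23 * d12
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (d12 ** 2 + d23 ** 2 - d13 ** 2) / denom
    vals = np.arccos(np.clip(arg, -1.0, 1.0))
    undefined = denom == 0.0
    if undefined.any():
        logger.info("turn_angle: %d zero-displacement triples flagged undefined",
                    int(undefined.sum()))
        vals = np.where(undefined, np.nan, vals)
    return DerivedSamples(values=vals, units="rad", quantity="turn_angle",
                          animal_id=traj.animal_id,
                          columns=traj.grid.times[1:-1])


def residence_time(traj: TrajectoryPosteriorSamples, region: Region
                   ) -> DerivedSamples:
    """Time spent inside the region per sampled trajectory, in hours.

    Counts grid points whose location lies inside (boundary included) and
    multiplies by Δt; the raw count is the value divided by Δt.
    """
    inside = region.covers_points(traj.samples[:, :, 0], traj.samples[:, :, 1])
    hours = inside.sum(axis=1, dtype=float) * traj.grid.dt_hours
    return DerivedSamples(values=hours[:, None], units="h",
                          quantity=f"residence_time[{region.name}]",
                          animal_id=traj.animal_id)


def contact(traj: TrajectoryPosteriorSamples, point: tuple[float, float],
            epsilon: float) -> tuple[DerivedSamples, float]:
    """Contact indicators with a point of interest at tolerance epsilon.

    Returns (per-time indicator samples, contact probability), the latter
    being the fraction of the K samples that come within epsilon meters of
    the point at any grid time.  Exact equality has probability zero for
    continuous locations, so epsilon is required.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive (meters)")
    px, py = float(point[0]), float(point[1])
    dist = np.hypot(traj.samples[:, :, 0] - px, traj.samples[:, :, 1] - py)
    ind = (dist <= epsilon).astype(float)
    prob = float(np.mean(ind.max(axis=1) > 0))
    samples = DerivedSamples(values=ind, units="indicator", quantity="contact",
                             animal_id=traj.animal_id, columns=traj.grid.times)
    return samples, prob


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

def classify_regions(traj: TrajectoryPosteriorSamples, regions: list[Region]
                     ) -> tuple[np.ndarray, list[str]]:
    """Label each sampled location with the region containing it.

    Returns (labels, names): labels is a K x M integer matrix indexing into
    names; locations in no region get the implicit ``outside`` label (last).
    Regions must be pairwise disjoint (interiors); overlap is an error.
    """
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            inter = regions[i].geometry.intersection(regions[j].geometry)
            if inter.area > 0:
                raise ValueError(
                    f"regions {regions[i].name!r} and {regions[j].name!r} overlap")
    names = [r.name for r in regions] + [OUTSIDE]
    labels = np.full(traj.samples.shape[:2], len(regions), dtype=int)
    for idx in range(len(regions) - 1, -1, -1):
        inside = regions[idx].covers_points(traj.samples[:, :, 0],
                                            traj.samples[:, :, 1])
        labels[inside] = idx
    return labels, names


def percent_time_by_region(labels: np.ndarray, names: list[str]
                           ) -> DerivedSamples:
    """Percent of grid points in each region, per sample; rows sum to 100."""
    K, M = labels.shape
    counts = np.stack([(labels == i).sum(axis=1) for i in range(len(names))],
                      axis=1)
    vals = 100.0 * counts / M
    return DerivedSamples(values=vals, units="%", quantity="percent_time",
                          columns=np.array(names, dtype=object))


def displacement_by_region(traj: TrajectoryPosteriorSamples,
                           labels: np.ndarray, names: list[str]
                           ) -> dict[str, DerivedSamples]:
    """Displacement sequences attributed to regions by their starting point.

    Each of the M - 1 intervals is assigned the label of its starting grid
    point; for each region the full K x (M - 1) sequence is returned with
    out-of-region intervals masked NaN, so window transforms and summaries
    skip them while sample alignment is preserved.
    """
    disp = displacement(traj)
    start_labels = labels[:, :-1]
    out = {}
    for i, name in enumerate(names):
        vals = np.where(start_labels == i, disp.values, np.nan)
        out[name] = DerivedSamples(values=vals, units="m",
                                   quantity=f"displacement[{name}]",
                                   animal_id=traj.animal_id,
                                   columns=disp.columns)
    return out


# ---------------------------------------------------------------------------
# temporal rescaling, aggregation, summaries
# ---------------------------------------------------------------------------

_WITHIN_OPS = {"sum": np.nansum, "mean": np.nanmean, "max": np.nanmax}
_ACROSS_OPS = {"mean": np.nanmean, "sum": np.nansum, "max": np.nanmax,
               "identity": None}


def window_transform(samples: DerivedSamples, window: WindowSpec, dt: float,
                     within_op: str = "sum", across_op: str = "mean"
                     ) -> DerivedSamples:
    """Re-summarize a Δt-resolution sequence over longer windows.

    Applies ``within_op`` inside each window of ``window.length`` seconds,
    then ``across_op`` across windows — always independently within each
    sample k, never across samples.  E.g. 744 hourly displacements with
    daily windows, sum within and mean across give the average daily
    distance traveled, one value per sample.

    A trailing partial window is dropped (with a log message); NaN-masked
    entries are skipped, and an all-NaN window is NaN.
    """
    steps = window.length / dt
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError("window length must be an integer multiple of dt")
    steps = int(round(steps))
    K, L = samples.values.shape
    n_win = L // steps
    if n_win == 0:
        raise ValueError("sequence shorter than one window")
    dropped = L - n_win * steps
    if dropped:
        logger.info("window_transform: dropping %d trailing values (partial window)",
                    dropped)
    if within_op not in _WITHIN_OPS or across_op not in _ACROSS_OPS:
        raise ValueError(f"unknown window op {within_op!r}/{across_op!r}")
    blocks = samples.values[:, :n_win * steps].reshape(K, n_win, steps)
    all_nan = np.isnan(blocks).all(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        within = _WITHIN_OPS[within_op](blocks, axis=2)
    within = np.where(all_nan, np.nan, within)
    if across_op == "identity":
        vals = within
        cols = (samples.columns[0:n_win * steps:steps]
                if samples.columns is not None else None)
    else:
        nan_rows = np.isnan(within).all(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = _ACROSS_OPS[across_op](within, axis=1)[:, None]
        vals = np.where(nan_rows[:, None], np.nan, vals)
        cols = None
    return DerivedSamples(values=vals, units=samples.units,
                          quantity=f"{samples.quantity}:{within_op}/{across_op}",
                          animal_id=samples.animal_id, columns=cols)


def population_aggregate(per_individual: list[DerivedSamples]) -> DerivedSamples:
    """Element-wise mean across individuals within each aligned sample index.

    All inputs must share K and shape; no silent resampling is performed.
    NaN-masked entries are skipped per element (an individual with no data
    for a region does not drag the population value to NaN).
    """
    if not per_individual:
        raise ValueError("need at least one individual")
    shapes = {d.values.shape for d in per_individual}
    if len(shapes) > 1:
        raise ValueError(f"mismatched sample shapes across individuals: {shapes}")
    units = per_individual[0].units
    stack = np.stack([d.values for d in per_individual])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN elements stay NaN
        vals = np.nanmean(stack, axis=0)
    return DerivedSamples(values=vals, units=units,
                          quantity=f"population:{per_individual[0].quantity}",
                          animal_id=None, columns=per_individual[0].columns)


def summarize(samples: DerivedSamples, level: float = 0.95) -> pd.DataFrame:
    """Per-column mean and equal-tailed credible interval (percentile method).

    Undefined (NaN) entries are excluded and counted in ``n_undefined``.
    """
    if not (0 < level < 1):
        raise ValueError("credible level must lie in (0, 1)")
    if samples.k < 2:
        raise ValueError("need K >= 2 samples to summarize")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    v = samples.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns stay NaN
        mean = np.nanmean(v, axis=0)
        lower = np.nanquantile(v, lo_q, axis=0)
        upper = np.nanquantile(v, hi_q, axis=0)
    n_undef = np.isnan(v).sum(axis=0)
    cols = (samples.columns if samples.columns is not None
            else np.arange(samples.l))
    return pd.DataFrame({
        "quantity": samples.quantity,
        "animal": samples.animal_id,
        "column": cols,
        "mean": mean,
        "lower": lower,
        "upper": upper,
        "K": samples.k,
        "n_undefined": n_undef,
        "units": samples.units,
    })
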