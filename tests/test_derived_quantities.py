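import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, box

from tgpmove.derived_quantities import (
    DerivedSamples,
    Region,
    WindowSpec,
    classify_regions,
    contact,
    displacement,
    displacement_by_region,
    percent_time_by_region,
    population_aggregate,
    residence_time,
    summarize,
    turn_angle,
    window_transform,
)
from tgpmove.trajectory import HOUR, TimeGrid, TrajectoryPosteriorSamples


def make_traj(paths, dt=HOUR, animal="toy"):
    """Build TrajectoryPosteriorSamples from a list of (M, 2) paths."""
    samples = np.asarray(paths, dtype=float)
    m = samples.shape[1]
    grid = TimeGrid(times=dt * np.arange(m), dt=dt)
    return TrajectoryPosteriorSamples(animal_id=animal, samples=samples,
                                      grid=grid)


class TestDisplacement:
    def test_three_four_five_triangle(self):
        traj = make_traj([[[0.0, 0.0], [3.0, 4.0]]])
        assert displacement(traj).values[0, 0] == pytest.approx(5.0)

    def test_stationary_is_zero(self):
        traj = make_traj([[[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]]])
        assert np.all(displacement(traj).values == 0.0)

    def test_month_of_hourly_intervals(self):
        rng = np.random.default_rng(0)
        traj = make_traj(rng.normal(size=(2, 745, 2)))
        disp = displacement(traj)
        assert disp.values.shape == (2, 744)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_triangle_inequality_per_sample(self, seed):
        rng = np.random.default_rng(seed)
        traj = make_traj(rng.normal(size=(3, 5, 2)) * 100)
        d = displacement(traj).values
        s = traj.samples
        d13 = np.hypot(s[:, 2:, 0] - s[:, :-2, 0], s[:, 2:, 1] - s[:, :-2, 1])
        assert np.all(d13 <= d[:, :-1] + d[:, 1:] + 1e-9)


class TestTurnAngle:
    def test_collinear_forward_motion_is_pi(self):
        traj = make_traj([[[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]])
        assert turn_angle(traj).values[0, 0] == pytest.approx(math.pi)

    def test_right_angle(self):
        traj = make_traj([[[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]]])
        assert turn_angle(traj).values[0, 0] == pytest.approx(math.pi / 2)

    def test_reversal_is_zero(self):
        traj = make_traj([[[0.0, 0.0], [1.0, 0.0], [0.0, 0.0]]])
        assert turn_angle(traj).values[0, 0] == pytest.approx(0.0)

    def test_zero_leg_flagged_undefined(self):
        traj = make_traj([[[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]])
        ta = turn_angle(traj)
        assert np.isnan(ta.values[0, 0])
        assert ta.n_undefined == 1

    @given(seed=st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_angles_lie_in_zero_pi(self, seed):
        rng = np.random.default_rng(seed)
        traj = make_traj(rng.normal(size=(2, 6, 2)))
        vals = turn_angle(traj).values
        ok = ~np.isnan(vals)
        assert np.all(vals[ok] >= 0.0) and np.all(vals[ok] <= math.pi)


class TestResidenceAndContact:
    def test_all_inside(self):
        traj = make_traj([[[0.0, 0.0], [0.5, 0.5], [0.2, 0.8]]])
        region = Region("sq", box(-1, -1, 2, 2))
        assert residence_time(traj, region).values[0, 0] == pytest.approx(3.0)

    def test_none_inside(self):
        traj = make_traj([[[5.0, 5.0], [6.0, 6.0], [7.0, 7.0]]])
        region = Region("sq", box(-1, -1, 2, 2))
        assert residence_time(traj, region).values[0, 0] == 0.0

    def test_middle_point_inside_unit_square(self):
        """Brute-force check on a printed toy path: only the middle location
        of three lies in the unit square, so residence is 1 h at Δt = 1 h."""
        path = [[-2.0, 0.5], [0.5, 0.5], [3.0, 0.5]]
        traj = make_traj([path])
        region = Region("unit", box(0, 0, 1, 1))

        def brute_inside(p):
            return 0 <= p[0] <= 1 and 0 <= p[1] <= 1

        expected_hours = sum(brute_inside(p) for p in path) * 1.0
        assert expected_hours == 1.0
        assert residence_time(traj, region).values[0, 0] == pytest.approx(1.0)

    def test_boundary_counts_as_inside(self):
        traj = make_traj([[[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]])
        region = Region("unit", box(0, 0, 1, 1))
        assert residence_time(traj, region).values[0, 0] == pytest.approx(2.0)

    def test_contact_probability_one_when_shared(self):
        traj = make_traj([[[1.0, 1.0], [5.0, 5.0]], [[1.0, 1.0], [9.0, 9.0]]])
        _, prob = contact(traj, (1.0, 1.0), epsilon=0.1)
        assert prob == 1.0

    def test_contact_probability_zero_when_far(self):
        traj = make_traj([[[1.0, 1.0], [5.0, 5.0]]])
        _, prob = contact(traj, (100.0, 100.0), epsilon=1.0)
        assert prob == 0.0

    def test_contact_counting(self):
        traj = make_traj([[[0.0, 0.0], [10.0, 0.0]],
                          [[50.0, 50.0], [60.0, 60.0]]])
        ind, prob = contact(traj, (10.0, 0.0), epsilon=0.5)
        assert prob == 0.5
        assert ind.values.shape == (2, 2)

    def test_epsilon_required_positive(self):
        traj = make_traj([[[0.0, 0.0], [1.0, 1.0]]])
        with pytest.raises(ValueError):
            contact(traj, (0.0, 0.0), epsilon=0.0)


class TestRegionClassification:
    west = Region("west", box(-10, -10, 0, 10))
    east = Region("east", box(0, -10, 10, 10))

    def test_outside_label(self):
        traj = make_traj([[[100.0, 0.0], [-5.0, 0.0], [5.0, 0.0]]])
        labels, names = classify_regions(traj, [self.west, self.east])
        assert names == ["west", "east", "outside"]
        assert labels.tolist() == [[2, 0, 1]]

    def test_labels_partition_grid(self):
        rng = np.random.default_rng(1)
        traj = make_traj(rng.uniform(-20, 20, size=(4, 12, 2)))
        labels, names = classify_regions(traj, [self.west, self.east])
        counts = np.stack([(labels == i).sum(axis=1) for i in range(len(names))])
        assert np.all(counts.sum(axis=0) == 12)

    def test_matches_brute_force_point_in_polygon(self):
        path = [[-3.0, 0.0], [-1.0, 1.0], [2.0, 2.0], [40.0, 0.0], [0.0, 0.0]]
        traj = make_traj([path])
        labels, names = classify_regions(traj, [self.west, self.east])

        def brute(p):
            if -10 <= p[0] <= 0 and -10 <= p[1] <= 10:
                return 0
            if 0 <= p[0] <= 10 and -10 <= p[1] <= 10:
                return 1
            return 2

        assert labels[0].tolist() == [brute(p) for p in path]

    def test_overlapping_regions_rejected(self):
        traj = make_traj([[[0.0, 0.0], [1.0, 1.0]]])
        overlap = Region("big", box(-5, -5, 5, 5))
        with pytest.raises(ValueError, match="overlap"):
            classify_regions(traj, [self.west, overlap])


class TestPercentTime:
    def test_single_label_dominates(self):
        labels = np.zeros((3, 8), dtype=int)
        pct = percent_time_by_region(labels, ["a", "outside"])
        assert np.all(pct.values[:, 0] == 100.0)
        assert np.all(pct.values[:, 1] == 0.0)

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, size=(5, 12))
        pct = percent_time_by_region(labels, ["a", "b", "outside"])
        assert np.allclose(pct.values.sum(axis=1), 100.0)

    def test_three_one_split(self):
        labels = np.array([[0, 0, 0, 1]])
        pct = percent_time_by_region(labels, ["a", "b"])
        assert pct.values.tolist() == [[75.0, 25.0]]


class TestDisplacementByRegion:
    def test_single_region_equals_displacement(self):
        rng = np.random.default_rng(3)
        traj = make_traj(rng.normal(size=(2, 6, 2)))
        labels = np.zeros((2, 6), dtype=int)
        by = displacement_by_region(traj, labels, ["all"])
        assert np.allclose(by["all"].values, displacement(traj).values)

    def test_interval_counts_conserved(self):
        rng = np.random.default_rng(4)
        traj = make_traj(rng.uniform(-20, 20, size=(3, 10, 2)))
        labels, names = classify_regions(
            traj, [TestRegionClassification.west, TestRegionClassification.east])
        by = displacement_by_region(traj, labels, names)
        counts = sum((~np.isnan(d.values)).sum() for d in by.values())
        assert counts == 3 * 9

    def test_starting_point_attribution(self):
        """Hand-worked toy: intervals take the label of their starting fix."""
        path = [[-5.0, 0.0], [5.0, 0.0], [100.0, 0.0]]
        traj = make_traj([path])
        labels, names = classify_regions(
            traj, [TestRegionClassification.west, TestRegionClassification.east])
        by = displacement_by_region(traj, labels, names)
        assert by["west"].values[0].tolist() == [10.0, None] or \
            (by["west"].values[0, 0] == 10.0 and np.isnan(by["west"].values[0, 1]))
        assert by["east"].values[0, 1] == pytest.approx(95.0)
        assert np.isnan(by["east"].values[0, 0])


class TestWindowTransform:
    def test_month_of_hourly_to_daily(self):
        """744 hourly values -> 31 daily sums per sample, then one monthly
        average per sample."""
        rng = np.random.default_rng(5)
        vals = rng.exponential(100.0, size=(10, 744))
        ds = DerivedSamples(values=vals, units="m", quantity="displacement")
        daily = window_transform(ds, WindowSpec.days(1), dt=HOUR,
                                 within_op="sum", across_op="identity")
        assert daily.values.shape == (10, 31)
        avg = window_transform(ds, WindowSpec.days(1), dt=HOUR,
                               within_op="sum", across_op="mean")
        assert avg.values.shape == (10, 1)
        assert np.allclose(avg.values[:, 0], daily.values.mean(axis=1))

    def test_constant_sequence(self):
        ds = DerivedSamples(values=np.full((2, 48), 3.0), units="m",
                            quantity="d")
        out = window_transform(ds, WindowSpec.days(1), dt=HOUR, within_op="sum",
                               across_op="mean")
        assert np.allclose(out.values, 3.0 * 24)

    def test_identity_keeps_window_count(self):
        ds = DerivedSamples(values=np.arange(48.0)[None, :], units="m",
                            quantity="d")
        out = window_transform(ds, WindowSpec.hours(12), dt=HOUR,
                               within_op="max", across_op="identity")
        assert out.values.shape == (1, 4)

    def test_non_multiple_window_rejected(self):
        ds = DerivedSamples(values=np.zeros((1, 10)), units="m", quantity="d")
        with pytest.raises(ValueError):
            window_transform(ds, WindowSpec(length=1.5 * HOUR), dt=HOUR)

    def test_ragged_tail_dropped(self):
        ds = DerivedSamples(values=np.ones((1, 30)), units="m", quantity="d")
        out = window_transform(ds, WindowSpec.days(1), dt=HOUR,
                               within_op="sum", across_op="identity")
        assert out.values.shape == (1, 1)
        assert out.values[0, 0] == 24.0


class TestPopulationAggregate:
    def test_identical_individuals(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(5, 3))
        inds = [DerivedSamples(values=vals, units="m", quantity="d")
                for _ in range(4)]
        agg = population_aggregate(inds)
        assert np.allclose(agg.values, vals)

    def test_two_constant_individuals(self):
        a = DerivedSamples(values=np.full((4, 2), 2.0), units="m", quantity="d")
        b = DerivedSamples(values=np.full((4, 2), 4.0), units="m", quantity="d")
        assert np.allclose(population_aggregate([a, b]).values, 3.0)

    def test_mean_commutes_with_aggregation(self):
        """For the mean statistic, summarizing the population samples equals
        averaging the individual summaries (linearity)."""
        rng = np.random.default_rng(7)
        inds = [DerivedSamples(values=rng.normal(size=(50, 2)), units="m",
                               quantity="d") for _ in range(3)]
        agg_mean = summarize(population_aggregate(inds))["mean"].to_numpy()
        ind_means = np.mean([summarize(d)["mean"].to_numpy() for d in inds],
                            axis=0)
        assert np.allclose(agg_mean, ind_means)

    def test_mismatched_k_rejected(self):
        a = DerivedSamples(values=np.zeros((4, 2)), units="m", quantity="d")
        b = DerivedSamples(values=np.zeros((5, 2)), units="m", quantity="d")
        with pytest.raises(ValueError):
            population_aggregate([a, b])


class TestSummarize:
    def test_constant_samples_zero_width_interval(self):
        ds = DerivedSamples(values=np.full((20, 1), 7.5), units="m",
                            quantity="d")
        out = summarize(ds)
        assert out.loc[0, "mean"] == 7.5
        assert out.loc[0, "lower"] == out.loc[0, "upper"] == 7.5

    def test_normal_quantiles(self):
        rng = np.random.default_rng(8)
        mu, sd = 10.0, 2.0
        ds = DerivedSamples(values=rng.normal(mu, sd, size=(100_000, 1)),
                            units="m", quantity="d")
        out = summarize(ds, level=0.95)
        from scipy import stats as ss

        assert out.loc[0, "lower"] == pytest.approx(
            ss.norm.ppf(0.025, mu, sd), abs=0.05)
        assert out.loc[0, "upper"] == pytest.approx(
            ss.norm.ppf(0.975, mu, sd), abs=0.05)

    def test_invalid_level_rejected(self):
        ds = DerivedSamples(values=np.zeros((5, 1)), units="m", quantity="d")
        with pytest.raises(ValueError):
            summarize(ds, level=1.5)

    def test_undefined_entries_counted(self):
        vals = np.array([[1.0], [np.nan], [3.0]])
        ds = DerivedSamples(values=vals, units="m", quantity="d")
        out = summarize(ds)
        assert out.loc[0, "n_undefined"] == 1
        assert out.loc[0, "mean"] == pytest.approx(2.0)

    @given(seed=st.integers(0, 300), shift=st.floats(-5, 5), scale=st.floats(0.1, 4))
    @settings(max_examples=25, deadline=None)
    def test_quantile_equivariance_under_affine_maps(self, seed, shift, scale):
        """Quantiles of f(samples) equal f(quantiles) for monotone affine f."""
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(200, 1))
        a = summarize(DerivedSamples(values=vals, units="m", quantity="d"))
        b = summarize(DerivedSamples(values=scale * vals + shift, units="m",
                                     quantity="d"))
        assert b.loc[0, "lower"] == pytest.approx(
            scale * a.loc[0, "lower"] + shift, abs=1e-9)
        assert b.loc[0, "upper"] == pytest.approx(
            scale * a.loc[0, "upper"] + shift, abs=1e-9)


class TestConservationAcrossQuantities:
    def test_residence_over_exclusive_regions_sums_to_span(self):
        rng = np.random.default_rng(9)
        traj = make_traj(rng.uniform(-20, 20, size=(3, 9, 2)))
        west, east = TestRegionClassification.west, TestRegionClassification.east
        labels, names = classify_regions(traj, [west, east])
        pct = percent_time_by_region(labels, names)
        r_west = residence_time(traj, west).values[:, 0]
        r_east = residence_time(traj, east).values[:, 0]
        outside_h = traj.m * traj.grid.dt_hours - r_west - r_east
        # hours implied by the percent-time rows agree with residence_time
        assert np.allclose(pct.values[:, 0] / 100 * traj.m, r_west)
        assert np.allclose(pct.values[:, 1] / 100 * traj.m, r_east)
        assert np.all(outside_h >= -1e-9)

    def test_derived_quantities_are_deterministic(self):
        rng = np.random.default_rng(10)
        traj = make_traj(rng.normal(size=(4, 8, 2)))
        a = displacement(traj).values
        b = displacement(traj).values
        assert np.array_equal(a, b)
        ta = turn_angle(traj).values
        tb = turn_angle(traj).values
        assert np.array_equal(ta[~np.isnan(ta)], tb[~np.isnan(tb)])
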