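"""Normalization, resistance, recovery index and trajectory geometry."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monoflux.resilience import (
    NormalizationError,
    compare_perturbation,
    daily_group_means,
    normalize_fluxes,
    recovery_index,
    resistance,
    trajectory_metrics,
)


def means_frame(rows):
    return pd.DataFrame(rows, columns=["date", "land_use", "treatment", "variable", "mean"])


def path(points):
    dates = [dt.date(2014, 5, 1) + dt.timedelta(days=i) for i in range(len(points))]
    return pd.DataFrame(
        {"date": dates, "norm_gpp_sat": [p[0] for p in points], "norm_er": [p[1] for p in points]}
    )


class TestNormalize:
    def test_ratio_of_group_means(self):
        d = dt.date(2014, 6, 1)
        out = normalize_fluxes(
            means_frame(
                [
                    (d, "meadow", "control", "gpp_sat", 10.0),
                    (d, "meadow", "drought", "gpp_sat", 5.0),
                    (d, "meadow", "control", "er", 4.0),
                    (d, "meadow", "drought", "er", 4.0),
                ]
            )
        )
        gpp = out[out["variable"] == "gpp_sat"]["norm"].iloc[0]
        er = out[out["variable"] == "er"]["norm"].iloc[0]
        assert gpp == pytest.approx(0.5) and er == pytest.approx(1.0)

    def test_unmatched_dates_dropped(self):
        d1, d2 = dt.date(2014, 6, 1), dt.date(2014, 6, 2)
        out = normalize_fluxes(
            means_frame(
                [
                    (d1, "meadow", "control", "er", 4.0),
                    (d1, "meadow", "drought", "er", 2.0),
                    (d2, "meadow", "control", "er", 4.0),  # no drought counterpart
                ]
            )
        )
        assert list(out["date"]) == [d1]

    def test_non_positive_control_raises_with_context(self):
        d = dt.date(2014, 6, 1)
        with pytest.raises(NormalizationError, match="gpp_sat"):
            normalize_fluxes(
                means_frame(
                    [
                        (d, "meadow", "control", "gpp_sat", 0.0),
                        (d, "meadow", "drought", "gpp_sat", 5.0),
                    ]
                )
            )

    def test_daily_group_means_shape(self):
        df = pd.DataFrame(
            {
                "date": [dt.date(2014, 6, 1)] * 4,
                "land_use": ["meadow"] * 4,
                "treatment": ["control", "control", "drought", "drought"],
                "gpp": [10.0, 12.0, 4.0, 6.0],
            }
        )
        out = daily_group_means(df, "gpp", "gpp_sat")
        ctl = out[out["treatment"] == "control"].iloc[0]
        assert ctl["mean"] == pytest.approx(11.0) and ctl["n"] == 2
        assert set(out["variable"]) == {"gpp_sat"}


class TestIndices:
    def test_resistance_ratio(self):
        assert resistance(8.0, 10.0) == pytest.approx(0.8)
        assert resistance(10.0, 10.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            resistance(1.0, 0.0)

    @pytest.mark.parametrize(
        "d_rec,c_rec,rst,expected",
        [(9.0, 10.0, 0.8, 0.1), (10.0, 10.0, 0.6, 0.4), (10.0, 10.0, 1.0, 0.0)],
    )
    def test_recovery_index_formula(self, d_rec, c_rec, rst, expected):
        assert recovery_index(d_rec, c_rec, rst) == pytest.approx(expected)

    def test_recovery_index_identity_on_random_inputs(self, rng):
        d = rng.uniform(0.1, 20, 200)
        c = rng.uniform(0.1, 20, 200)
        r = rng.uniform(0.05, 1.0, 200)
        for di, ci, ri in zip(d, c, r):
            assert recovery_index(di, ci, ri) == pytest.approx(di / ci - ri, rel=1e-12)


class TestTrajectory:
    def test_hand_geometry(self):
        traj = trajectory_metrics(path([(1, 1), (0.5, 1), (0.5, 0.5), (1, 1)]))
        assert traj.segment_distances == pytest.approx(
            [0.5, 0.5, np.sqrt(0.5)], abs=1e-9
        )
        assert traj.cumulative_length == pytest.approx(1.70711, abs=1e-5)
        assert traj.cumulative_distance[0] == 0.0

    def test_zero_segment_for_repeated_points(self):
        traj = trajectory_metrics(path([(1, 1), (1, 1), (0.5, 1)]))
        assert traj.segment_distances[0] == 0.0

    def test_scaling_equivariance_about_origin_point(self):
        pts = [(1, 1), (0.6, 0.9), (0.3, 0.5), (0.8, 1.2)]
        scaled = [(1 + 2 * (x - 1), 1 + 2 * (y - 1)) for x, y in pts]
        l1 = trajectory_metrics(path(pts)).cumulative_length
        l2 = trajectory_metrics(path(scaled)).cumulative_length
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            trajectory_metrics(path([(1, 1)]))

    def test_unsorted_input_is_ordered_by_date(self):
        p = path([(1, 1), (0.5, 1), (0.5, 0.5)])
        shuffled = p.iloc[[2, 0, 1]]
        assert trajectory_metrics(shuffled).cumulative_length == pytest.approx(
            trajectory_metrics(p).cumulative_length
        )


class TestComparePerturbation:
    def test_relative_difference(self):
        a = trajectory_metrics(path([(0, 0), (1.33, 0)]))
        b = trajectory_metrics(path([(0, 0), (1.0, 0)]))
        assert compare_perturbation(a, b) == pytest.approx(0.33)
        assert compare_perturbation(b, b) == 0.0

    def test_zero_reference_raises(self):
        a = trajectory_metrics(path([(0, 0), (1, 0)]))
        z = trajectory_metrics(path([(1, 1), (1, 1)]))
        with pytest.raises(ValueError):
            compare_perturbation(a, z)


coord = st.floats(-3, 3, allow_nan=False)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    pts=st.lists(st.tuples(coord, coord), min_size=2, max_size=8),
    shift=st.tuples(coord, coord),
    k=st.floats(0.1, 5),
)
def test_trajectory_invariances_property(pts, shift, k):
    """Translation invariance, x k scaling equivariance, triangle inequality."""
    base = trajectory_metrics(path(pts)).cumulative_length
    moved = [(x + shift[0], y + shift[1]) for x, y in pts]
    assert trajectory_metrics(path(moved)).cumulative_length == pytest.approx(
        base, rel=1e-9, abs=1e-9
    )
    scaled = [(k * x, k * y) for x, y in pts]
    assert trajectory_metrics(path(scaled)).cumulative_length == pytest.approx(
        k * base, rel=1e-9, abs=1e-9
    )
    if len(pts) >= 3:
        dropped = pts[:1] + pts[2:]
        assert (
            trajectory_metrics(path(dropped)).cumulative_length <= base + 1e-9
        )
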