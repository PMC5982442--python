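"""Normalized fluxes, resistance, recovery index and response trajectories.

The drought treatment is expressed relative to the controls: daily group
means of GPP_sat and ER in the drought treatment are divided by the
corresponding control means. Resistance (RST) is the drought/control ratio
at peak drought; the recovery index is D_rec/C_rec - RST with drought and
control values taken at the recovery occasion, so an unperturbed system
scores 0 and a fully converged system scores 1 - RST.

The sequence of daily normalized (GPP_sat, ER) points forms a response
trajectory in the bivariate flux space; the Euclidean distance between
consecutive points measures change, and the cumulative length of the path
from the pretreatment start measures the overall perturbation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationError",
    "NormalizedTrajectory",
    "daily_group_means",
    "normalize_fluxes",
    "resistance",
    "recovery_index",
    "trajectory_metrics",
    "compare_perturbation",
]

logger = logging.getLogger("monoflux")


class NormalizationError(ValueError):
    pass


def daily_group_means(records: pd.DataFrame, value_col: str, variable: str) -> pd.DataFrame:
    """Daily mean, n and standard error per date x land_use x treatment."""
    g = records.groupby(["date", "land_use", "treatment"], observed=True)[value_col]
    out = g.agg(mean="mean", n="size", se="sem").reset_index()
    out.insert(3, "variable", variable)
    return out


def normalize_fluxes(means: pd.DataFrame) -> pd.DataFrame:
    """Divide drought daily means by the matching control means.

    ``means`` is tidy with columns date, land_use, treatment, variable,
    mean (as produced by :func:`daily_group_means`, possibly concatenated
    over variables). Dates present in only one treatment are dropped with a
    log entry. Returns columns date, land_use, variable, norm.
    """
    wide = means.pivot_table(
        index=["date", "land_use", "variable"], columns="treatment", values="mean",
        observed=True,
    )
    for col in ("control", "drought"):
        if col not in wide.columns:
            raise NormalizationError(f"means table lacks treatment level {col!r}")
    unmatched = wide[wide["control"].isna() | wide["drought"].isna()]
    for (day, lu, var) in unmatched.index:
        logger.info("normalize_fluxes: dropping %s %s %s (present in one treatment only)",
                    day, lu, var)
    wide = wide.dropna()
    bad = wide[wide["control"] <= 0]
    if len(bad):
        day, lu, var = bad.index[0]
        raise NormalizationError(
            f"non-positive control mean for {var} on {day} ({lu}); cannot normalize"
        )
    out = (wide["drought"] / wide["control"]).rename("norm").reset_index()
    return out


def resistance(d_peak: float, c_peak: float) -> float:
    """RST: drought/control ratio at peak drought."""
    if c_peak <= 0:
        raise ValueError(f"control value at peak drought must be positive, got {c_peak}")
    return d_peak / c_peak


def recovery_index(d_rec: float, c_rec: float, rst: float) -> float:
    """D_rec/C_rec - RST, with control values at the recovery occasion."""
    if c_rec <= 0:
        raise ValueError(f"control value at recovery must be positive, got {c_rec}")
    return d_rec / c_rec - rst


@dataclass
class NormalizedTrajectory:
    """Date-ordered path in (normalized GPP_sat, normalized ER) space."""

    points: pd.DataFrame  # columns: date, norm_gpp_sat, norm_er
    segment_distances: np.ndarray  # len = n_points - 1
    cumulative_distance: np.ndarray  # len = n_points, starts at 0

    @property
    def cumulative_length(self) -> float:
        return float(self.cumulative_distance[-1])


def trajectory_metrics(points: pd.DataFrame) -> NormalizedTrajectory:
    """Segment and cumulative Euclidean distances along the trajectory.

    ``points`` must hold columns date, norm_gpp_sat, norm_er with at least
    two rows; the path is ordered by date, starting at the first
    (pretreatment) point.
    """
    if len(points) < 2:
        raise ValueError(f"a trajectory needs >= 2 points, got {len(points)}")
    pts = points.sort_values("date").reset_index(drop=True)
    dx = np.diff(pts["norm_gpp_sat"].to_numpy(dtype=float))
    dy = np.diff(pts["norm_er"].to_numpy(dtype=float))
    seg = np.hypot(dx, dy)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return NormalizedTrajectory(points=pts, segment_distances=seg, cumulative_distance=cum)


def compare_perturbation(traj_a: NormalizedTrajectory, traj_b: NormalizedTrajectory) -> float:
    """Relative difference (L_a - L_b) / L_b of cumulative lengths."""
    lb = traj_b.cumulative_length
    if lb == 0:
        raise ValueError("reference trajectory has zero cumulative length")
    return (traj_a.cumulative_length - lb) / lb
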