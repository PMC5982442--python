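"""Closed-chamber CO2 flux derivation.

Net ecosystem exchange (NEE) is measured with a transparent chamber placed
on the monolith, ecosystem respiration (ER) with the same chamber darkened.
The CO2 mixing ratio inside the closed chamber changes approximately
linearly over the short (~1 min) enclosure; the fitted slope (ppm s^-1),
scaled by the molar density of air and the effective chamber height, gives
the flux in umol CO2 m^-2 s^-1.

Sign conventions: NEE follows the micrometeorological convention (negative =
net uptake by the ecosystem); ER and GPP are stored positive, so the
partitioning identity is ``gpp = er - nee``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as Date, datetime as DateTime

import numpy as np
from scipy import stats

R_GAS = 8.314462618  # J mol^-1 K^-1
STANDARD_PRESSURE_PA = 101325.0

__all__ = [
    "R_GAS",
    "STANDARD_PRESSURE_PA",
    "ChamberGeometry",
    "ChamberSeries",
    "SlopeFit",
    "FluxFragment",
    "FluxRecord",
    "DegenerateFitError",
    "PairingError",
    "fit_concentration_slope",
    "grouped_ols",
    "slope_to_flux",
    "pair_and_partition",
    "replicate_filter",
]


class DegenerateFitError(ValueError):
    """Concentration series cannot support a linear fit (too few points or
    zero time variance)."""


class PairingError(ValueError):
    """Sunlit/dark measurements cannot be paired."""


@dataclass(frozen=True)
class ChamberGeometry:
    """Right-cylinder chamber; volume/area reduces to the effective height.

    ``headspace_m`` is an optional additive height for air volume between
    the monolith surface and the chamber rim (default 0: the Plexiglas
    cylinder volume only).
    """

    diameter_m: float = 0.25
    height_m: float = 0.50
    headspace_m: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_m <= 0 or self.height_m <= 0:
            raise ValueError("chamber diameter and height must be positive")
        if self.headspace_m < 0:
            raise ValueError("headspace_m must be >= 0")

    @property
    def area_m2(self) -> float:
        return math.pi * (self.diameter_m / 2.0) ** 2

    @property
    def effective_height_m(self) -> float:
        return self.height_m + self.headspace_m

    @property
    def volume_m3(self) -> float:
        return self.area_m2 * self.effective_height_m


@dataclass
class ChamberSeries:
    """One chamber enclosure: timestamped CO2/temperature/PAR record."""

    monolith_id: str
    datetime: DateTime
    mode: str  # "sunlit" | "dark"
    elapsed_s: np.ndarray
    co2_ppm: np.ndarray
    air_temp_c: float
    par: float | None = None
    geometry: ChamberGeometry = ChamberGeometry()

    def __post_init__(self) -> None:
        self.elapsed_s = np.asarray(self.elapsed_s, dtype=float)
        self.co2_ppm = np.asarray(self.co2_ppm, dtype=float)
        if self.mode not in ("sunlit", "dark"):
            raise ValueError(f"mode must be 'sunlit' or 'dark', got {self.mode!r}")
        if self.elapsed_s.size != self.co2_ppm.size:
            raise ValueError("elapsed_s and co2_ppm must have equal length")
        if self.elapsed_s.size < 2:
            raise ValueError("a chamber series needs at least 2 samples")
        if np.any(np.diff(self.elapsed_s) <= 0):
            raise ValueError("elapsed_s must be strictly increasing")
        if np.any(self.co2_ppm <= 0):
            raise ValueError("co2_ppm must be positive")
        if self.mode == "sunlit" and self.par is None:
            raise ValueError("sunlit series must record PAR")
        if self.par is not None and self.par < 0:
            raise ValueError("par must be >= 0")


@dataclass(frozen=True)
class SlopeFit:
    slope: float  # ppm s^-1
    intercept: float  # ppm
    r_squared: float  # in [0, 1]; NaN when the series has no CO2 variance
    n_used: int
    qc_pass: bool
    qc_reason: str


@dataclass(frozen=True)
class FluxFragment:
    """A single quality-controlled chamber flux before partitioning."""

    monolith_id: str
    datetime: DateTime
    mode: str
    flux: float  # umol m^-2 s^-1, chamber sign (accumulation positive)
    par: float | None
    qc_pass: bool


@dataclass(frozen=True)
class FluxRecord:
    monolith_id: str
    date: Date
    nee: float  # negative = net uptake
    er: float  # positive
    gpp: float  # er - nee, positive under net assimilation
    par: float
    qc_pass: bool
    qc_reason: str = "ok"


def fit_concentration_slope(
    series: ChamberSeries,
    deadband_s: float = 10.0,
    min_points: int = 8,
    r2_min: float = 0.90,
    low_signal_ppm: float = 5.0,
) -> SlopeFit:
    """OLS fit of CO2 against elapsed time after discarding a start deadband.

    QC: the fit passes when enough points remain and either r^2 meets
    ``r2_min`` or the fitted concentration change over the enclosure is below
    ``low_signal_ppm`` (a valid near-zero flux, which an r^2-only criterion
    would reject). A series with zero CO2 variance has undefined r^2 and
    fails with reason ``no_signal``.
    """
    if deadband_s < 0:
        raise ValueError("deadband_s must be >= 0")
    mask = series.elapsed_s >= deadband_s
    t = series.elapsed_s[mask]
    y = series.co2_ppm[mask]
    if t.size < 2:
        raise DegenerateFitError(
            f"{series.monolith_id}: {t.size} samples remain after the "
            f"{deadband_s:g}s deadband; need >= 2"
        )
    if np.ptp(t) == 0:
        raise DegenerateFitError(f"{series.monolith_id}: zero time variance")

    if np.ptp(y) == 0:
        slope, intercept, r2 = 0.0, float(y[0]), float("nan")
    else:
        res = stats.linregress(t, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)

    n_used = int(t.size)
    if math.isnan(r2):
        qc_pass, reason = False, "no_signal"
    elif n_used < min_points:
        qc_pass, reason = False, "too_few_points"
    elif r2 >= r2_min:
        qc_pass, reason = True, "ok"
    elif abs(slope) * np.ptp(t) <= low_signal_ppm:
        qc_pass, reason = True, "low_signal"
    else:
        qc_pass, reason = False, "poor_fit"
    return SlopeFit(slope, intercept, r2, n_used, qc_pass, reason)


def grouped_ols(
    group_idx: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    n_groups: int,
) -> dict[str, np.ndarray]:
    """Vectorized per-group OLS used by the pipeline fast path.

    Returns slope, intercept, r_squared (NaN where the group has zero CO2
    variance), n, and the time span per group. Groups with fewer than 2
    points or zero time variance yield NaN slopes; callers decide how to
    treat them. Verified against :func:`fit_concentration_slope` in tests.
    """
    group_idx = np.asarray(group_idx)
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = np.bincount(group_idx, minlength=n_groups).astype(float)
    sx = np.bincount(group_idx, weights=t, minlength=n_groups)
    sy = np.bincount(group_idx, weights=y, minlength=n_groups)
    sxx = np.bincount(group_idx, weights=t * t, minlength=n_groups)
    sxy = np.bincount(group_idx, weights=t * y, minlength=n_groups)
    syy = np.bincount(group_idx, weights=y * y, minlength=n_groups)
    tmin = np.full(n_groups, np.inf)
    tmax = np.full(n_groups, -np.inf)
    np.minimum.at(tmin, group_idx, t)
    np.maximum.at(tmax, group_idx, t)

    with np.errstate(divide="ignore", invalid="ignore"):
        den_t = n * sxx - sx * sx
        den_y = n * syy - sy * sy
        cov = n * sxy - sx * sy
        slope = np.where(den_t > 0, cov / np.where(den_t > 0, den_t, 1.0), np.nan)
        r2 = np.where(
            (den_t > 0) & (den_y > 0),
            cov**2 / np.where(den_y > 0, den_t * den_y, 1.0),
            np.nan,
        )
        intercept = (sy - slope * sx) / np.where(n > 0, n, 1.0)
    # exactly flat series: defined zero slope, undefined r^2
    flat = (den_t > 0) & (den_y == 0)
    slope[flat] = 0.0
    return {
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
        "n": n.astype(int),
        "span_s": np.where(n > 0, tmax - tmin, 0.0),
    }


def slope_to_flux(
    slope_ppm_s,
    air_temp_c,
    pressure_pa: float = STANDARD_PRESSURE_PA,
    geometry: ChamberGeometry = ChamberGeometry(),
):
    """Convert a concentration slope (ppm s^-1) to an areal flux.

    flux = slope * (P / (R T)) * (V / A); for a right cylinder V/A is the
    effective chamber height. ppm is umol mol^-1, so the result is in
    umol m^-2 s^-1. Accepts scalars or arrays.
    """
    air_temp_c = np.asarray(air_temp_c, dtype=float)
    if np.any(air_temp_c <= -50.0):
        raise ValueError("air_temp_c must be > -50 degC")
    if pressure_pa <= 0:
        raise ValueError("pressure_pa must be positive")
    molar_density = pressure_pa / (R_GAS * (air_temp_c + 273.15))  # mol m^-3
    out = np.asarray(slope_ppm_s, dtype=float) * molar_density * geometry.effective_height_m
    return float(out) if out.ndim == 0 else out


def pair_and_partition(
    sunlit: FluxFragment,
    dark: FluxFragment,
    max_gap_min: float = 30.0,
) -> FluxRecord:
    """Pair a sunlit with a dark measurement and partition NEE into ER/GPP.

    NEE comes from the sunlit chamber (negative = uptake), ER from the dark
    chamber (stored positive), and GPP = ER - NEE. Negative ER or GPP is
    flagged via ``qc_pass``/``qc_reason``, never clipped.
    """
    if sunlit.mode != "sunlit" or dark.mode != "dark":
        raise PairingError("expected one sunlit and one dark fragment")
    if sunlit.monolith_id != dark.monolith_id:
        raise PairingError(
            f"cannot pair across monoliths: {sunlit.monolith_id} vs {dark.monolith_id}"
        )
    if not (sunlit.qc_pass and dark.qc_pass):
        raise ValueError("both fragments must pass slope QC before pairing")
    gap_min = abs((sunlit.datetime - dark.datetime).total_seconds()) / 60.0
    if gap_min > max_gap_min:
        raise PairingError(
            f"unpaired measurement {sunlit.monolith_id} @ {sunlit.datetime}: "
            f"nearest dark is {gap_min:.1f} min away (max {max_gap_min:g})"
        )
    nee = sunlit.flux
    er = dark.flux
    gpp = er - nee
    qc_pass, reason = True, "ok"
    if er < 0:
        qc_pass, reason = False, "negative_er"
    elif gpp < 0:
        qc_pass, reason = False, "negative_gpp"
    return FluxRecord(
        monolith_id=sunlit.monolith_id,
        date=sunlit.datetime.date(),
        nee=nee,
        er=er,
        gpp=gpp,
        par=float(sunlit.par),
        qc_pass=qc_pass,
        qc_reason=reason,
    )


def replicate_filter(records, min_reps: int = 3):
    """Retain only days on which every land-use x treatment cell has at
    least ``min_reps`` QC-passing records.

    ``records`` is a DataFrame with columns date, land_use, treatment,
    qc_pass. Returns ``(retained_dates, filtered)`` where ``filtered`` keeps
    all rows (passing or not) on retained days.
    """
    import pandas as pd

    required = {"date", "land_use", "treatment", "qc_pass"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if records.empty:
        return [], records
    cells = (
        records[["land_use", "treatment"]].drop_duplicates().itertuples(index=False)
    )
    cells = [tuple(c) for c in cells]
    ok = records[records["qc_pass"]]
    counts = (
        ok.groupby(["date", "land_use", "treatment"], observed=True)
        .size()
        .unstack(["land_use", "treatment"], fill_value=0)
    )
    retained = []
    for day, row in counts.iterrows():
        if all(row.get(cell, 0) >= min_reps for cell in cells):
            retained.append(day)
    retained = sorted(retained)
    filtered = records[records["date"].isin(retained)].copy()
    return retained, filtered
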