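"""Synthetic monolith drought experiment with closed-form ground truth.

Emulates a common-garden rain-exclusion experiment on intact grassland
monoliths: two land-use types (managed meadow, abandoned grassland) x two
treatments (control, drought) x blocks, measured on a fixed calendar of
chamber campaigns spanning pretreatment, drought and recovery. The
generator writes the same delimited-text tables the pipeline reads, and
every index the pipeline estimates (resistance, recovery index, trajectory
length, label recovery) has a closed-form noise-free value available via
:func:`ground_truth`, so the whole analysis is testable by parameter
recovery.

Flux dynamics (per land use, drought treatment, relative to control):

* during rain exclusion both GPP_sat and ER decline linearly from 1 to the
  configured resistance ratio, reaching it at the last scheduled
  measurement inside the window (the peak-drought occasion);
* after rewetting GPP_sat relaxes back to 1 by first-order decay with the
  configured half-time, while ER jumps to an overshoot ratio >= 1 (the
  rewetting respiration pulse) and decays back to 1 with the same
  half-time.

Noise model: i.i.d. Gaussian ppm noise on chamber CO2 readings; lognormal
between-monolith multipliers (shared across a monolith's fluxes, biomass
and pools); Gaussian per-mil noise on delta15N. All randomness flows from
the single integer ``seed``.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .chamber import R_GAS, STANDARD_PRESSURE_PA, ChamberGeometry
from .isotope import MONOLITH_AREA_M2, atom_percent_to_delta, delta_to_atom_percent
from .lightresponse import rectangular_hyperbola
from .resilience import trajectory_metrics

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "LandUseTruth",
    "GroundTruth",
    "SyntheticExperiment",
    "generate_experiment",
    "ground_truth",
    "normalized_flux_path",
    "read_experiment",
    "FUNCTIONAL_GROUPS",
]

MONOLITH_DEPTH_MM = 280.0

_D = dt.date
DEFAULT_FLUX_DATES = (
    _D(2014, 5, 12), _D(2014, 5, 19),
    _D(2014, 5, 26), _D(2014, 6, 2), _D(2014, 6, 10), _D(2014, 6, 18), _D(2014, 6, 26),
    _D(2014, 7, 3), _D(2014, 7, 7), _D(2014, 7, 15), _D(2014, 7, 22), _D(2014, 7, 28),
)
DEFAULT_DROUGHT_WINDOW = (_D(2014, 5, 21), _D(2014, 6, 28))
DEFAULT_RECOVERY_WINDOW = (_D(2014, 6, 29), _D(2014, 7, 16))
DEFAULT_HARVEST_CAMPAIGNS: Mapping[str, dt.date] = {
    "resistance": _D(2014, 7, 1),
    "recovery1": _D(2014, 7, 24),
    "recovery2": _D(2014, 8, 22),
}

# functional-group composition: (group, leaf biomass g m^-2, SLA m^2 kg^-1)
FUNCTIONAL_GROUPS: Mapping[str, tuple[tuple[str, float, float], ...]] = {
    "meadow": (("forbs", 110.0, 20.3), ("grasses", 160.0, 10.1), ("legumes", 30.0, 18.0)),
    "abandoned": (("grasses", 150.0, 7.3), ("forbs", 25.0, 15.2), ("dwarf_shrubs", 20.0, 6.0)),
}
_STEM_PER_LEAF = 0.45 / 0.55 * 0.85  # stems: 45% of biomass split 85/15 stem/repro
_REPRO_PER_LEAF = 0.45 / 0.55 * 0.15
_LEAF_WEIGHT = 0.55  # leaf share of living biomass
NECROMASS_BASE = {"meadow": 60.0, "abandoned": 90.0}

LR_PFD_LEVELS = (50.0, 100.0, 200.0, 400.0, 700.0, 1000.0, 1500.0, 2000.0)

# isotope / tissue constants
TISSUE_N_CONC = {"shoot": 20.0, "root": 12.0}  # mg N g^-1
SHOOT_DRY_MASS_BASE = 280.0  # g m^-2 at the labelling harvest
ROOT_DRY_MASS_BASE = 800.0
DELTA_NA_BASE = {"meadow": 2.0, "abandoned": -1.0}  # natural-abundance per mil
LABEL_FRACTION_SHOOT = 0.25  # control shoot recovery fraction of applied label
LABEL_FRACTION_ROOT = 0.30
LABEL_FRACTION_CAP = 0.95  # closed system: total recovery stays below 1

WATER_IN_CONTROL = {"meadow": 180.0, "abandoned": 170.0}  # mm over rain exclusion
LEACHATE_CONTROL = 25.0  # mm


class ConfigError(ValueError):
    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


def _lu_map(**kw) -> dict[str, float]:
    return dict(kw)


@dataclass(frozen=True)
class ExperimentConfig:
    """Design and ground-truth parameters of a synthetic experiment.

    Per-land-use parameters are mappings keyed by land-use label. Defaults
    follow the reported experiment: six blocks, rain exclusion 21 May -
    28 Jun 2014, GPP_sat resistance 0.2 (meadow) / 0.4 (abandoned), ER
    resistance 0.4 / 0.75, a faster meadow recovery, a rewetting ER
    overshoot, and a post-drought shoot 15N uptake pulse in the meadow.
    """

    n_blocks: int = 6
    land_uses: tuple[str, ...] = ("meadow", "abandoned")
    treatments: tuple[str, ...] = ("control", "drought")
    dates: tuple[dt.date, ...] = DEFAULT_FLUX_DATES
    drought_window: tuple[dt.date, dt.date] = DEFAULT_DROUGHT_WINDOW
    recovery_window: tuple[dt.date, dt.date] = DEFAULT_RECOVERY_WINDOW
    harvest_campaigns: Mapping[str, dt.date] = field(
        default_factory=lambda: dict(DEFAULT_HARVEST_CAMPAIGNS)
    )
    true_gpp_max: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=25.0, abandoned=18.0)
    )
    true_alpha: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=0.05, abandoned=0.045)
    )
    true_er_base: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=8.0, abandoned=6.0)
    )
    resistance_gpp: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=0.2, abandoned=0.4)
    )
    resistance_er: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=0.4, abandoned=0.75)
    )
    recovery_halftime: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=3.0, abandoned=6.0)
    )
    er_overshoot: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=1.3, abandoned=1.15)
    )
    leafN_pulse: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=1.1, abandoned=0.0)
    )
    resistance_lai: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=0.55, abandoned=0.8)
    )
    resistance_biomass: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=0.65, abandoned=0.85)
    )
    harvest_recovery_halftime: Mapping[str, float] = field(
        default_factory=lambda: _lu_map(meadow=15.0, abandoned=30.0)
    )
    noise_sd_ppm: float = 0.5
    block_sd: float = 0.15  # lognormal sigma of between-monolith multipliers
    isotope_delta_sd: float = 0.3  # per mil
    par_sunlit: float = 1500.0  # PFD of standard clear-sky measurements
    air_temp_c: float = 15.0
    air_temp_sd: float = 2.0
    pressure_pa: float = STANDARD_PRESSURE_PA
    geometry: ChamberGeometry = ChamberGeometry()
    soil_moisture_threshold: float = 25.0  # vol.%, controls stay above this
    applied_label_mg: float = 2.0
    monolith_area_m2: float = MONOLITH_AREA_M2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 3:
            raise ConfigError("n_blocks", "need >= 3 blocks to satisfy the replicate filter")
        for name, vals in (("land_uses", self.land_uses), ("treatments", self.treatments)):
            if len(vals) == 0:
                raise ConfigError(name, "must not be empty")
        if set(self.treatments) != {"control", "drought"}:
            raise ConfigError("treatments", "must be {'control', 'drought'}")
        if len(self.dates) < 4:
            raise ConfigError("dates", "need at least 4 measurement dates")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ConfigError("dates", "must be strictly increasing")
        d0, d1 = self.drought_window
        if d1 <= d0:
            raise ConfigError("drought_window", "end must come after start")
        if d0 <= self.dates[0] or d1 >= self.dates[-1]:
            raise ConfigError("drought_window", "must lie strictly within the date span")
        r0, r1 = self.recovery_window
        if r1 < r0:
            raise ConfigError("recovery_window", "end must come after start")
        if not any(d0 <= d <= d1 for d in self.dates):
            raise ConfigError("dates", "need at least one measurement inside the drought window")
        if not any(d > d1 for d in self.dates):
            raise ConfigError("dates", "need at least one post-rewetting measurement")
        if not any(r0 <= d <= r1 for d in self.dates):
            raise ConfigError("recovery_window", "contains no measurement date")
        for name in ("resistance_gpp", "resistance_er", "resistance_lai", "resistance_biomass"):
            m = getattr(self, name)
            for lu in self.land_uses:
                if lu not in m:
                    raise ConfigError(name, f"missing land use {lu!r}")
                if not 0.0 < m[lu] <= 1.0:
                    raise ConfigError(name, f"{lu}: must lie in (0, 1], got {m[lu]}")
        for name in (
            "true_gpp_max", "true_alpha", "true_er_base", "recovery_halftime",
            "harvest_recovery_halftime",
        ):
            m = getattr(self, name)
            for lu in self.land_uses:
                if lu not in m:
                    raise ConfigError(name, f"missing land use {lu!r}")
                if m[lu] <= 0:
                    raise ConfigError(name, f"{lu}: must be positive, got {m[lu]}")
        for lu in self.land_uses:
            if self.er_overshoot[lu] < 1.0:
                raise ConfigError("er_overshoot", f"{lu}: must be >= 1, got {self.er_overshoot[lu]}")
            if self.leafN_pulse[lu] < 0:
                raise ConfigError("leafN_pulse", f"{lu}: must be >= 0")
            if lu not in FUNCTIONAL_GROUPS:
                raise ConfigError("land_uses", f"no functional-group composition for {lu!r}")
            # leaf vs total-biomass resistance must be jointly feasible
            if _stem_resistance(self, lu) <= 0:
                raise ConfigError(
                    "resistance_biomass",
                    f"{lu}: incompatible with resistance_lai (implied stem factor <= 0)",
                )
        for name in ("noise_sd_ppm", "block_sd", "isotope_delta_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be >= 0")
        if self.applied_label_mg <= 0:
            raise ConfigError("applied_label_mg", "must be positive")

    def zero_noise(self) -> "ExperimentConfig":
        """Copy with every stochastic component switched off."""
        return replace(self, noise_sd_ppm=0.0, block_sd=0.0, isotope_delta_sd=0.0,
                       air_temp_sd=0.0)

    @property
    def peak_drought_date(self) -> dt.date:
        """Last scheduled measurement inside the rain-exclusion window."""
        d0, d1 = self.drought_window
        return max(d for d in self.dates if d0 <= d <= d1)


# ---------------------------------------------------------------------------
# closed-form dynamics


def _days(a: dt.date, b: dt.date) -> float:
    return (b - a).days


def _decay(days_since: float, halftime: float) -> float:
    return 0.5 ** (days_since / halftime)


def _norm_flux_at(config: ExperimentConfig, land_use: str, when: dt.date, variable: str) -> float:
    """Noise-free drought/control ratio of GPP_sat or ER on a given date."""
    d0, d1 = config.drought_window
    peak = config.peak_drought_date
    r = (config.resistance_gpp if variable == "gpp_sat" else config.resistance_er)[land_use]
    if when < d0:
        return 1.0
    if when <= d1:
        ramp = 1.0 if peak == d0 else min(1.0, _days(d0, when) / _days(d0, peak))
        return 1.0 - (1.0 - r) * ramp
    ht = config.recovery_halftime[land_use]
    decay = _decay(_days(d1, when), ht)
    if variable == "gpp_sat":
        return 1.0 - (1.0 - r) * decay
    over = config.er_overshoot[land_use]
    return 1.0 + (over - 1.0) * decay


def _stem_resistance(config: ExperimentConfig, land_use: str) -> float:
    """Drought factor for stem+reproductive biomass implied by the leaf and
    total-biomass resistances (leaf share of living biomass is fixed)."""
    r_leaf = config.resistance_lai[land_use]
    r_total = config.resistance_biomass[land_use]
    return (r_total - _LEAF_WEIGHT * r_leaf) / (1.0 - _LEAF_WEIGHT)


def _norm_harvest_at(config: ExperimentConfig, land_use: str, when: dt.date, r: float) -> float:
    """Noise-free drought/control ratio of a harvest pool with drought
    factor ``r``: linear decline to r over the rain exclusion, then
    first-order relaxation with the harvest half-time."""
    d0, d1 = config.drought_window
    if when < d0:
        return 1.0
    if when <= d1:
        return 1.0 - (1.0 - r) * min(1.0, _days(d0, when) / _days(d0, d1))
    decay = _decay(_days(d1, when), config.harvest_recovery_halftime[land_use])
    return 1.0 - (1.0 - r) * decay


def normalized_flux_path(config: ExperimentConfig, land_use: str) -> pd.DataFrame:
    """Noise-free trajectory points (date, norm_gpp_sat, norm_er)."""
    rows = [
        {
            "date": d,
            "norm_gpp_sat": _norm_flux_at(config, land_use, d, "gpp_sat"),
            "norm_er": _norm_flux_at(config, land_use, d, "er"),
        }
        for d in config.dates
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LandUseTruth:
    rst_gpp_sat: float
    rst_er: float
    rst_lai: float
    rst_biomass: float
    ri_gpp_sat: float
    ri_er: float
    ri_lai: float
    ri_biomass: float
    trajectory_length: float
    shoot_label_ratio: float  # drought/control shoot label recovery


@dataclass(frozen=True)
class GroundTruth:
    per_land_use: Mapping[str, LandUseTruth]

    def __getitem__(self, land_use: str) -> LandUseTruth:
        return self.per_land_use[land_use]


def ground_truth(config: ExperimentConfig) -> GroundTruth:
    """Closed-form noise-free values of every index the pipeline estimates.

    Flux resistances are evaluated at the peak-drought occasion, recovery
    indices as the mean normalized value over the recovery-window dates
    minus the resistance; harvest parameters use the resistance and first
    recovery campaigns.
    """
    truths: dict[str, LandUseTruth] = {}
    r0, r1 = config.recovery_window
    rec_dates = [d for d in config.dates if r0 <= d <= r1]
    rst_campaign = config.harvest_campaigns["resistance"]
    rec_campaign = config.harvest_campaigns["recovery1"]
    for lu in config.land_uses:
        peak = config.peak_drought_date
        rst_gpp = _norm_flux_at(config, lu, peak, "gpp_sat")
        rst_er = _norm_flux_at(config, lu, peak, "er")
        ri_gpp = float(np.mean([_norm_flux_at(config, lu, d, "gpp_sat") for d in rec_dates])) - rst_gpp
        ri_er = float(np.mean([_norm_flux_at(config, lu, d, "er") for d in rec_dates])) - rst_er

        path = normalized_flux_path(config, lu)
        traj_len = trajectory_metrics(path).cumulative_length

        r_leaf = config.resistance_lai[lu]
        r_stem = _stem_resistance(config, lu)
        rst_lai = _norm_harvest_at(config, lu, rst_campaign, r_leaf)
        rst_bio = (
            _LEAF_WEIGHT * rst_lai
            + (1 - _LEAF_WEIGHT) * _norm_harvest_at(config, lu, rst_campaign, r_stem)
        )
        ri_lai = _norm_harvest_at(config, lu, rec_campaign, r_leaf) - rst_lai
        ri_bio = (
            _LEAF_WEIGHT * _norm_harvest_at(config, lu, rec_campaign, r_leaf)
            + (1 - _LEAF_WEIGHT) * _norm_harvest_at(config, lu, rec_campaign, r_stem)
        ) - rst_bio

        truths[lu] = LandUseTruth(
            rst_gpp_sat=rst_gpp,
            rst_er=rst_er,
            rst_lai=rst_lai,
            rst_biomass=rst_bio,
            ri_gpp_sat=ri_gpp,
            ri_er=ri_er,
            ri_lai=ri_lai,
            ri_biomass=ri_bio,
            trajectory_length=traj_len,
            shoot_label_ratio=1.0 + config.leafN_pulse[lu],
        )
    return GroundTruth(per_land_use=truths)


# ---------------------------------------------------------------------------
# generation


@dataclass
class SyntheticExperiment:
    """Complete synthetic dataset in the pipeline's input formats."""

    config: ExperimentConfig
    monoliths: pd.DataFrame
    chamber_series: pd.DataFrame
    harvest: pd.DataFrame
    isotope: pd.DataFrame
    water_balance: pd.DataFrame
    soil_moisture: pd.DataFrame

    _TABLES = ("monoliths", "chamber_series", "harvest", "isotope", "water_balance", "soil_moisture")

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)


def read_experiment(in_dir) -> dict[str, pd.DataFrame]:
    """Read the delimited-text tables written by :meth:`SyntheticExperiment.write`."""
    in_dir = Path(in_dir)
    out = {}
    parse_dates = {
        "chamber_series": ["datetime"],
        "harvest": ["date"],
        "soil_moisture": ["date"],
        "water_balance": ["period_start", "period_end"],
        "isotope": ["date"],
    }
    for name in SyntheticExperiment._TABLES:
        path = in_dir / f"{name}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table {path}")
        out[name] = pd.read_csv(path, sep="\t", parse_dates=parse_dates.get(name, False))
    return out


def _monolith_table(config: ExperimentConfig) -> pd.DataFrame:
    rows = []
    for lu in config.land_uses:
        for tr in config.treatments:
            for b in range(1, config.n_blocks + 1):
                rows.append(
                    {
                        "monolith_id": f"{lu[:2]}-{tr[:2]}-b{b}",
                        "land_use": lu,
                        "treatment": tr,
                        "block": b,
                    }
                )
    return pd.DataFrame(rows)


def generate_experiment(config: ExperimentConfig) -> SyntheticExperiment:
    """Generate the full dataset; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    monoliths = _monolith_table(config)
    n_mono = len(monoliths)

    # between-monolith lognormal multipliers, mean 1
    sd = config.block_sd
    mult = np.exp(rng.normal(-0.5 * sd**2, sd, n_mono)) if sd > 0 else np.ones(n_mono)
    monoliths = monoliths.assign(bio_mult=mult)

    chamber = _chamber_table(config, monoliths, rng)
    harvest = _harvest_table(config, monoliths, rng)
    isotope = _isotope_table(config, monoliths, rng)
    water = _water_table(config, monoliths, rng)
    soil = _soil_moisture_table(config, rng)

    return SyntheticExperiment(
        config=config,
        monoliths=monoliths.drop(columns="bio_mult"),
        chamber_series=chamber,
        harvest=harvest,
        isotope=isotope,
        water_balance=water,
        soil_moisture=soil,
    )


def _series_rows(
    config: ExperimentConfig,
    rng: np.random.Generator,
    ids: list[str],
    datetimes: list[dt.datetime],
    modes: list[str],
    fluxes: np.ndarray,
    pars: list[float],
) -> pd.DataFrame:
    """Expand per-series true fluxes into 13-sample concentration ramps."""
    n_series = len(ids)
    t = np.arange(0.0, 61.0, 5.0)  # 1 min logged at 5-s intervals
    temps = config.air_temp_c + (
        rng.normal(0.0, config.air_temp_sd, n_series) if config.air_temp_sd > 0 else np.zeros(n_series)
    )
    molar_density = config.pressure_pa / (R_GAS * (temps + 273.15))
    slopes = fluxes / (molar_density * config.geometry.effective_height_m)
    co2 = 400.0 + slopes[:, None] * t[None, :]
    if config.noise_sd_ppm > 0:
        co2 = co2 + rng.normal(0.0, config.noise_sd_ppm, co2.shape)
    k = t.size
    return pd.DataFrame(
        {
            "monolith_id": np.repeat(ids, k),
            "datetime": np.repeat(np.array(datetimes, dtype="datetime64[s]"), k),
            "mode": np.repeat(modes, k),
            "elapsed_s": np.tile(t, n_series),
            "co2_ppm": co2.ravel(),
            "air_temp_c": np.repeat(np.round(temps, 3), k),
            "par": np.repeat(pars, k),
        }
    )


def _chamber_table(
    config: ExperimentConfig, monoliths: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    ids: list[str] = []
    datetimes: list[dt.datetime] = []
    modes: list[str] = []
    fluxes: list[float] = []
    pars: list[float] = []

    mono = monoliths.reset_index(drop=True)
    gpp_at_par = {
        lu: rectangular_hyperbola(
            config.par_sunlit, config.true_alpha[lu], config.true_gpp_max[lu]
        )
        for lu in config.land_uses
    }

    for day in config.dates:
        for i, row in enumerate(mono.itertuples(index=False)):
            norm_g = (
                _norm_flux_at(config, row.land_use, day, "gpp_sat")
                if row.treatment == "drought"
                else 1.0
            )
            norm_e = (
                _norm_flux_at(config, row.land_use, day, "er")
                if row.treatment == "drought"
                else 1.0
            )
            gpp = row.bio_mult * norm_g * gpp_at_par[row.land_use]
            er = row.bio_mult * norm_e * config.true_er_base[row.land_use]
            base = dt.datetime.combine(day, dt.time(8, 30)) + dt.timedelta(minutes=4 * i)
            # sunlit (NEE) then dark (ER), 2 min apart
            ids += [row.monolith_id, row.monolith_id]
            datetimes += [base, base + dt.timedelta(minutes=2)]
            modes += ["sunlit", "dark"]
            fluxes += [er - gpp, er]
            pars += [config.par_sunlit, 0.0]

    # dedicated light-response sequences: block-1 monolith of each cell on
    # the last pretreatment date, shaded to a range of PFD levels
    d0 = config.drought_window[0]
    lr_day = max(d for d in config.dates if d < d0)
    lr_mono = mono[mono["block"] == 1]
    for j, row in enumerate(lr_mono.itertuples(index=False)):
        base = dt.datetime.combine(lr_day, dt.time(10, 30)) + dt.timedelta(minutes=25 * j)
        er = row.bio_mult * config.true_er_base[row.land_use]
        for k, pfd in enumerate(LR_PFD_LEVELS):
            gpp = row.bio_mult * rectangular_hyperbola(
                pfd, config.true_alpha[row.land_use], config.true_gpp_max[row.land_use]
            )
            ids.append(row.monolith_id)
            datetimes.append(base + dt.timedelta(minutes=2 * k))
            modes.append("sunlit")
            fluxes.append(er - gpp)
            pars.append(pfd)
        ids.append(row.monolith_id)
        datetimes.append(base + dt.timedelta(minutes=2 * len(LR_PFD_LEVELS)))
        modes.append("dark")
        fluxes.append(er)
        pars.append(0.0)

    return _series_rows(config, rng, ids, datetimes, modes, np.asarray(fluxes), pars)


def _harvest_table(
    config: ExperimentConfig, monoliths: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    sd = config.block_sd
    for campaign, day in config.harvest_campaigns.items():
        for row in monoliths.itertuples(index=False):
            r_leaf = config.resistance_lai[row.land_use]
            r_stem = _stem_resistance(config, row.land_use)
            if row.treatment == "drought":
                f_leaf = _norm_harvest_at(config, row.land_use, day, r_leaf)
                f_stem = _norm_harvest_at(config, row.land_use, day, r_stem)
            else:
                f_leaf = f_stem = 1.0
            for group, leaf_base, sla in FUNCTIONAL_GROUPS[row.land_use]:
                noise = np.exp(rng.normal(-0.5 * (sd / 2) ** 2, sd / 2)) if sd > 0 else 1.0
                rows.append(
                    {
                        "monolith_id": row.monolith_id,
                        "campaign": campaign,
                        "date": day,
                        "functional_group": group,
                        "leaf_biomass": leaf_base * f_leaf * row.bio_mult * noise,
                        "stem_biomass": leaf_base * _STEM_PER_LEAF * f_stem * row.bio_mult * noise,
                        "reproductive_biomass": leaf_base * _REPRO_PER_LEAF * f_stem * row.bio_mult * noise,
                        "necromass": NECROMASS_BASE[row.land_use] / 3.0 * row.bio_mult,
                        "sla": sla,
                    }
                )
    return pd.DataFrame(rows)


def _isotope_table(
    config: ExperimentConfig, monoliths: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Labelled-harvest samples plus paired natural-abundance samples.

    The label is applied at rewetting and sampled at the first recovery
    campaign; recovery fractions are capped so the sampled pools never hold
    more than the applied amount (closed system).
    """
    rows = []
    day = config.harvest_campaigns["recovery1"]
    dsd = config.isotope_delta_sd
    sd = config.block_sd
    for row in monoliths.itertuples(index=False):
        norm_bio = (
            _norm_harvest_at(
                config, row.land_use, day,
                _LEAF_WEIGHT * config.resistance_lai[row.land_use]
                + (1 - _LEAF_WEIGHT) * _stem_resistance(config, row.land_use),
            )
            if row.treatment == "drought"
            else 1.0
        )
        pulse = 1.0 + (config.leafN_pulse[row.land_use] if row.treatment == "drought" else 0.0)
        f_shoot = LABEL_FRACTION_SHOOT * pulse
        f_root = LABEL_FRACTION_ROOT
        if sd > 0:
            f_shoot *= np.exp(rng.normal(-0.5 * sd**2, sd))
            f_root *= np.exp(rng.normal(-0.5 * sd**2, sd))
        total = f_shoot + f_root
        if total > LABEL_FRACTION_CAP:
            f_shoot *= LABEL_FRACTION_CAP / total
            f_root *= LABEL_FRACTION_CAP / total
        dry_mass = {
            "shoot": SHOOT_DRY_MASS_BASE * norm_bio * row.bio_mult,
            "root": ROOT_DRY_MASS_BASE * row.bio_mult,
        }
        frac = {"shoot": f_shoot, "root": f_root}
        atom_na_base = delta_to_atom_percent(DELTA_NA_BASE[row.land_use])
        for tissue in ("shoot", "root"):
            n_pool = TISSUE_N_CONC[tissue] * dry_mass[tissue]
            inc = frac[tissue] * config.applied_label_mg / config.monolith_area_m2
            atom_lab = atom_na_base + 100.0 * inc / n_pool
            delta_lab = atom_percent_to_delta(atom_lab)
            delta_na = DELTA_NA_BASE[row.land_use]
            if dsd > 0:
                delta_lab += rng.normal(0.0, dsd)
                delta_na += rng.normal(0.0, dsd)
            for labelled, delta in ((True, delta_lab), (False, delta_na)):
                rows.append(
                    {
                        "monolith_id": row.monolith_id,
                        "date": day,
                        "tissue": tissue,
                        "delta15n_permil": delta,
                        "n_conc_mg_g": TISSUE_N_CONC[tissue],
                        "dry_mass_g_m2": dry_mass[tissue],
                        "labelled": labelled,
                    }
                )
    return pd.DataFrame(rows)


def _water_table(
    config: ExperimentConfig, monoliths: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    d0, d1 = config.drought_window
    sd = config.block_sd
    rows = []
    for row in monoliths.itertuples(index=False):
        if row.treatment == "control":
            water_in = WATER_IN_CONTROL[row.land_use] + (rng.normal(0, 20 * sd) if sd > 0 else 0.0)
            leachate = LEACHATE_CONTROL * (np.exp(rng.normal(-0.5 * sd**2, sd)) if sd > 0 else 1.0)
            theta_start = 31.0
            theta_end = 30.0
        else:
            water_in = 0.0
            leachate = 0.0
            theta_start = 31.0
            theta_end = 11.0
        if sd > 0:
            theta_start += rng.normal(0, 8 * sd)
            theta_end += rng.normal(0, 8 * sd)
        rows.append(
            {
                "monolith_id": row.monolith_id,
                "period_start": d0,
                "period_end": d1,
                "water_in_mm": water_in,
                "leachate_mm": leachate,
                "theta_start": theta_start,
                "theta_end": theta_end,
                "effective_depth_mm": MONOLITH_DEPTH_MM,
            }
        )
    return pd.DataFrame(rows)


def _soil_moisture_table(config: ExperimentConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily group-level soil-moisture traces (vol.%).

    Controls fluctuate above the watering threshold (they are irrigated to
    stay there); drought traces decline monotonically over the rain
    exclusion and jump back up at rewetting. The drought decline is left
    noise-free, mimicking a smoothed sensor record.
    """
    d0, d1 = config.drought_window
    thr = config.soil_moisture_threshold
    start = config.dates[0] - dt.timedelta(days=7)
    end = config.dates[-1]
    days = pd.date_range(start, end, freq="D")
    n = len(days)
    rows = []
    sd = config.block_sd
    for lu in config.land_uses:
        for tr in config.treatments:
            i = np.arange(n)
            base = thr + 3.0 + 2.0 * np.sin(2 * np.pi * i / 25.0)
            noise = rng.normal(0, 2 * sd, n) if sd > 0 else np.zeros(n)
            vwc = np.maximum(base + noise, thr + 0.2)
            if tr == "drought":
                day_arr = days.date
                in_win = (day_arr >= d0) & (day_arr <= d1)
                span = max(_days(d0, d1), 1)
                frac = np.array([_days(d0, d) / span for d in day_arr])
                vwc = np.where(in_win, 30.0 - (30.0 - 10.0) * frac, vwc)
                after = day_arr > d1
                vwc = np.where(after, np.maximum(base + noise, thr + 0.2) - 1.0, vwc)
            rows.append(
                pd.DataFrame(
                    {
                        "date": days,
                        "land_use": lu,
                        "treatment": tr,
                        "vwc_percent": np.round(vwc, 3),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
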