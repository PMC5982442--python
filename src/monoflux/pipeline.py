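"""End-to-end orchestration: raw tables -> fluxes -> resilience -> report.

Stage order follows the measurement workflow: chamber slope fitting and QC,
unit conversion, sunlit/dark pairing into NEE/ER/GPP records, the replicate
filter, light-response fits and the saturation filter, normalization and
resilience metrics, harvest (LAI/CWM/biomass) and isotope budgets, the
water balance, and permutation tests. Every stage logs records in/out and
itemizes drops; tables are pure dataflow (no stage mutates its input).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import canopy, chamber, isotope, lightresponse, permstats, resilience, synthetic
from .chamber import ChamberGeometry
from .synthetic import ExperimentConfig, SyntheticExperiment

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "plot_trajectories"]

logger = logging.getLogger("monoflux")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; either a synthetic block or an
    input directory of delimited-text tables must be provided."""

    synthetic: ExperimentConfig | None = None
    input_dir: str | None = None
    out_dir: str | None = None
    # chamber QC
    deadband_s: float = 10.0
    min_points: int = 8
    r2_min: float = 0.90
    low_signal_ppm: float = 5.0
    max_gap_min: float = 30.0
    pressure_pa: float = chamber.STANDARD_PRESSURE_PA
    geometry: ChamberGeometry = ChamberGeometry()
    min_reps: int = 3
    # light response / saturation
    pfd_threshold: float = 1000.0
    # occasions
    drought_window: tuple[dt.date, dt.date] | None = None
    recovery_window: tuple[dt.date, dt.date] | None = None
    rst_campaign: str = "resistance"
    recovery_campaign: str = "recovery1"
    # permutation inference
    run_stats: bool = True
    n_perm: int = 4999
    seed: int = 0
    # isotope
    r_standard: float = isotope.R_STANDARD_AIR_N2
    applied_label_mg: float = 2.0
    monolith_area_m2: float = isotope.MONOLITH_AREA_M2
    # water balance
    effective_depth_mm: float = canopy.MONOLITH_DEPTH_MM
    write_plot: bool = False

    def __post_init__(self) -> None:
        if self.synthetic is None and self.input_dir is None:
            raise ValueError("PipelineConfig needs a synthetic block or an input_dir")
        if self.synthetic is not None:
            if self.drought_window is None:
                self.drought_window = self.synthetic.drought_window
            if self.recovery_window is None:
                self.recovery_window = self.synthetic.recovery_window
            self.applied_label_mg = self.synthetic.applied_label_mg
            self.monolith_area_m2 = self.synthetic.monolith_area_m2
            self.pressure_pa = self.synthetic.pressure_pa
            self.geometry = self.synthetic.geometry
        if self.drought_window is None or self.recovery_window is None:
            raise ValueError("drought_window and recovery_window are required in input mode")

    # -- flat key-value (YAML) round trip -----------------------------------
    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            for key in ("dates",):
                if key in syn:
                    syn[key] = tuple(_as_date(d) for d in syn[key])
            for key in ("drought_window", "recovery_window"):
                if key in syn:
                    syn[key] = tuple(_as_date(d) for d in syn[key])
            if "harvest_campaigns" in syn:
                syn["harvest_campaigns"] = {
                    k: _as_date(v) for k, v in syn["harvest_campaigns"].items()
                }
            for key in ("land_uses", "treatments"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "geometry" in syn:
                syn["geometry"] = ChamberGeometry(**syn["geometry"])
            syn = ExperimentConfig(**syn)
        for key in ("drought_window", "recovery_window"):
            if raw.get(key) is not None:
                raw[key] = tuple(_as_date(d) for d in raw[key])
        if "geometry" in raw:
            raw["geometry"] = ChamberGeometry(**raw["geometry"])
        return cls(synthetic=syn, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict[str, Any]:
        def convert(obj):
            if isinstance(obj, dt.date):
                return obj.isoformat()
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            return obj

        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if f.name == "synthetic" and val is not None:
                syn = {k: convert(v) for k, v in dataclasses.asdict(val).items()}
                val = syn
            elif isinstance(val, ChamberGeometry):
                val = dataclasses.asdict(val)
            else:
                val = convert(val)
            out[f.name] = val
        return out


def _as_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass
class PipelineResult:
    config: PipelineConfig
    tables: dict[str, pd.DataFrame]
    trajectories: dict[str, resilience.NormalizedTrajectory]
    ground_truth: synthetic.GroundTruth | None
    stage_counts: list[dict[str, Any]] = field(default_factory=list)
    log_lines: list[str] = field(default_factory=list)

    def summary(self, parameter: str, land_use: str) -> pd.Series:
        t = self.tables["resilience_summary"]
        row = t[(t["parameter"] == parameter) & (t["land_use"] == land_use)]
        if row.empty:
            raise KeyError(f"no resilience summary for {parameter} / {land_use}")
        return row.iloc[0]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and return the result bundle; deterministic for a
    fixed config (including seeds)."""
    counts: list[dict[str, Any]] = []
    lines: list[str] = []

    def log(stage: str, n_in: int, n_out: int, **dropped) -> None:
        entry = {"stage": stage, "in": int(n_in), "out": int(n_out), "dropped": dropped}
        counts.append(entry)
        msg = f"{stage}: {n_in} in, {n_out} out"
        if dropped:
            msg += ", dropped " + ", ".join(f"{k}={v}" for k, v in dropped.items())
        lines.append(msg)
        logger.info(msg)

    # ---- stage 0: inputs ---------------------------------------------------
    truth = None
    if config.synthetic is not None:
        exp = synthetic.generate_experiment(config.synthetic)
        data = {
            "monoliths": exp.monoliths,
            "chamber_series": exp.chamber_series,
            "harvest": exp.harvest,
            "isotope": exp.isotope,
            "water_balance": exp.water_balance,
            "soil_moisture": exp.soil_moisture,
        }
        truth = synthetic.ground_truth(config.synthetic)
        lines.append(f"simulated experiment with seed {config.synthetic.seed}")
    else:
        data = synthetic.read_experiment(config.input_dir)

    monoliths = data["monoliths"]
    tables: dict[str, pd.DataFrame] = {"monoliths": monoliths}

    # ---- stage 1: chamber slopes + fluxes ----------------------------------
    series_flux = _series_fluxes(data["chamber_series"], config)
    n_pass = int(series_flux["qc_pass"].sum())
    log("slope_qc", len(series_flux), n_pass,
        **series_flux.loc[~series_flux["qc_pass"], "qc_reason"].value_counts().to_dict())
    tables["series_flux"] = series_flux

    # ---- stage 2: pairing & partitioning ----------------------------------
    flux_records, n_orphan = _pair_fluxes(series_flux, config)
    flux_records = flux_records.merge(monoliths, on="monolith_id", how="left")
    log("pairing", n_pass, len(flux_records), orphan_sunlit=n_orphan)
    tables["flux_records"] = flux_records

    # ---- stage 3: replicate filter -----------------------------------------
    retained_dates, kept = chamber.replicate_filter(flux_records, config.min_reps)
    log("replicate_filter", len(flux_records), len(kept),
        days_dropped=len(set(flux_records["date"])) - len(retained_dates))
    kept = kept[kept["qc_pass"]].copy()
    tables["flux_records_qc"] = kept

    # ---- stage 4: light-response fits --------------------------------------
    fits = []
    for (lu, tr), grp in kept.groupby(["land_use", "treatment"], observed=True):
        try:
            fit = lightresponse.fit_light_response(
                grp["gpp"].to_numpy(), grp["par"].to_numpy(), group=f"{lu}:{tr}"
            )
            fits.append(
                {
                    "land_use": lu, "treatment": tr, "alpha": fit.alpha,
                    "p_max": fit.p_max, "r_squared": fit.r_squared, "n_obs": fit.n_obs,
                    "saturation_fraction": lightresponse.saturation_fraction(
                        fit, config.pfd_threshold
                    ),
                }
            )
        except lightresponse.LightResponseError as exc:
            lines.append(f"light_response {lu}:{tr} failed: {exc.reason}")
    tables["light_response"] = pd.DataFrame(fits)

    # ---- stage 5: saturation filter ----------------------------------------
    gpp_sat = lightresponse.saturation_filter(kept, config.pfd_threshold)
    log("saturation_filter", len(kept), len(gpp_sat))
    tables["gpp_sat"] = gpp_sat

    # ---- stage 6: normalization, trajectories, flux resilience -------------
    means = pd.concat(
        [
            resilience.daily_group_means(gpp_sat, "gpp", "gpp_sat"),
            resilience.daily_group_means(kept, "er", "er"),
        ],
        ignore_index=True,
    )
    tables["daily_means"] = means
    norm = resilience.normalize_fluxes(means)
    tables["normalized"] = norm

    trajectories: dict[str, resilience.NormalizedTrajectory] = {}
    summary_rows = []
    d0, d1 = config.drought_window
    r0, r1 = config.recovery_window
    for lu, norm_lu in norm.groupby("land_use", observed=True):
        points = norm_lu.pivot(index="date", columns="variable", values="norm").reset_index()
        points = points.rename(columns={"gpp_sat": "norm_gpp_sat", "er": "norm_er"}).dropna()
        if len(points) >= 2:
            trajectories[lu] = resilience.trajectory_metrics(
                points[["date", "norm_gpp_sat", "norm_er"]]
            )
        peak_dates = [d for d in points["date"] if d0 <= d <= d1]
        if not peak_dates:
            lines.append(f"resilience {lu}: no retained date inside the drought window")
            continue
        peak = max(peak_dates)
        rec_dates = [d for d in points["date"] if r0 <= d <= r1]
        for var, col in (("gpp_sat", "norm_gpp_sat"), ("er", "norm_er")):
            rst = float(points.loc[points["date"] == peak, col].iloc[0])
            if rec_dates:
                d_over_c = float(points.loc[points["date"].isin(rec_dates), col].mean())
                ri = d_over_c - rst
            else:
                d_over_c, ri = np.nan, np.nan
            summary_rows.append(
                {
                    "parameter": var, "land_use": lu, "resistance": rst,
                    "recovery_ratio": d_over_c, "recovery_index": ri,
                    "peak_date": peak,
                }
            )

    # ---- stage 7: harvest (LAI, CWM, biomass) ------------------------------
    harvest = data["harvest"].copy()
    if "date" in harvest.columns:
        harvest["date"] = pd.to_datetime(harvest["date"]).dt.date
    per_mono = (
        harvest.groupby(["campaign", "monolith_id"], observed=True)
        .apply(_harvest_indices, include_groups=False)
        .reset_index()
    )
    per_mono = per_mono.merge(monoliths, on="monolith_id", how="left")
    tables["canopy"] = per_mono
    for lu in per_mono["land_use"].dropna().unique():
        sub = per_mono[per_mono["land_use"] == lu]
        for parameter in ("lai", "biomass"):
            try:
                rst = _group_ratio(sub, config.rst_campaign, parameter)
                ratio_rec = _group_ratio(sub, config.recovery_campaign, parameter)
            except ValueError as exc:
                lines.append(f"harvest resilience {lu}/{parameter}: {exc}")
                continue
            summary_rows.append(
                {
                    "parameter": parameter, "land_use": lu, "resistance": rst,
                    "recovery_ratio": ratio_rec,
                    "recovery_index": resilience.recovery_index(ratio_rec, 1.0, rst),
                    "peak_date": config.rst_campaign,
                }
            )
    tables["resilience_summary"] = pd.DataFrame(summary_rows)

    # ---- stage 8: isotope budget -------------------------------------------
    iso = data["isotope"].merge(monoliths, on="monolith_id", how="left")
    iso["atom_percent"] = isotope.delta_to_atom_percent(
        iso["delta15n_permil"].to_numpy(), config.r_standard
    )
    iso["n_pool_mg_m2"] = isotope.nitrogen_pool(iso["n_conc_mg_g"], iso["dry_mass_g_m2"])
    tables["isotope_samples"] = iso
    budget_rows = []
    for (lu, tr), grp in iso.groupby(["land_use", "treatment"], observed=True):
        fractions = isotope.label_budget(
            grp, config.applied_label_mg, config.monolith_area_m2
        )
        for tissue, frac in fractions.items():
            budget_rows.append(
                {
                    "land_use": lu, "treatment": tr, "tissue": tissue,
                    "recovery_fraction": frac,
                    "recovered_mg": frac * config.applied_label_mg,
                }
            )
    budget = pd.DataFrame(budget_rows)
    tables["label_budget"] = budget

    # ---- stage 9: water balance --------------------------------------------
    water = data["water_balance"].copy()
    et_rows = []
    for row in water.itertuples(index=False):
        res = canopy.evapotranspiration(
            row.water_in_mm, row.leachate_mm, row.theta_start, row.theta_end,
            getattr(row, "effective_depth_mm", config.effective_depth_mm),
        )
        et_rows.append({"et_mm": res.et_mm, "delta_storage_mm": res.delta_storage_mm,
                        "suspect": res.suspect})
    water = pd.concat([water.reset_index(drop=True), pd.DataFrame(et_rows)], axis=1)
    water = water.merge(monoliths, on="monolith_id", how="left")
    n_suspect = int(water["suspect"].sum())
    if n_suspect:
        lines.append(f"water_balance: {n_suspect} physically suspect ET values flagged")
    tables["water_balance"] = water

    # ---- stage 10: permutation inference -----------------------------------
    if config.run_stats:
        tables["perm_tests"] = _permutation_tests(
            kept, gpp_sat, per_mono, iso, water, config, retained_dates
        )

    # ---- outputs ------------------------------------------------------------
    result = PipelineResult(
        config=config, tables=tables, trajectories=trajectories,
        ground_truth=truth, stage_counts=counts, log_lines=lines,
    )
    if config.out_dir:
        _write_outputs(result)
    return result


def _series_fluxes(chamber_long: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Batch slope fit + QC + unit conversion, one row per enclosure."""
    df = chamber_long
    dt_col = pd.to_datetime(df["datetime"])
    keys = pd.MultiIndex.from_arrays(
        [df["monolith_id"], dt_col, df["mode"]], names=["monolith_id", "datetime", "mode"]
    )
    codes, uniques = pd.factorize(keys, sort=True)
    mask = df["elapsed_s"].to_numpy(dtype=float) >= config.deadband_s
    fit = chamber.grouped_ols(
        codes[mask],
        df["elapsed_s"].to_numpy(dtype=float)[mask],
        df["co2_ppm"].to_numpy(dtype=float)[mask],
        len(uniques),
    )
    meta = (
        df.assign(_code=codes)
        .groupby("_code", observed=True)
        .agg(air_temp_c=("air_temp_c", "first"), par=("par", "first"))
    )
    out = pd.DataFrame(list(uniques), columns=["monolith_id", "datetime", "mode"])
    out["air_temp_c"] = meta["air_temp_c"].to_numpy()
    out["par"] = meta["par"].to_numpy()
    out["slope"] = fit["slope"]
    out["r_squared"] = fit["r_squared"]
    out["n_used"] = fit["n"]

    r2 = fit["r_squared"]
    no_signal = np.isnan(r2) & (fit["n"] >= 2)
    low_signal = np.abs(fit["slope"]) * fit["span_s"] <= config.low_signal_ppm
    qc_pass = (fit["n"] >= config.min_points) & ~no_signal & (
        (r2 >= config.r2_min) | low_signal
    )
    reason = np.full(len(out), "ok", dtype=object)
    reason[(r2 < config.r2_min) & low_signal] = "low_signal"
    reason[(fit["n"] < config.min_points)] = "too_few_points"
    reason[no_signal] = "no_signal"
    reason[~qc_pass & (reason == "ok")] = "poor_fit"
    out["qc_pass"] = qc_pass
    out["qc_reason"] = reason
    out["flux"] = chamber.slope_to_flux(
        fit["slope"], out["air_temp_c"].to_numpy(), config.pressure_pa, config.geometry
    )
    out["date"] = pd.to_datetime(out["datetime"]).dt.date
    return out


def _pair_fluxes(series_flux: pd.DataFrame, config: PipelineConfig) -> tuple[pd.DataFrame, int]:
    """Pair each QC-passing sunlit series with the nearest QC-passing dark
    series of the same monolith and day; returns records and orphan count."""
    ok = series_flux[series_flux["qc_pass"]]
    sun = ok[ok["mode"] == "sunlit"]
    dark = ok[ok["mode"] == "dark"][["monolith_id", "date", "datetime", "flux"]].rename(
        columns={"datetime": "dark_datetime", "flux": "er_flux"}
    )
    merged = sun.merge(dark, on=["monolith_id", "date"], how="left")
    merged["gap_min"] = (
        (pd.to_datetime(merged["datetime"]) - pd.to_datetime(merged["dark_datetime"]))
        .abs()
        .dt.total_seconds()
        / 60.0
    )
    merged = merged[merged["gap_min"] <= config.max_gap_min]
    merged = merged.sort_values("gap_min").groupby(
        ["monolith_id", "datetime"], observed=True, as_index=False
    ).first()
    n_orphan = len(sun) - len(merged)

    nee = merged["flux"].to_numpy()
    er = merged["er_flux"].to_numpy()
    gpp = er - nee
    qc_pass = np.ones(len(merged), dtype=bool)
    reason = np.full(len(merged), "ok", dtype=object)
    reason[gpp < 0] = "negative_gpp"
    reason[er < 0] = "negative_er"
    qc_pass[(gpp < 0) | (er < 0)] = False
    records = pd.DataFrame(
        {
            "monolith_id": merged["monolith_id"],
            "date": merged["date"],
            "datetime": merged["datetime"],
            "nee": nee,
            "er": er,
            "gpp": gpp,
            "par": merged["par"],
            "qc_pass": qc_pass,
            "qc_reason": reason,
        }
    )
    return records, n_orphan


def _harvest_indices(grp: pd.DataFrame) -> pd.Series:
    living = grp[["leaf_biomass", "stem_biomass", "reproductive_biomass"]].sum().sum()
    return pd.Series(
        {
            "lai": canopy.lai(grp),
            "cwm_sla": canopy.cwm_sla(grp),
            "biomass": living,
            "necromass": grp["necromass"].sum(),
        }
    )


def _group_ratio(per_mono: pd.DataFrame, campaign: str, parameter: str) -> float:
    sub = per_mono[per_mono["campaign"] == campaign]
    if sub.empty:
        raise ValueError(f"no harvest data for campaign {campaign!r}")
    means = sub.groupby("treatment", observed=True)[parameter].mean()
    if "control" not in means or "drought" not in means:
        raise ValueError(f"campaign {campaign!r} lacks a treatment level")
    return resilience.resistance(float(means["drought"]), float(means["control"]))


def _permutation_tests(
    kept: pd.DataFrame,
    gpp_sat: pd.DataFrame,
    per_mono: pd.DataFrame,
    iso: pd.DataFrame,
    water: pd.DataFrame,
    config: PipelineConfig,
    retained_dates,
) -> pd.DataFrame:
    """Treatment x land-use permutation ANOVA per occasion, plus
    within-land-use drought tests."""
    rows: list[permstats.PermTestResult] = []
    rng = np.random.default_rng(config.seed)

    def occasions(df):
        d0, d1 = config.drought_window
        occ = []
        pre = [d for d in retained_dates if d < d0]
        if pre:
            occ.append(("pretreatment", max(pre)))
        within = [d for d in retained_dates if d0 <= d <= d1]
        if within:
            occ.append(("peak_drought", max(within)))
        r0, r1 = config.recovery_window
        for i, d in enumerate([d for d in retained_dates if d > d1], start=1):
            occ.append((f"recovery{i}", d))
        return occ

    def run_factorial(df, value, occasion_label, day):
        sub = df[df["date"] == day]
        per = sub.groupby(["monolith_id", "land_use", "treatment"], observed=True)[
            value
        ].mean().reset_index()
        seed = int(rng.integers(2**31 - 1))
        try:
            rows.extend(
                permstats.two_way_perm_anova(
                    per[value].to_numpy(), per["treatment"], per["land_use"],
                    n_perm=config.n_perm, seed=seed, response=value,
                    occasion=occasion_label,
                )
            )
            for lu, lu_grp in per.groupby("land_use", observed=True):
                rows.append(
                    permstats.within_group_perm_test(
                        lu_grp[value].to_numpy(), lu_grp["treatment"],
                        n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1)),
                        response=value, occasion=occasion_label,
                        factor=f"treatment_within_{lu}",
                    )
                )
        except ValueError as exc:
            logger.info("perm test skipped (%s %s): %s", value, occasion_label, exc)

    for label, day in occasions(gpp_sat):
        run_factorial(gpp_sat, "gpp", label, day)
    for label, day in occasions(kept):
        run_factorial(kept, "er", label, day)

    for campaign, grp in per_mono.groupby("campaign", observed=True):
        for value in ("biomass", "lai"):
            seed = int(rng.integers(2**31 - 1))
            try:
                rows.extend(
                    permstats.two_way_perm_anova(
                        grp[value].to_numpy(), grp["treatment"], grp["land_use"],
                        n_perm=config.n_perm, seed=seed, response=value,
                        occasion=str(campaign),
                    )
                )
            except ValueError as exc:
                logger.info("perm test skipped (%s %s): %s", value, campaign, exc)

    # shoot label uptake at the labelling harvest
    shoots = iso[(iso["tissue"] == "shoot") & iso["labelled"]]
    if not shoots.empty:
        na_ref = (
            iso[(iso["tissue"] == "shoot") & ~iso["labelled"]]
            .groupby("land_use", observed=True)["atom_percent"].mean()
        )
        for lu, grp in shoots.groupby("land_use", observed=True):
            inc = isotope.incorporated_15n(
                grp["atom_percent"].to_numpy(), float(na_ref[lu]),
                grp["n_pool_mg_m2"].to_numpy(),
            )
            try:
                rows.append(
                    permstats.within_group_perm_test(
                        inc, grp["treatment"], n_perm=config.n_perm,
                        seed=int(rng.integers(2**31 - 1)),
                        response="shoot_15n", occasion="labelling",
                        factor=f"treatment_within_{lu}",
                    )
                )
            except ValueError as exc:
                logger.info("perm test skipped (shoot_15n %s): %s", lu, exc)

    # evapotranspiration over the rain exclusion
    try:
        rows.extend(
            permstats.two_way_perm_anova(
                water["et_mm"].to_numpy(), water["treatment"], water["land_use"],
                n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1)),
                response="et", occasion="rain_exclusion",
            )
        )
    except ValueError as exc:
        logger.info("perm test skipped (et): %s", exc)

    table = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if not table.empty:
        table["stars"] = [permstats.significance_stars(p) for p in table["p_perm"]]
    return table


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in result.tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    for lu, traj in result.trajectories.items():
        seg = traj.points.copy()
        seg["segment_distance"] = np.concatenate([[np.nan], traj.segment_distances])
        seg["cumulative_distance"] = traj.cumulative_distance
        seg.to_csv(out / f"trajectory_{lu}.tsv", sep="\t", index=False)
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(result.log_lines) + "\n")
    if result.config.write_plot and result.trajectories:
        plot_trajectories(result.trajectories, out / "trajectories.png")


def plot_trajectories(trajectories, path) -> None:
    """Basic bivariate trajectory plot (normalized GPP_sat vs ER)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for lu, traj in trajectories.items():
        ax.plot(
            traj.points["norm_gpp_sat"], traj.points["norm_er"], marker="o",
            label=f"{lu} (L={traj.cumulative_length:.2f})",
        )
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.axvline(1.0, color="grey", lw=0.5)
    ax.set_xlabel("normalized GPP$_{sat}$")
    ax.set_ylabel("normalized ER")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
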