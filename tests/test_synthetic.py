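"""Synthetic experiment generator: determinism, dynamics, ground truth."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from monoflux.chamber import R_GAS, ChamberGeometry, fit_concentration_slope, ChamberSeries
from monoflux.synthetic import (
    ConfigError,
    ExperimentConfig,
    FUNCTIONAL_GROUPS,
    generate_experiment,
    ground_truth,
    normalized_flux_path,
)


def _lu(meadow, abandoned):
    return {"meadow": meadow, "abandoned": abandoned}


class TestConfigValidation:
    def test_defaults_valid(self):
        ExperimentConfig()

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_blocks": 2}, "n_blocks"),
            ({"resistance_gpp": _lu(0.0, 0.4)}, "resistance_gpp"),
            ({"resistance_gpp": _lu(1.5, 0.4)}, "resistance_gpp"),
            ({"er_overshoot": _lu(0.9, 1.0)}, "er_overshoot"),
            ({"noise_sd_ppm": -1.0}, "noise_sd_ppm"),
            (
                {"drought_window": (dt.date(2014, 6, 28), dt.date(2014, 5, 21))},
                "drought_window",
            ),
            ({"treatments": ("control",)}, "treatments"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError) as err:
            ExperimentConfig(**kwargs)
        assert err.value.field_name == field


class TestDeterminism:
    def test_same_seed_byte_identical_tables(self):
        cfg = ExperimentConfig(seed=77)
        e1 = generate_experiment(cfg)
        e2 = generate_experiment(cfg)
        for name in e1._TABLES:
            csv1 = getattr(e1, name).to_csv(index=False)
            csv2 = getattr(e2, name).to_csv(index=False)
            assert csv1 == csv2, name

    def test_different_seed_differs(self):
        c1 = generate_experiment(ExperimentConfig(seed=1)).chamber_series
        c2 = generate_experiment(ExperimentConfig(seed=2)).chamber_series
        assert not np.allclose(c1["co2_ppm"], c2["co2_ppm"])


class TestZeroNoise:
    def test_chamber_slopes_equal_true_flux_implied_slopes(self, zero_noise_config):
        exp = generate_experiment(zero_noise_config)
        cfg = zero_noise_config
        gt_path = {lu: normalized_flux_path(cfg, lu).set_index("date") for lu in cfg.land_uses}
        mono = exp.monoliths.set_index("monolith_id")
        df = exp.chamber_series
        # check every dark (ER) series on standard occasions
        dark = df[df["mode"] == "dark"]
        checked = 0
        for (mid, ts), grp in dark.groupby(["monolith_id", "datetime"]):
            lu = mono.loc[mid, "land_use"]
            tr = mono.loc[mid, "treatment"]
            day = ts.date() if hasattr(ts, "date") else ts
            if day not in gt_path[lu].index:
                continue
            norm = gt_path[lu].loc[day, "norm_er"] if tr == "drought" else 1.0
            er_true = norm * cfg.true_er_base[lu]
            temp = grp["air_temp_c"].iloc[0]
            implied = er_true * R_GAS * (temp + 273.15) / cfg.pressure_pa / cfg.geometry.effective_height_m
            fit = fit_concentration_slope(
                ChamberSeries(mid, ts.to_pydatetime(), "dark", grp["elapsed_s"].to_numpy(),
                              grp["co2_ppm"].to_numpy(), temp, None)
            )
            assert fit.slope == pytest.approx(implied, rel=1e-12)
            checked += 1
            if checked >= 30:
                break
        assert checked >= 30

    def test_no_perturbation_limit_zero_recovery_indices(self):
        cfg = ExperimentConfig(
            resistance_gpp=_lu(1.0, 1.0),
            resistance_er=_lu(1.0, 1.0),
            er_overshoot=_lu(1.0, 1.0),
            resistance_lai=_lu(1.0, 1.0),
            resistance_biomass=_lu(1.0, 1.0),
        )
        gt = ground_truth(cfg)
        for lu in cfg.land_uses:
            t = gt[lu]
            assert t.rst_gpp_sat == 1.0 and t.rst_er == 1.0
            for ri in (t.ri_gpp_sat, t.ri_er, t.ri_lai, t.ri_biomass):
                assert ri == pytest.approx(0.0, abs=1e-12)
            assert t.trajectory_length == pytest.approx(0.0, abs=1e-12)

    def test_full_recovery_recovery_index_is_one_minus_rst(self):
        cfg = ExperimentConfig(
            resistance_gpp=_lu(0.5, 0.5),
            er_overshoot=_lu(1.0, 1.0),
            recovery_halftime=_lu(0.1, 0.1),  # effectively instant recovery
        )
        gt = ground_truth(cfg)
        assert gt["meadow"].ri_gpp_sat == pytest.approx(0.5, abs=1e-6)

    def test_trajectory_truth_equals_brute_force_sum(self, default_config):
        gt = ground_truth(default_config)
        for lu in default_config.land_uses:
            path = normalized_flux_path(default_config, lu)
            total = 0.0
            for i in range(1, len(path)):
                total += np.sqrt(
                    (path["norm_gpp_sat"][i] - path["norm_gpp_sat"][i - 1]) ** 2
                    + (path["norm_er"][i] - path["norm_er"][i - 1]) ** 2
                )
            assert gt[lu].trajectory_length == pytest.approx(total, rel=1e-12)

    def test_configured_resistance_realized_at_peak(self, default_config):
        gt = ground_truth(default_config)
        assert gt["meadow"].rst_gpp_sat == pytest.approx(0.2, abs=1e-12)
        assert gt["abandoned"].rst_gpp_sat == pytest.approx(0.4, abs=1e-12)


class TestDynamicsShape:
    def test_deeper_drought_never_shortens_trajectory(self, default_config):
        lengths = []
        for r in (0.8, 0.6, 0.4, 0.2):
            cfg = dataclasses.replace(default_config, resistance_gpp=_lu(r, r))
            lengths.append(ground_truth(cfg)["meadow"].trajectory_length)
        assert all(b >= a - 1e-12 for a, b in zip(lengths, lengths[1:]))

    def test_pretreatment_normalized_to_one(self, default_config):
        path = normalized_flux_path(default_config, "meadow")
        pre = path[path["date"] < default_config.drought_window[0]]
        assert np.allclose(pre["norm_gpp_sat"], 1.0) and np.allclose(pre["norm_er"], 1.0)

    def test_er_overshoot_after_rewetting(self, default_config):
        path = normalized_flux_path(default_config, "meadow")
        post = path[path["date"] > default_config.drought_window[1]]
        assert (post["norm_er"] > 1.0).all()


class TestSoilMoisture:
    def test_control_never_below_threshold(self, experiment, default_config):
        soil = experiment.soil_moisture
        ctl = soil[soil["treatment"] == "control"]
        assert (ctl["vwc_percent"] > default_config.soil_moisture_threshold).all()

    def test_drought_monotone_decline_then_rewetting_jump(self, experiment, default_config):
        d0, d1 = default_config.drought_window
        soil = experiment.soil_moisture
        dr = soil[(soil["treatment"] == "drought") & (soil["land_use"] == "meadow")]
        dr = dr.set_index("date").sort_index()
        window = dr.loc[str(d0): str(d1), "vwc_percent"]
        assert (np.diff(window.to_numpy()) <= 0).all()
        after = dr.loc[str(d1 + dt.timedelta(days=1)):, "vwc_percent"]
        assert after.iloc[0] > window.iloc[-1] + 5.0


class TestComposition:
    def test_functional_groups_cover_land_uses(self, default_config):
        for lu in default_config.land_uses:
            assert len(FUNCTIONAL_GROUPS[lu]) >= 2

    def test_harvest_has_three_campaigns_all_monoliths(self, experiment):
        h = experiment.harvest
        assert set(h["campaign"]) == {"resistance", "recovery1", "recovery2"}
        assert h.groupby("campaign")["monolith_id"].nunique().min() == 24
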