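"""Chamber slope fitting, QC, unit conversion, pairing and replicate filter."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from monoflux.chamber import (
    ChamberGeometry,
    ChamberSeries,
    DegenerateFitError,
    FluxFragment,
    PairingError,
    fit_concentration_slope,
    grouped_ols,
    pair_and_partition,
    replicate_filter,
    slope_to_flux,
)

T13 = np.arange(0.0, 61.0, 5.0)
NOON = dt.datetime(2014, 6, 1, 9, 0)


def series(co2, mode="dark", par=None, temp=20.0, t=T13):
    if mode == "sunlit" and par is None:
        par = 1500.0
    return ChamberSeries("m1", NOON, mode, t, np.asarray(co2, float), temp, par)


def sigma_formula_ols(t, y):
    """Independent closed-form OLS oracle."""
    n = len(t)
    sx, sy = t.sum(), y.sum()
    sxx, sxy, syy = (t * t).sum(), (t * y).sum(), (y * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
    r2 = (n * sxy - sx * sy) ** 2 / ((n * sxx - sx**2) * (n * syy - sy**2))
    return slope, r2


class TestSlopeFit:
    def test_exact_line_recovered(self):
        fit = fit_concentration_slope(series(400.0 + 0.5 * T13))
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(400.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.qc_pass and fit.qc_reason == "ok"

    def test_flat_series_fails_with_no_signal(self):
        fit = fit_concentration_slope(series(np.full(13, 400.0)))
        assert fit.slope == 0.0
        assert np.isnan(fit.r_squared)
        assert not fit.qc_pass and fit.qc_reason == "no_signal"

    def test_noisy_slope_matches_sigma_formula_oracle(self, rng):
        for _ in range(50):
            y = 400.0 + 0.8 * T13 + rng.normal(0, 1.0, T13.size)
            fit = fit_concentration_slope(series(y), deadband_s=10.0)
            mask = T13 >= 10.0
            slope, r2 = sigma_formula_ols(T13[mask], y[mask])
            assert fit.slope == pytest.approx(slope, rel=1e-12)
            assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    def test_deadband_discards_early_samples(self):
        y = 400.0 + 0.5 * T13
        y[:2] += 30.0  # disturbed start
        fit = fit_concentration_slope(series(y), deadband_s=10.0)
        assert fit.n_used == 11
        assert fit.slope == pytest.approx(0.5, abs=1e-12)

    def test_min_points_quality_gate(self):
        fit = fit_concentration_slope(series(400.0 + 0.5 * T13), deadband_s=45.0)
        assert not fit.qc_pass and fit.qc_reason == "too_few_points"

    def test_near_zero_flux_passes_as_low_signal(self, rng):
        y = 400.0 + 0.005 * T13 + rng.normal(0, 0.5, T13.size)
        fit = fit_concentration_slope(series(y))
        assert fit.qc_pass and fit.qc_reason == "low_signal"

    def test_large_poor_fit_rejected(self, rng):
        y = 400.0 + 0.2 * T13 + rng.normal(0, 8.0, T13.size)
        fit = fit_concentration_slope(series(y))
        assert not fit.qc_pass and fit.qc_reason == "poor_fit"

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateFitError):
            fit_concentration_slope(series(400.0 + 0.5 * T13), deadband_s=60.0)
        with pytest.raises(ValueError):
            ChamberSeries("m1", NOON, "dark", [0.0, 0.0], [400.0, 401.0], 20.0, None)

    def test_grouped_ols_matches_scalar_path(self, rng):
        slopes = rng.uniform(-0.6, 0.6, 40)
        ys = 400.0 + slopes[:, None] * T13[None, :] + rng.normal(0, 1.0, (40, 13))
        idx = np.repeat(np.arange(40), 13)
        mask = np.tile(T13, 40) >= 10.0
        batch = grouped_ols(idx[mask], np.tile(T13, 40)[mask], ys.ravel()[mask], 40)
        for i in range(40):
            fit = fit_concentration_slope(series(ys[i]), deadband_s=10.0)
            assert batch["slope"][i] == pytest.approx(fit.slope, rel=1e-10)
            assert batch["r_squared"][i] == pytest.approx(fit.r_squared, rel=1e-10)


class TestSlopeToFlux:
    def test_zero_slope_zero_flux(self):
        assert slope_to_flux(0.0, 20.0) == 0.0

    def test_hand_calculated_reference_value(self):
        # molar density 101325/(8.3145*293.15) = 41.57 mol m^-3, x 0.5 m
        flux = slope_to_flux(-0.5, 20.0, 101325.0, ChamberGeometry(0.25, 0.50))
        assert flux == pytest.approx(-10.39, abs=0.005)

    def test_linear_in_height_and_slope(self):
        g1 = ChamberGeometry(0.25, 0.50)
        g2 = ChamberGeometry(0.25, 1.00)
        assert slope_to_flux(-0.5, 20.0, geometry=g2) == pytest.approx(
            2 * slope_to_flux(-0.5, 20.0, geometry=g1)
        )
        assert slope_to_flux(-1.0, 20.0) == pytest.approx(2 * slope_to_flux(-0.5, 20.0))

    def test_headspace_adds_to_effective_height(self):
        g = ChamberGeometry(0.25, 0.50, headspace_m=0.10)
        ref = ChamberGeometry(0.25, 0.60)
        assert slope_to_flux(0.3, 15.0, geometry=g) == pytest.approx(
            slope_to_flux(0.3, 15.0, geometry=ref)
        )

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            slope_to_flux(0.1, -60.0)
        with pytest.raises(ValueError):
            slope_to_flux(0.1, 20.0, pressure_pa=0.0)
        with pytest.raises(ValueError):
            ChamberGeometry(0.0, 0.5)


def frag(mode, flux, minutes=0, par=1500.0, monolith="m1", qc=True):
    return FluxFragment(
        monolith, NOON + dt.timedelta(minutes=minutes), mode, flux,
        par if mode == "sunlit" else None, qc,
    )


class TestPairAndPartition:
    @pytest.mark.parametrize(
        "nee,er,gpp,ok,reason",
        [
            (-15.0, 5.0, 20.0, True, "ok"),
            (5.0, 5.0, 0.0, True, "ok"),
            (6.0, 5.0, -1.0, False, "negative_gpp"),
            (1.0, -0.5, -1.5, False, "negative_er"),
        ],
    )
    def test_partition_identity_and_sign_guards(self, nee, er, gpp, ok, reason):
        rec = pair_and_partition(frag("sunlit", nee), frag("dark", er, minutes=2))
        assert rec.gpp == pytest.approx(gpp)
        assert rec.gpp == pytest.approx(rec.er - rec.nee)  # never clipped
        assert rec.qc_pass is ok and rec.qc_reason == reason

    def test_pairing_errors(self):
        with pytest.raises(PairingError, match="monolith"):
            pair_and_partition(frag("sunlit", -5.0), frag("dark", 5.0, monolith="m2"))
        with pytest.raises(PairingError, match="unpaired"):
            pair_and_partition(frag("sunlit", -5.0), frag("dark", 5.0, minutes=45))
        with pytest.raises(PairingError):
            pair_and_partition(frag("dark", 5.0), frag("dark", 5.0))


def records_frame(cell_counts, day=dt.date(2014, 6, 1)):
    rows = []
    for (lu, tr), n in cell_counts.items():
        for i in range(n):
            rows.append({"date": day, "land_use": lu, "treatment": tr, "qc_pass": True})
    return pd.DataFrame(rows)


class TestReplicateFilter:
    CELLS = [("meadow", "control"), ("meadow", "drought"),
             ("abandoned", "control"), ("abandoned", "drought")]

    def test_day_with_full_cells_retained(self):
        df = records_frame({c: 3 for c in self.CELLS})
        retained, kept = replicate_filter(df)
        assert retained == [dt.date(2014, 6, 1)] and len(kept) == 12

    def test_one_short_cell_drops_the_day(self):
        counts = {c: 3 for c in self.CELLS}
        counts[("abandoned", "control")] = 2
        retained, kept = replicate_filter(records_frame(counts))
        assert retained == [] and kept.empty

    def test_degenerate_threshold_retains_any_nonempty_cells(self):
        df = records_frame({c: 1 for c in self.CELLS})
        retained, _ = replicate_filter(df, min_reps=1)
        assert retained == [dt.date(2014, 6, 1)]

    def test_failing_qc_records_do_not_count(self):
        df = records_frame({c: 3 for c in self.CELLS})
        df.loc[df.index[:1], "qc_pass"] = False
        retained, _ = replicate_filter(df)
        assert retained == []


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    slope=st.floats(-1.0, 1.0),
    temp=st.floats(-20.0, 40.0),
    height=st.floats(0.1, 2.0),
)
def test_flux_conversion_linearity_property(slope, temp, height):
    g = ChamberGeometry(0.25, height)
    f1 = slope_to_flux(slope, temp, geometry=g)
    f2 = slope_to_flux(2 * slope, temp, geometry=g)
    assert f2 == pytest.approx(2 * f1, rel=1e-12, abs=1e-12)
    assert slope_to_flux(0.0, temp, geometry=g) == 0.0
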