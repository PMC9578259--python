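"""Quantitative physiology: growth-rate fits, batch/chemostat yields,
wash-in kinetics and electron recoveries."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from redoxferm import (
    BiomassParameters,
    CultureSeries,
    DegenerateRegressionError,
    DomainError,
    InsufficientDataError,
    Measurement,
    ParseError,
    SteadyState,
    WashinParams,
    batch_stoichiometry,
    chemostat_rates,
    correct_ethanol_evaporation,
    default_registry,
    detect_consumption_loss,
    fit_growth_rate,
    pooled_steady_state,
    predict,
    reduction_recovery,
    reduction_recovery_chemostat,
    washin_concentration,
)


def exponential_series(mu=0.30, x0=0.10, n=10, dt=0.8, stoich=(16.2, 1.47, 11.8, 0.0)):
    """Noise-free batch series with exact exponential growth and fixed
    product stoichiometry (helper independent of the simulate module)."""
    y_x, y_eth, gly_per_x, sorb_per_x = stoich
    reg = default_registry()
    t = np.arange(n) * dt
    X = x0 * np.exp(mu * t)
    dX = X - x0
    glc_mol = dX / y_x
    df = pd.DataFrame({
        "time_h": t,
        "biomass_gL": X,
        "glucose_gL": 20.0 - glc_mol * reg.molar_mass("glucose"),
        "sorbitol_gL": 30.0 - sorb_per_x * dX / 1000 * reg.molar_mass("sorbitol"),
        "ethanol_gL": y_eth * glc_mol * reg.molar_mass("ethanol"),
        "glycerol_gL": gly_per_x * dX / 1000 * reg.molar_mass("glycerol"),
    })
    return CultureSeries(data=df)


class TestCultureSeries:
    def test_requires_time_and_biomass_columns(self):
        with pytest.raises(ParseError):
            CultureSeries(pd.DataFrame({"time_h": [0, 1]}))

    def test_rejects_non_increasing_time(self):
        df = pd.DataFrame({"time_h": [0.0, 1.0, 1.0], "biomass_gL": [1, 2, 3]})
        with pytest.raises(ParseError):
            CultureSeries(df)

    def test_rejects_missing_values(self):
        df = pd.DataFrame({"time_h": [0.0, 1.0], "biomass_gL": [1.0, np.nan]})
        with pytest.raises(ParseError):
            CultureSeries(df)

    def test_rejects_misnamed_columns(self):
        df = pd.DataFrame({"time_h": [0.0], "biomass_gL": [1.0], "glucose": [5.0]})
        with pytest.raises(ParseError):
            CultureSeries(df)


class TestFitGrowthRate:
    def test_noise_free_is_exact(self):
        series = exponential_series(mu=0.30)
        fit = fit_growth_rate(series)
        assert fit.mu == pytest.approx(0.30, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_six_points_insufficient(self):
        series = exponential_series(n=6)
        with pytest.raises(InsufficientDataError):
            fit_growth_rate(series)

    def test_explicit_window(self):
        series = exponential_series(mu=0.27, n=12)
        fit = fit_growth_rate(series, window=(2.0, 9.0))
        assert fit.n_points == 9
        assert fit.mu == pytest.approx(0.27, abs=1e-12)

    def test_ci_covers_truth_under_noise(self):
        """95% CI coverage over 100 seeded noisy series (5% multiplicative
        noise on biomass, 10 samples, mu = 0.27)."""
        mu_true = 0.27
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            series = exponential_series(mu=mu_true, n=10)
            df = series.data.copy()
            df["biomass_gL"] = df["biomass_gL"] * rng.lognormal(0.0, 0.05, len(df))
            noisy = CultureSeries(df)
            fit = fit_growth_rate(noisy, window=(0.0, 9.0))
            if fit.ci_low <= mu_true <= fit.ci_high:
                covered += 1
        assert covered >= 85

    def test_auto_window_skips_stationary_phase(self):
        series = exponential_series(mu=0.30, n=9)
        df = series.data.copy()
        # append a stationary plateau
        plateau = df.iloc[[-1]].copy()
        rows = [df]
        for k in range(1, 5):
            p = plateau.copy()
            p["time_h"] += 2.0 * k
            rows.append(p)
        full = CultureSeries(pd.concat(rows, ignore_index=True))
        fit = fit_growth_rate(full)
        assert fit.mu == pytest.approx(0.30, abs=1e-9)


class TestBatchStoichiometry:
    def test_noise_free_round_trip(self):
        series = exponential_series(stoich=(16.2, 1.47, 11.8, 4.3))
        out = batch_stoichiometry(series, window=(0.0, 9.0))
        assert out.y_biomass_g_per_mol == pytest.approx(16.2, abs=1e-9)
        assert out.y_ethanol_mol_per_mol == pytest.approx(1.47, abs=1e-9)
        assert out.glycerol_per_biomass_mmol_per_g == pytest.approx(11.8, abs=1e-9)
        assert not out.sorbitol_per_biomass.censored
        assert out.sorbitol_per_biomass.value == pytest.approx(4.3, abs=1e-9)

    def test_combined_substrate_yield_below_glucose_yield(self):
        series = exponential_series(stoich=(16.2, 1.47, 11.8, 5.4))
        out = batch_stoichiometry(series, window=(0.0, 9.0))
        assert out.y_ethanol_substrates_mol_per_mol < out.y_ethanol_mol_per_mol

    def test_small_yields_within_three_percent_under_noise(self):
        """2% multiplicative noise, fixed seed: yields within 3% of truth."""
        rng = np.random.default_rng(7)
        series = exponential_series(n=12, stoich=(16.2, 1.47, 11.8, 0.0))
        df = series.data.copy()
        for col in df.columns:
            if col != "time_h":
                df[col] = df[col] * rng.lognormal(0.0, 0.02, len(df))
        out = batch_stoichiometry(CultureSeries(df), window=(0.0, 11.0))
        assert out.y_ethanol_mol_per_mol == pytest.approx(1.47, rel=0.03)
        assert out.y_biomass_g_per_mol == pytest.approx(16.2, rel=0.03)

    def test_constant_glucose_degenerate(self):
        series = exponential_series()
        df = series.data.copy()
        df["glucose_gL"] = 20.0
        with pytest.raises(DegenerateRegressionError):
            batch_stoichiometry(CultureSeries(df), window=(0.0, 9.0))

    def test_undetectable_sorbitol_reported_as_censored_bound(self):
        series = exponential_series(stoich=(16.2, 1.47, 11.8, 0.0))
        out = batch_stoichiometry(series, window=(0.0, 9.0))
        assert out.sorbitol_per_biomass.censored
        assert str(out.sorbitol_per_biomass).startswith("<")


class TestChemostatRates:
    def reference_state(self, per_biomass=27.0, Cx=1.18, D=0.025):
        reg = default_registry()
        delta = per_biomass * Cx * reg.molar_mass("sorbitol") / 1000.0
        return SteadyState(
            D=D,
            c_in={"glucose": 10.0, "sorbitol": 10.0},
            c_out={"glucose": 0.03, "sorbitol": 10.0 - delta,
                   "ethanol": 7.3, "glycerol": 0.11},
            Cx=Cx,
        )

    def test_engineered_strain_sorbitol_rate(self):
        """27.0 mmol per g biomass at D = 0.025 1/h gives q = 0.675."""
        quant = chemostat_rates(self.reference_state())
        assert quant.q["sorbitol"] == pytest.approx(0.675, abs=1e-9)
        assert quant.per_biomass["sorbitol"] == pytest.approx(27.0, abs=1e-9)

    def test_per_biomass_times_dilution_equals_q(self):
        quant = chemostat_rates(self.reference_state())
        for name in ("glucose", "sorbitol"):
            assert quant.per_biomass[name] * quant.D == \
                pytest.approx(quant.q[name], abs=1e-12)

    def test_no_consumption_gives_zero_rate(self):
        ss = SteadyState(D=0.025, c_in={"glucose": 10.0, "ethanol": 0.0},
                         c_out={"glucose": 5.0, "ethanol": 0.0}, Cx=1.0)
        quant = chemostat_rates(ss, substrates=("glucose",))
        assert quant.q["ethanol"] == pytest.approx(0.0, abs=1e-12)

    def test_residual_equal_to_feed_reported_censored(self):
        """A strain that cannot consume sorbitol leaves the feed untouched;
        the rate is reported as a detection bound, not a zero."""
        ss = SteadyState(D=0.025, c_in={"glucose": 10.0, "sorbitol": 10.0},
                         c_out={"glucose": 0.02, "sorbitol": 10.0,
                                "ethanol": 4.9, "glycerol": 1.0}, Cx=1.4)
        quant = chemostat_rates(ss)
        assert isinstance(quant.q["sorbitol"], Measurement)
        assert quant.q["sorbitol"].censored
        assert quant.q["sorbitol"].value < 0.05

    def test_nonpositive_biomass_rejected(self):
        with pytest.raises(DomainError):
            chemostat_rates(SteadyState(D=0.025, c_in={"glucose": 10.0},
                                        c_out={"glucose": 1.0}, Cx=0.0))

    def test_pooled_matches_single_replicate_average(self):
        a = self.reference_state(per_biomass=26.0)
        b = self.reference_state(per_biomass=28.0)
        pooled = chemostat_rates(pooled_steady_state([a, b]))
        assert pooled.per_biomass["sorbitol"] == pytest.approx(27.0, abs=1e-9)


class TestWashin:
    def test_boundary_value(self):
        p = WashinParams(c_in=10.0, c_t0=4.0, D=0.025, t0=400.0)
        assert washin_concentration(p, 400.0) == pytest.approx(4.0, abs=1e-12)

    def test_asymptote(self):
        p = WashinParams(c_in=10.0, c_t0=4.0, D=0.025)
        assert washin_concentration(p, 2000.0) == pytest.approx(10.0, abs=1e-6)

    def test_half_life_evaluation(self):
        p = WashinParams(c_in=10.0, c_t0=4.0, D=0.025)
        t_half = np.log(2) / 0.025
        assert washin_concentration(p, t_half) == pytest.approx(7.0, abs=1e-12)

    def test_before_event_rejected(self):
        p = WashinParams(c_in=10.0, c_t0=4.0, D=0.025, t0=400.0)
        with pytest.raises(DomainError):
            washin_concentration(p, 399.0)

    @settings(max_examples=40, derandomize=True)
    @given(
        c_in=st.floats(0.5, 50), c_t0=st.floats(0.0, 50),
        d=st.floats(0.005, 0.5),
    )
    def test_monotone_and_bounded(self, c_in, c_t0, d):
        p = WashinParams(c_in=c_in, c_t0=c_t0, D=d)
        t = np.linspace(0, 300, 200)
        c = washin_concentration(p, t)
        lo, hi = min(c_in, c_t0), max(c_in, c_t0)
        assert np.all(c >= lo - 1e-9) and np.all(c <= hi + 1e-9)
        diffs = np.diff(c)
        assert np.all(diffs >= -1e-9) if c_in >= c_t0 else np.all(diffs <= 1e-9)


class TestDetectConsumptionLoss:
    def washed_in_series(self, noise=0.0, seed=0):
        p = WashinParams(c_in=10.0, c_t0=4.0, D=0.025, t0=400.0)
        t = np.arange(400.0, 560.0, 10.0)
        c = np.asarray(washin_concentration(p, t))
        if noise:
            c = c * np.random.default_rng(seed).lognormal(0.0, noise, t.size)
        df = pd.DataFrame({"time_h": t, "biomass_gL": np.full(t.size, 1.18),
                           "sorbitol_gL": c})
        return CultureSeries(df), p

    def test_exact_washin_classified_washed_in(self):
        series, p = self.washed_in_series()
        assert detect_consumption_loss(series, p).label == "washed-in"

    def test_sustained_consumption_classified_consuming(self):
        p = WashinParams(c_in=10.0, c_t0=4.0, D=0.025, t0=400.0)
        t = np.arange(400.0, 560.0, 10.0)
        df = pd.DataFrame({"time_h": t, "biomass_gL": np.full(t.size, 1.18),
                           "sorbitol_gL": np.full(t.size, 4.0)})  # plateau
        assert detect_consumption_loss(CultureSeries(df), p).label == "consuming"

    def test_too_few_post_event_points(self):
        series, p = self.washed_in_series()
        short = CultureSeries(series.data.iloc[:2].reset_index(drop=True))
        with pytest.raises(InsufficientDataError):
            detect_consumption_loss(short, p)

    def test_noisy_washin_rarely_flagged_consuming(self):
        """At 10% noise with tol 0.05 the label depends on the draw, but a
        truly washed-in culture must essentially never look 'consuming'."""
        labels = {"washed-in": 0, "partial": 0, "consuming": 0}
        for seed in range(100):
            series, p = self.washed_in_series(noise=0.10, seed=seed)
            labels[detect_consumption_loss(series, p).label] += 1
        assert labels["consuming"] <= 5
        assert labels["washed-in"] + labels["partial"] >= 95


class TestReductionRecovery:
    def test_balanced_model_fluxes_recover_exactly_100(self, calibrated_params):
        """Exchange fluxes of a feasible network solve close the electron
        balance exactly."""
        pred = predict(0.05, "wt_glucose", calibrated_params)
        # per g biomass per h: consumed/produced mol, biomass 1 g * mu h
        consumed = {"glucose": pred.q_substrate / 1000.0}
        produced = {"ethanol": pred.q_ethanol / 1000.0,
                    "glycerol": pred.q_glycerol / 1000.0}
        rec = reduction_recovery(consumed, produced, biomass_g=pred.mu)
        assert rec == pytest.approx(100.0, abs=1e-9)

    def test_underreported_ethanol_lowers_recovery_proportionally(self, calibrated_params):
        pred = predict(0.05, "wt_glucose", calibrated_params)
        consumed = {"glucose": pred.q_substrate / 1000.0}
        produced = {"ethanol": pred.q_ethanol / 1000.0 * 0.95,
                    "glycerol": pred.q_glycerol / 1000.0}
        rec = reduction_recovery(consumed, produced, biomass_g=pred.mu)
        reg = default_registry()
        eth_fraction = (reg.gamma("ethanol") * pred.q_ethanol
                        / (reg.gamma("glucose") * pred.q_substrate))
        assert rec == pytest.approx(100.0 - 5.0 * eth_fraction, abs=1e-9)

    def test_noisy_recoveries_fall_in_physiological_range(self):
        """2% measurement noise keeps electron recoveries within 95-105%."""
        reg = default_registry()
        base = {"glucose": 10.0 / reg.molar_mass("glucose")}
        eth = (reg.gamma("glucose") * base["glucose"]
               - 4.2 * 1.5 / 26.4) / reg.gamma("ethanol")
        inside = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            f = rng.lognormal(0.0, 0.02, 3)
            rec = reduction_recovery(
                {"glucose": base["glucose"] * f[0]},
                {"ethanol": eth * f[1]},
                biomass_g=1.5 * f[2],
            )
            if 95.0 <= rec <= 105.0:
                inside += 1
        assert inside >= 95

    def test_zero_substrate_electrons_rejected(self):
        with pytest.raises(DomainError):
            reduction_recovery({}, {"ethanol": 0.1})


class TestEvaporationCorrection:
    def make_series(self, ethanol):
        t = np.arange(len(ethanol), dtype=float)
        df = pd.DataFrame({"time_h": t, "biomass_gL": np.ones_like(t),
                           "ethanol_gL": ethanol})
        return CultureSeries(df)

    def test_zero_constant_is_identity(self):
        series = self.make_series(np.array([1.0, 3.0, 5.0]))
        out = correct_ethanol_evaporation(series, 0.0)
        np.testing.assert_allclose(out.concentration("ethanol"),
                                   series.concentration("ethanol"))

    def test_constant_profile_closed_form(self):
        """10 g/L held for 10 h at k = 0.001 1/h adds back 0.1 g/L."""
        series = self.make_series(np.full(11, 10.0))
        out = correct_ethanol_evaporation(series, 0.001)
        assert out.concentration("ethanol")[-1] == pytest.approx(10.1, abs=1e-12)

    def test_correction_never_decreases(self):
        series = self.make_series(np.array([8.0, 6.0, 5.0, 4.0]))
        out = correct_ethanol_evaporation(series, 0.01)
        assert np.all(out.concentration("ethanol") >= series.concentration("ethanol"))

    def test_negative_constant_rejected(self):
        series = self.make_series(np.array([1.0, 2.0]))
        with pytest.raises(DomainError):
            correct_ethanol_evaporation(series, -0.1)
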