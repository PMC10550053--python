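"""Step-wise estimation: sensitivity, base temperature, grid searches."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from sklearn.base import clone

from frostdamage import (
    DeltaCCSeries,
    EstimationInfeasibleError,
    FrostDamageIndexModel,
    GridProfile,
    InsufficientDataError,
    ScoringTable,
    UndefinedSensitivityError,
    diagnostics,
    estimate_sensitivity,
    estimate_tbase,
    grid_search_lag,
    grid_search_smoothing,
    pair_observations,
    select_smoothing,
    stepwise_fit,
    validate_against_scoring,
)
from frostdamage.core import FDIParams
from frostdamage.estimation import _DailyFDI
from frostdamage.simulate import (
    ColdSpell,
    SimulationConfig,
    make_recovery_dataset,
    simulate_cc,
    simulate_temperature,
)


def small_dataset(seed=0, rows=2, **kw):
    """A small noiseless single-season dataset for estimation tests."""
    cfg = SimulationConfig(
        seed=seed,
        cold_spells=(
            ColdSpell(100, 3, -10.2, 1.0),
            ColdSpell(131, 6, -8.7, 2.0),
        ),
        genotypes={"A": 1e-3, "B": 3e-3},
        rows_per_genotype=rows,
        schedule_days=tuple(range(0, 151)),
        cc_initial=0.6,
        **kw,
    )
    temp = simulate_temperature(cfg)
    cc, truth = simulate_cc(cfg, temp)
    return cfg, temp, cc, truth


class TestEstimateSensitivity:
    def test_noiseless_exact_recovery(self):
        f = np.array([-40.0, -10.0, -3.0, 0.0])
        assert estimate_sensitivity(0.002 * f, f) == pytest.approx(0.002)

    def test_all_zero_dcc_gives_zero(self):
        assert estimate_sensitivity(np.zeros(4), np.array([-1.0, -2, 0, -3])) == 0.0

    def test_negative_slope_clipped_at_zero(self):
        f = np.array([-10.0, -5.0])
        assert estimate_sensitivity(-0.001 * f, f) == 0.0

    def test_matches_numeric_minimizer(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            f = -rng.exponential(10, 20)
            d = 2e-3 * f + rng.normal(0, 0.01, 20)
            closed = estimate_sensitivity(d, f)
            num = optimize.minimize_scalar(
                lambda s: np.mean((d - f * max(s, 0.0)) ** 2),
                bounds=(0, 1),
                method="bounded",
                options={"xatol": 1e-12},
            ).x
            assert closed == pytest.approx(max(num, 0.0), abs=1e-8)

    def test_all_zero_fdi_is_undefined(self):
        with pytest.raises(UndefinedSensitivityError):
            estimate_sensitivity(np.array([-0.1, -0.2]), np.zeros(2))


def _daily_deltas_from_fdi(temp, t_base, s, days):
    """Construct daily dCC exactly proportional to the FDI at t_base."""
    ends = (pd.Timestamp("2017-10-17") + pd.to_timedelta(days, "D")).asi8
    f = _DailyFDI(temp, 0, 0, ends)(t_base)
    return DeltaCCSeries(
        "u1", "A", pd.DatetimeIndex(ends), s * f, daily=True
    )


class TestEstimateTbase:
    def test_constructed_recovery_at_minus_five(self):
        cfg, temp, _, _ = small_dataset()
        days = np.arange(95, 140)
        delta = _daily_deltas_from_fdi(temp, -5.0, 2e-3, days)
        got = estimate_tbase([delta], temp, lag_days=0, smooth_hours=0)
        assert got == pytest.approx(-5.0, abs=0.05)

    def test_translation_equivariance(self):
        from frostdamage import TemperatureSeries

        cfg, temp, _, _ = small_dataset()
        days = np.arange(95, 140)
        delta = _daily_deltas_from_fdi(temp, -6.0, 2e-3, days)
        base = estimate_tbase([delta], temp, 0, 0)
        shifted_temp = TemperatureSeries(temp.timestamps, temp.values + 2.0)
        shifted = estimate_tbase([delta], shifted_temp, 0, 0)
        assert shifted == pytest.approx(base + 2.0, abs=0.05)

    def test_infeasible_when_no_frost(self, cc_series):
        from frostdamage import TemperatureSeries

        idx = pd.date_range("2020-01-01 01:00", periods=24 * 40, freq="h")
        warm = TemperatureSeries(idx, np.full(idx.size, 10.0))
        deltas = [
            DeltaCCSeries(
                "u1",
                "A",
                pd.date_range("2020-01-05", periods=5, freq="D"),
                np.full(5, -0.01),
                daily=True,
            )
        ]
        with pytest.raises(EstimationInfeasibleError):
            estimate_tbase(deltas, warm, 0, 0)


class TestGridSearches:
    def test_profile_lengths(self):
        _, temp, cc, _ = small_dataset()
        lag_prof = grid_search_lag(cc, temp)
        assert len(lag_prof.grid_values) == 11
        smooth_prof = grid_search_smoothing(cc, temp, 3)
        assert len(smooth_prof.grid_values) == 10 + 1  # 0,6,...,54 plus 56

    def test_profile_invariant_to_unit_relabeling(self):
        from frostdamage import CanopyCoverSeries

        _, temp, cc, _ = small_dataset()
        relabeled = [
            CanopyCoverSeries(f"x{i}", c.genotype, c.dates, c.cc)
            for i, c in enumerate(cc)
        ]
        a = grid_search_lag(cc, temp, lag_grid=(0, 3, 6))
        b = grid_search_lag(relabeled, temp, lag_grid=(0, 3, 6))
        np.testing.assert_allclose(a.pearson_r, b.pearson_r)

    def test_noiseless_data_peaks_at_true_lag(self):
        from frostdamage import select_lag

        _, temp, cc, _ = small_dataset()
        prof = grid_search_lag(cc, temp, smooth_hours=18)
        assert select_lag(prof) == 3


class TestSelectSmoothing:
    def _profile(self, grid, r, rmse):
        return GridProfile(np.asarray(grid), r, rmse, np.full(len(grid), 10))

    def test_reported_compromise_between_twelve_and_twentyfour(self):
        grid = list(range(0, 55, 6)) + [56]
        r = [0.1] * len(grid)
        rmse = [1.0] * len(grid)
        r[grid.index(12)] = 0.9
        rmse[grid.index(24)] = 0.5
        assert select_smoothing(self._profile(grid, r, rmse)) == 18

    def test_identical_optima(self):
        grid = [0, 6, 12]
        prof = self._profile(grid, [0.1, 0.9, 0.2], [1.0, 0.2, 0.9])
        assert select_smoothing(prof) == 6

    def test_midpoint_rule_on_four_point_profile(self):
        # monotone r (optimum 18), flat rmse (optimum at smallest, 0):
        # midpoint 9 is equidistant from 6 and 12; ties go smaller
        prof = self._profile([0, 6, 12, 18], [0.1, 0.2, 0.3, 0.4], [1, 1, 1, 1])
        assert select_smoothing(prof) == 6

    def test_explicit_rules(self):
        prof = self._profile([0, 6, 12], [0.1, 0.9, 0.2], [0.9, 0.8, 0.1])
        assert select_smoothing(prof, "max_r") == 6
        assert select_smoothing(prof, "min_rmse") == 12
        with pytest.raises(ValueError, match="rule"):
            select_smoothing(prof, "banana")


class TestDiagnostics:
    def test_perfect_prediction(self):
        d = diagnostics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (d.pearson_r, d.rmse, d.mae) == (pytest.approx(1.0), 0.0, 0.0)

    def test_anticorrelated(self):
        obs = np.array([-1.0, 0.5, 2.0])
        assert diagnostics(obs, -obs).pearson_r == pytest.approx(-1.0)

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(2)
        o, p = rng.normal(size=30), rng.normal(size=30)
        d = diagnostics(o, p)
        r = np.sum((o - o.mean()) * (p - p.mean())) / (
            np.sqrt(np.sum((o - o.mean()) ** 2)) * np.sqrt(np.sum((p - p.mean()) ** 2))
        )
        assert d.pearson_r == pytest.approx(r, abs=1e-12)
        assert d.rmse == pytest.approx(np.sqrt(np.mean((o - p) ** 2)), abs=1e-12)
        assert d.mae == pytest.approx(np.mean(np.abs(o - p)), abs=1e-12)

    def test_zero_variance_flagged_not_nan(self):
        d = diagnostics([1.0, 1.0, 1.0], [0.5, 0.6, 0.7])
        assert d.pearson_r is None
        assert not d.r_defined
        assert np.isfinite(d.rmse)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            diagnostics([1.0], [1.0, 2.0])


class TestScoringValidation:
    def test_perfect_and_reversed_rank_order(self):
        s = {"A": 1e-3, "B": 2e-3, "C": 3e-3, "D": 4e-3}
        scoring = ScoringTable(("A", "B", "C", "D"), [1, 3, 5, 9])
        assert validate_against_scoring(s, scoring) == pytest.approx(1.0)
        reversed_scores = ScoringTable(("A", "B", "C", "D"), [9, 5, 3, 1])
        assert validate_against_scoring(s, reversed_scores) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(3)
        genos = [f"G{i}" for i in range(12)]
        s = {g: float(v) for g, v in zip(genos, rng.uniform(1e-4, 5e-3, 12))}
        scores = rng.integers(1, 10, 12)
        scores[3] = scores[7]  # force ties
        rho = validate_against_scoring(s, ScoringTable(tuple(genos), scores))
        from scipy.stats import rankdata

        ra = rankdata([s[g] for g in genos])
        rb = rankdata(scores)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_insufficient_overlap(self):
        with pytest.raises(InsufficientDataError):
            validate_against_scoring({"A": 1e-3, "B": 2e-3}, {"A": 3, "B": 5})

    def test_scoring_table_range(self):
        with pytest.raises(ValueError):
            ScoringTable(("A",), [10])


class TestPairObservations:
    def test_pair_counts(self, cc_series):
        _, temp, cc, truth = small_dataset()
        params = FDIParams(t_base=-9.0, lag_days=3, smooth_hours=18)
        pairs = pair_observations(cc, temp, params)
        neg = 0
        for c in cc:
            neg += int((np.diff(c.cc) < 0).sum())
        assert len(pairs) == neg  # daily schedule: one day per interval
        assert (pairs.fdi <= 0).all()

    def test_empty_pairing_is_representable(self, cc_series):
        _, temp, _, _ = small_dataset()
        flat = cc_series(range(10), np.linspace(0.2, 0.4, 10))
        pairs = pair_observations([flat], temp, FDIParams(t_base=-9.0))
        assert len(pairs) == 0


class TestStepwiseFit:
    def test_single_genotype_global_equals_genotype_s(self):
        cfg = SimulationConfig(
            seed=1,
            cold_spells=(ColdSpell(100, 3, -10.2, 1.0), ColdSpell(131, 6, -8.7, 2.0)),
            genotypes={"A": 2e-3},
            rows_per_genotype=2,
            schedule_days=tuple(range(0, 151)),
            cc_initial=0.6,
        )
        temp = simulate_temperature(cfg)
        cc, _ = simulate_cc(cfg, temp)
        res = stepwise_fit(cc, temp)
        s_geno, n = res.per_genotype_s["A"]
        assert s_geno == pytest.approx(res.params.sensitivity, rel=1e-12)
        assert n >= 5

    def test_row_order_invariance(self):
        _, temp, cc, _ = small_dataset()
        a = stepwise_fit(cc, temp, lag_grid=(2, 3, 4), smooth_grid=(12, 18, 24))
        b = stepwise_fit(cc[::-1], temp, lag_grid=(2, 3, 4), smooth_grid=(12, 18, 24))
        assert (a.params.lag_days, a.params.smooth_hours) == (
            b.params.lag_days, b.params.smooth_hours
        )
        assert a.params.t_base == pytest.approx(b.params.t_base, abs=1e-9)
        assert a.params.sensitivity == pytest.approx(b.params.sensitivity, rel=1e-9)
        assert a.diagnostics.rmse == pytest.approx(b.diagnostics.rmse, rel=1e-9)

    def test_stage_name_in_infeasibility_error(self, cc_series):
        from frostdamage import TemperatureSeries

        idx = pd.date_range("2019-12-20 01:00", periods=24 * 60, freq="h")
        warm = TemperatureSeries(idx, np.full(idx.size, 12.0))
        cc = [cc_series([0, 5, 10, 15], [0.3, 0.28, 0.26, 0.24], origin="2020-01-01")]
        with pytest.raises(EstimationInfeasibleError, match="lag grid search"):
            stepwise_fit(cc, warm)


class TestModelInterface:
    def test_sklearn_params_roundtrip(self):
        model = FrostDamageIndexModel(smoothing_rule="max_r", min_genotype_obs=7)
        cloned = clone(model)
        assert cloned.get_params()["smoothing_rule"] == "max_r"
        cloned.set_params(min_genotype_obs=3)
        assert cloned.min_genotype_obs == 3

    def test_predict_uses_fitted_params(self):
        ds = make_recovery_dataset("noiseless", 5)
        model = FrostDamageIndexModel().fit(ds.cc, temperature=ds.temperature)
        sched = pd.date_range("2018-01-20", periods=8, freq="7D")
        pred = model.predict(sched, temperature=ds.temperature, genotype="G01")
        assert len(pred) == 7
        assert (pred.delta_cc <= 0).all()
        fdi = model.fdi(sched, temperature=ds.temperature)
        s = model.per_genotype_s_["G01"][0]
        np.testing.assert_allclose(pred.delta_cc, s * fdi.fdi)
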