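import numpy as np
import pytest

import busulfanpk as b
from busulfanpk.diagnostics import (
    bootstrap,
    covariate_stripped_cl,
    dose_linearity,
    icwres,
    npde,
    simulate_cl_trend,
    train_test_split,
    vpc,
)
from busulfanpk.nca import nca_all
from busulfanpk.popmodel import PopulationModel, final_model
from busulfanpk.saem import SaemSettings, evaluate_model, final_model_spec

STATIC_POP = PopulationModel(
    theta={"lV": 2.459, "lk": -1.007, "dk": 0.0, "lkappa": -3.5},
    omega2={"lV": 0.029, "lk": 0.033, "dk": 1e-10},
    sigma=0.076, n_subjects=40)


def _truth_fit(ds, pop, seed=0, ebes=True):
    """Condition the generating model on its own cohort (no estimation)."""
    return evaluate_model(ds, final_model_spec(), pop.theta, pop.omega2,
                          pop.sigma, seed=seed, compute_ebes=ebes)


class TestIcwres:
    def test_near_zero_on_noise_free_data_with_true_parameters(self):
        pop = PopulationModel(
            theta=dict(final_model().theta),
            omega2={"lV": 1e-10, "lk": 1e-10, "dk": 1e-12},
            sigma=1e-9, n_subjects=12)
        ds, _ = b.generate_cohort(b.CohortSpec(n_subjects=12), pop, seed=3)
        fit = evaluate_model(ds, final_model_spec(), pop.theta, pop.omega2,
                             sigma=0.05, seed=1)
        res = icwres(fit)
        assert np.abs(res["icwres"]).max() < 0.05

    def test_centered_under_correct_model(self, cohort124, final_pop):
        ds, _ = cohort124
        fit = _truth_fit(ds, final_pop, seed=2)
        res = icwres(fit)
        assert abs(res["icwres"].mean()) < 0.1

    def test_misspecified_static_fit_leaves_time_trend(self, small_cohort):
        # fitting a constant-k model to declining-clearance data pushes the
        # conditional residuals up in later dosing intervals
        from scipy.stats import spearmanr
        ds, _ = small_cohort
        fit = b.fit_saem(ds, b.static_model_spec(),
                         SaemSettings(exploration=200, smoothing=60, seed=3))
        res = icwres(fit)
        late = res[res["t"] > 24.0]["icwres"]
        rho, p = spearmanr(res["t"], res["icwres"])
        assert (p < 0.01 and rho > 0) or late.mean() > 0.1


class TestNpde:
    def test_self_simulation_calibration(self, cohort124_fixed_design,
                                         final_pop):
        ds, _ = cohort124_fixed_design
        fit = _truth_fit(ds, final_pop, seed=4, ebes=False)
        res = npde(fit, n_sim=1000, seed=9)
        z = res["npde"].to_numpy()
        assert abs(z.mean()) < 0.08
        assert 0.9 < z.var() < 1.1

    def test_seed_reproducible(self, small_fit):
        a = npde(small_fit, n_sim=300, seed=5)
        c = npde(small_fit, n_sim=300, seed=5)
        assert np.array_equal(a["npde"], c["npde"])


class TestVpc:
    def test_self_simulation_coverage(self, cohort124_fixed_design, final_pop):
        ds, _ = cohort124_fixed_design
        fit = _truth_fit(ds, final_pop, seed=6, ebes=False)
        res = vpc(fit, n_sim=400, seed=3)
        tab = res.table[res.table["n"] >= 5]
        inside = 0
        for _, row in tab.iterrows():
            inside += (row["sim_p50_lo"] <= row["obs_p50"] <= row["sim_p50_hi"])
        assert inside / len(tab) >= 0.9

    def test_bands_collapse_without_variability(self):
        pop = PopulationModel(
            theta=dict(final_model().theta),
            omega2={"lV": 1e-12, "lk": 1e-12, "dk": 1e-14},
            sigma=1e-9, n_subjects=10)
        ds, _ = b.generate_cohort(b.CohortSpec(n_subjects=10), pop, seed=5)
        fit = evaluate_model(ds, final_model_spec(), pop.theta, pop.omega2,
                             pop.sigma, seed=1, compute_ebes=False)
        res = vpc(fit, n_sim=100, seed=2)
        width = (res.table["sim_p50_hi"] - res.table["sim_p50_lo"]).max()
        assert width < 1e-4  # single-precision simulation storage jitter

    def test_sparse_time_points_flagged(self, small_fit):
        res = vpc(small_fit, n_sim=50, seed=1)
        assert all(res.table.loc[res.table["t"].isin(res.flagged), "n"] < 5)


class TestBootstrap:
    def test_smoke_two_replicates(self, small_cohort):
        ds, _ = small_cohort
        st = SaemSettings(exploration=120, smoothing=40, compute_ebes=False,
                          n_conditional=40)
        res = bootstrap(ds, b.basic_model_spec(), n=2, settings=st, seed=7)
        assert res.n_requested == 2
        assert len(res.estimates) == res.n_converged <= 2
        assert (res.ci["lower"] <= res.ci["upper"]).all()

    def test_resampling_reproducible(self, small_cohort):
        ds, _ = small_cohort
        st = SaemSettings(exploration=80, smoothing=30, compute_ebes=False,
                          n_conditional=30)
        a = bootstrap(ds, b.basic_model_spec(), n=2, settings=st, seed=7)
        c = bootstrap(ds, b.basic_model_spec(), n=2, settings=st, seed=7)
        assert a.estimates.equals(c.estimates)


class TestTrainTestSplit:
    def test_study_ratio_93_31(self, cohort124):
        ds, _ = cohort124
        train, test, report = train_test_split(ds, ratio=0.75, seed=1)
        assert (report["n_train"], report["n_test"]) == (93, 31)
        ids_train = {s.subject_id for s in train.subjects}
        ids_test = {s.subject_id for s in test.subjects}
        assert not ids_train & ids_test
        assert len(ids_train | ids_test) == 124

    def test_refuses_tiny_datasets(self):
        ds, _ = b.generate_cohort(b.CohortSpec(n_subjects=5), seed=1)
        with pytest.raises(ValueError):
            train_test_split(ds, seed=0)

    def test_fit_and_ssr_report(self, small_cohort):
        ds, _ = small_cohort
        st = SaemSettings(exploration=150, smoothing=50, compute_ebes=False,
                          n_conditional=40)
        train, test, report = train_test_split(
            ds, ratio=0.75, seed=2, spec=b.basic_model_spec(), settings=st)
        assert report["ssr_train"] > 0 and report["ssr_test"] > 0
        assert {"obs", "pred"} <= set(report["obs_pred_test"].columns)


class TestCovariateStrippedCl:
    def test_planted_all_and_albumin_effects_visible(self, cohort124):
        ds, _ = cohort124
        st = SaemSettings(exploration=250, smoothing=70, seed=9)
        fit = b.fit_saem(ds, final_model_spec(), st)
        table, info = covariate_stripped_cl(ds, fit, settings=st)
        all_ratio = table.loc[table["ALL"], "cl_ratio"].mean()
        rest_ratio = table.loc[~table["ALL"], "cl_ratio"].mean()
        assert all_ratio < rest_ratio
        assert info["all_vs_rest_p"] < 0.05
        assert info["albumin_slope"] > 0

    def test_unknown_covariate_rejected(self, small_fit):
        with pytest.raises(ValueError):
            covariate_stripped_cl(None, small_fit, drop=(("lk", "dlnHct"),))


class TestDoseLinearity:
    def test_linear_pk_without_trend_gives_unit_ratios(self):
        ds, _ = b.generate_cohort(b.CohortSpec(n_subjects=60), STATIC_POP,
                                  seed=17)
        table, regs = dose_linearity(nca_all(ds))
        assert len(table) > 5
        assert abs(table["auc_dose_ratio"].median() - 1.0) < 0.1
        assert (table["interval"] % 2 == 1).all()

    def test_declining_clearance_raises_ratios_but_not_slope(self, cohort124):
        ds, _ = cohort124
        table, regs = dose_linearity(nca_all(ds))
        assert table["auc_dose_ratio"].mean() > 1.0
        slopes = [r for r in regs.values() if r is not None]
        assert slopes, "at least one interval must support a regression"

    def test_single_subject_regression_skipped(self):
        import pandas as pd
        tab = pd.DataFrame({
            "subject_id": ["a", "a"], "interval": [1, 3],
            "dose": [60.0, 50.0], "auc": [10.0, 9.0],
        })
        table, regs = dose_linearity(tab)
        assert len(table) == 1
        assert all(v is None for v in regs.values())


class TestClTrend:
    def test_asymptote_and_24h_reduction(self, final_pop):
        res = simulate_cl_trend(final_pop, n=20000, horizon_h=240.0, seed=3)
        assert res.mean_curve[-1] == pytest.approx(1.0 - 0.167, abs=1e-3)
        t24 = np.argmin(np.abs(res.t - 24.0))
        assert round(100.0 * (1.0 - res.mean_curve[t24])) == 12

    def test_hlh_xlp_curve_reaches_total_reduction(self, final_pop):
        res = simulate_cl_trend(final_pop, n=5000, horizon_h=400.0, seed=3)
        assert res.mean_curve_hlh[-1] == pytest.approx(1.0 - 0.312, abs=1e-3)

    def test_band_ordering_and_reproducibility(self, final_pop):
        a = simulate_cl_trend(final_pop, n=5000, horizon_h=72.0, seed=8)
        c = simulate_cl_trend(final_pop, n=5000, horizon_h=72.0, seed=8)
        assert np.array_equal(a.bands["lo95"], c.bands["lo95"])
        assert np.all(a.bands["lo95"] <= a.bands["lo80"] + 1e-12)
        assert np.all(a.bands["hi80"] <= a.bands["hi95"] + 1e-12)

    def test_bad_horizon_rejected(self, final_pop):
        with pytest.raises(ValueError):
            simulate_cl_trend(final_pop, n=100, horizon_h=0.0)
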