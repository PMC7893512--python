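import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paikit.pai_engine import (
    crossval_predict,
    fit_final_model,
    johnson_neyman,
    predict_under_arm,
)
from paikit.synthetic_trial import GeneratorConfig, generate


def _fixture(n=10, seed=0, n_mod=1):
    r = np.random.default_rng(seed)
    cov = pd.DataFrame(
        {"p": r.normal(size=n), **{f"m{j}": r.normal(size=n) for j in range(n_mod)}}
    )
    arm = np.tile([0.0, 1.0], n // 2 + 1)[:n]
    y = (
        1.0
        + 0.8 * cov["p"]
        + sum(0.5 * cov[f"m{j}"] * arm for j in range(n_mod))
        + r.normal(0, 0.5, n)
    ).to_numpy()
    return cov, y, arm


class TestFinalModel:
    def test_reduces_to_arm_mean_difference(self, rng):
        n = 40
        arm = np.tile([0.0, 1.0], 20)
        y = rng.normal(10, 2, n) + 3.0 * arm
        cov = pd.DataFrame(index=range(n))
        model = fit_final_model(cov, y, arm)
        diff = y[arm == 1].mean() - y[arm == 0].mean()
        assert model.params["arm"] == pytest.approx(diff, abs=1e-10)

    def test_normal_equations_oracle(self):
        cov, y, arm = _fixture(n=10, seed=1)
        model = fit_final_model(cov, y, arm, predictors=["p"], moderators=["m0"])
        X = np.column_stack(
            [np.ones(10), cov["p"], cov["m0"], arm, cov["m0"] * arm]
        )
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        got = model.params[["const", "p", "m0", "arm", "m0:arm"]].to_numpy()
        assert np.allclose(got, oracle, atol=1e-10)

    def test_recovers_generator_truth_at_n5000(self):
        cfg = GeneratorConfig(
            n_participants=5000,
            seed=77,
            visit_noise_sd=0.0,
            drift_sd=0.0,
            intercept=30.0,
            residual_sd=5.0,
            baseline_effect=0.0,
            missing_rate_covariates=0.0,
            missing_rate_outcomes=0.0,
        )
        ds, truth = generate(cfg)
        Z = truth.standardized_design
        cov = pd.DataFrame(
            {
                "x00": Z["z_x00"],
                "x01": Z["z_x01"],
                "x02": Z["z_x02"],
            }
        )
        y = np.where(
            ds.arm_numeric == 0,
            truth.expected_avg_bdi_ct,
            truth.expected_avg_bdi_ipt,
        ) + np.random.default_rng(1).normal(0, 5.0, 5000)
        model = fit_final_model(
            cov, y, ds.arm_numeric.to_numpy(),
            predictors=["x00"], moderators=["x01", "x02"],
        )
        se = np.sqrt(np.diag(model.cov.to_numpy()))
        expected = pd.Series(
            {
                "const": cfg.intercept,
                "x00": cfg.predictor_effect_sizes[0],
                "x01": 0.0,
                "x02": 0.0,
                "arm": cfg.arm_effect,
                "x01:arm": cfg.moderator_effect_sizes[0],
                "x02:arm": cfg.moderator_effect_sizes[1],
            }
        )
        err = (model.params - expected[model.params.index]).abs()
        assert (err < 3 * se + 1e-9).all()

    def test_rank_deficiency_rejected(self):
        cov, y, arm = _fixture(n=20, seed=2)
        cov["dup"] = cov["p"]
        with pytest.raises(ValueError, match="rank"):
            fit_final_model(cov, y, arm, predictors=["p", "dup"])

    def test_covariance_is_symmetric_psd(self):
        cov, y, arm = _fixture(n=30, seed=3)
        model = fit_final_model(cov, y, arm, predictors=["p"], moderators=["m0"])
        S = model.cov.to_numpy()
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > -1e-12


class TestCrossvalPredict:
    def test_leave_one_out_matches_brute_force_refit(self):
        cov, y, arm = _fixture(n=12, seed=4)
        tab = crossval_predict(
            cov, y, arm, predictors=["p"], moderators=["m0"],
            k=12, fold_assignment=np.arange(12),
        )
        for i in range(12):
            keep = np.arange(12) != i
            model = fit_final_model(
                cov.iloc[keep], y[keep], arm[keep],
                predictors=["p"], moderators=["m0"],
            )
            oracle_ct = predict_under_arm(model, cov.iloc[[i]], 0)[0]
            oracle_ipt = predict_under_arm(model, cov.iloc[[i]], 1)[0]
            assert tab["pred_ct"].iloc[i] == pytest.approx(oracle_ct, abs=1e-10)
            assert tab["pred_ipt"].iloc[i] == pytest.approx(oracle_ipt, abs=1e-10)

    def test_factual_matches_received_arm(self):
        cov, y, arm = _fixture(n=60, seed=5)
        tab = crossval_predict(cov, y, arm, predictors=["p"], moderators=["m0"])
        is_ct = tab["arm"] == "CT"
        assert np.allclose(tab.loc[is_ct, "factual"], tab.loc[is_ct, "pred_ct"])
        assert np.allclose(
            tab.loc[~is_ct, "factual"], tab.loc[~is_ct, "pred_ipt"]
        )

    def test_indicated_arm_sign_convention(self):
        cov, y, arm = _fixture(n=60, seed=6)
        tab = crossval_predict(cov, y, arm, moderators=["m0"])
        neg = tab["pai_signed"] < 0
        assert (tab.loc[neg, "indicated"] == "CT").all()
        assert (tab.loc[~neg & (tab["pai_signed"] > 0), "indicated"] == "IPT").all()

    def test_arm_swap_antisymmetry(self):
        cov, y, arm = _fixture(n=60, seed=7)
        fold = np.tile(np.arange(5), 12)
        tab = crossval_predict(
            cov, y, arm, moderators=["m0"], k=5, fold_assignment=fold
        )
        swapped = crossval_predict(
            cov, y, 1 - arm, moderators=["m0"], k=5, fold_assignment=fold
        )
        assert np.allclose(
            swapped["pai_signed"], -tab["pai_signed"], atol=1e-10
        )
        flips = {"CT": "IPT", "IPT": "CT", "none": "none"}
        assert (swapped["indicated"] == tab["indicated"].map(flips)).all()

    def test_pai_sign_agrees_with_fold_model_algebra(self):
        cov, y, arm = _fixture(n=80, seed=8)
        fold = np.tile(np.arange(5), 16)
        tab = crossval_predict(
            cov, y, arm, moderators=["m0"], k=5, fold_assignment=fold
        )
        for f in range(5):
            model = fit_final_model(
                cov[fold != f], y[fold != f], arm[fold != f], moderators=["m0"]
            )
            test = fold == f
            delta = (
                model.params["arm"]
                + model.params["m0:arm"] * cov.loc[test, "m0"]
            )
            assert np.allclose(
                np.sign(tab.loc[test, "pai_signed"]), np.sign(-delta)
            )

    def test_null_model_pai_shrinks_with_n(self):
        means = []
        for n in (100, 1000):
            r = np.random.default_rng(9)
            cov = pd.DataFrame({"m": r.normal(size=n)})
            arm = np.tile([0.0, 1.0], n // 2)
            y = r.normal(size=n)  # no arm effect, no moderation
            tab = crossval_predict(cov, y, arm, moderators=["m"], seed=0)
            means.append(tab["pai_abs"].mean())
        assert means[1] < means[0]

    def test_seed_changes_folds_not_predictions_much(self):
        cfg = GeneratorConfig(
            n_participants=5000,
            seed=55,
            missing_rate_covariates=0.0,
            missing_rate_outcomes=0.0,
        )
        ds, truth = generate(cfg)
        Z = truth.standardized_design
        cov = pd.DataFrame(
            {"x00": Z["z_x00"], "x01": Z["z_x01"], "x02": Z["z_x02"]}
        )
        months = np.asarray(ds.schedule)
        from paikit.outcomes import build_outcome_records

        rec = build_outcome_records(ds.outcomes, months, ds.baseline_bdi)
        y = rec["auc_residual"].to_numpy()
        arm = ds.arm_numeric.to_numpy()
        t1 = crossval_predict(
            cov, y, arm, predictors=["x00"], moderators=["x01", "x02"], seed=1
        )
        t2 = crossval_predict(
            cov, y, arm, predictors=["x00"], moderators=["x01", "x02"], seed=2
        )
        assert not np.array_equal(t1["fold"], t2["fold"])
        rel = abs(t1["pai_abs"].mean() - t2["pai_abs"].mean()) / t1["pai_abs"].mean()
        assert rel < 0.05


class TestJohnsonNeyman:
    def _model(self, n=200, seed=0, arm_eff=0.0, inter=1.0):
        r = np.random.default_rng(seed)
        cov = pd.DataFrame({"m": r.normal(size=n)})
        arm = np.tile([0.0, 1.0], n // 2)
        y = arm_eff * arm + inter * cov["m"].to_numpy() * arm + r.normal(size=n)
        return fit_final_model(cov, y, arm, moderators=["m"]), cov

    def test_zero_interaction_significant_everywhere(self):
        r = np.random.default_rng(3)
        n = 400
        cov = pd.DataFrame({"m": r.normal(size=n)})
        arm = np.tile([0.0, 1.0], n // 2)
        y = 2.0 * arm + r.normal(0, 0.5, n)  # strong arm effect, no moderation
        model = fit_final_model(cov, y, arm, moderators=["m"])
        region = johnson_neyman(model, "m", cov["m"])
        lo, hi = region.observed_range
        assert len(region.intervals) == 1
        a, b, favored = region.intervals[0]
        assert (a, b) == (lo, hi)
        assert favored == "CT"  # IPT raises the outcome here, so CT is better

    def test_grid_search_oracle(self):
        model, cov = self._model(seed=11, arm_eff=0.4, inter=0.9)
        region = johnson_neyman(model, "m", cov["m"], alpha=0.05)
        lo, hi = region.observed_range
        grid = np.linspace(lo, hi, 10_000)
        beta = model.params
        S = model.cov
        delta = beta["arm"] + beta["m:arm"] * grid
        se = np.sqrt(
            S.loc["arm", "arm"]
            + grid**2 * S.loc["m:arm", "m:arm"]
            + 2 * grid * S.loc["arm", "m:arm"]
        )
        tcrit = stats.t.ppf(0.975, model.df_resid)
        sig = np.abs(delta) > tcrit * se
        oracle_sig = {bool(region.significant_at(m)) for m in grid[sig]}
        assert oracle_sig <= {True}
        grid_res = (hi - lo) / 9999
        # boundaries agree with the grid transition points to grid resolution
        trans = np.flatnonzero(np.diff(sig.astype(int)) != 0)
        bounds = sorted(
            b for iv in region.intervals for b in iv[:2] if lo < b < hi
        )
        assert len(bounds) == len(trans)
        for b, t_idx in zip(bounds, trans):
            assert abs(b - grid[t_idx]) <= 2 * grid_res

    def test_symmetric_case_closed_form(self):
        # with no arm effect and zero covariance the boundary is
        # m* = t*se_int / |b_int| on both sides
        model, cov = self._model(seed=21, arm_eff=0.0, inter=0.8)
        beta = model.params.copy()
        S = model.cov.copy()
        beta["arm"] = 0.0
        S.loc["arm", "m:arm"] = S.loc["m:arm", "arm"] = 0.0
        model.params = beta
        model.cov = S
        region = johnson_neyman(model, "m", cov["m"], alpha=0.05)
        tcrit = region.t_crit
        inner = [b for iv in region.intervals for b in iv[:2]
                 if region.observed_range[0] < b < region.observed_range[1]]
        # analytic roots of delta^2 = t^2 SE^2 with d0=0, cov=0:
        # m^2 (b^2 - t^2 var_b) = t^2 var_a, symmetric about zero
        root = np.sqrt(
            tcrit**2 * S.loc["arm", "arm"]
            / (beta["m:arm"] ** 2 - tcrit**2 * S.loc["m:arm", "m:arm"])
        )
        assert np.allclose(sorted(np.abs(inner)), [root, root], rtol=1e-9)

    def test_missing_interaction_rejected(self):
        model, cov = self._model(seed=5)
        with pytest.raises(ValueError, match="no interaction"):
            johnson_neyman(model, "zzz", cov["m"])
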