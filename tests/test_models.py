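"""Component models, stepwise selection and the ensemble average."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import rangeshift as rs
from rangeshift.models import (
    fit_glm,
    fit_maxentlike,
    fit_rf,
    predict_table,
    stepwise_aic,
)
from rangeshift.occurrences import TrainingTable

from conftest import sim_table


class TestGlm:
    def test_recovers_known_coefficients_within_3se(self):
        """Slopes from weighted logistic fit match the generating model.

        Class weighting is a case-control style reweighting: it shifts the
        intercept but leaves slopes consistent, so only slopes are compared.
        Standard errors come from an independent statsmodels fit.
        """
        import statsmodels.api as sm
        from rangeshift.models import build_design, glm_terms, Standardizer

        betas = (1.0, -0.8, 0.5)
        tab = sim_table(0, n=20_000, betas=betas)
        comp = fit_glm(tab, 0)
        res = sm.GLM(
            tab.data.response.to_numpy(float),
            build_design(tab.data, comp.terms, comp.std),
            family=sm.families.Binomial(),
            freq_weights=tab.data.weight.to_numpy(float),
        ).fit()
        # cross-check the in-package IRLS against statsmodels
        np.testing.assert_allclose(comp.params, res.params, atol=1e-5)
        # simulation predictors are standard normal, so standardized-scale
        # coefficients estimate the generating betas directly
        for i, (name, truth) in enumerate(zip(("x1", "x2", "x3"), betas)):
            j = comp.terms.index(name) + 1  # +1 for intercept column
            se = res.bse[j]
            assert abs(comp.params[j] - truth) < 3 * se, name

    def test_degenerate_response_rejected(self, env_small):
        df = pd.DataFrame({"x1": np.random.default_rng(0).normal(size=10),
                           "bias": 0.5, "response": 1, "weight": 1.0})
        with pytest.raises(ValueError):
            TrainingTable(df, ["x1"])  # table invariant already catches it

    def test_duplicated_rows_with_halved_weights_identical(self):
        tab = sim_table(1, n=500)
        df2 = pd.concat([tab.data, tab.data], ignore_index=True)
        df2["weight"] = df2["weight"] / 2
        tab2 = TrainingTable(df2, tab.predictors, "dup")
        a = fit_glm(tab, 0)
        b = fit_glm(tab2, 0)
        np.testing.assert_allclose(a.params, b.params, atol=1e-6)


class TestStepwise:
    def test_noise_predictor_mostly_dropped_and_signal_kept(self):
        """AIC stepwise drops a true-zero predictor's terms in most
        replicates (per-term retention ~ P(chi2_1 > 2) = 0.157) and never
        discards the strong true predictors."""
        dropped, signal_kept = 0, 0
        reps = 50
        for rep in range(reps):
            tab = sim_table(rep, n=2000, betas=(1.0, -0.8, 0.0))
            red = stepwise_aic(fit_glm(tab, 0), tab)
            if not any(t.startswith("x3") for t in red.terms):
                dropped += 1
            if "x1" in red.terms and "x2" in red.terms:
                signal_kept += 1
        assert signal_kept == reps
        assert dropped >= reps // 2

    def test_reduced_aic_never_worse(self):
        tab = sim_table(5, n=1000)
        full = fit_glm(tab, 0)
        red = stepwise_aic(full, tab)
        assert red.aic <= full.aic + 1e-9

    def test_minimal_model_is_fixed_point(self):
        tab = sim_table(6, n=3000, betas=(1.5, 1.0, 0.8))
        red = stepwise_aic(fit_glm(tab, 0), tab)
        again = stepwise_aic(red, tab)
        assert set(again.terms) == set(red.terms)

    def test_bias_covariate_never_dropped(self):
        tab = sim_table(7, n=800, betas=(0.0, 0.0, 0.0))
        red = stepwise_aic(fit_glm(tab, 0), tab)
        assert red.include_bias  # control variable always in the design


class TestRandomForest:
    def test_separable_toy_table_perfect_training_auc(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)])
        df = pd.DataFrame({"x1": x, "bias": 0.5,
                           "response": np.r_[np.zeros(50, int), np.ones(50, int)],
                           "weight": 1.0})
        tab = TrainingTable(df, ["x1"], "toy")
        rf = fit_rf(tab, 0, n_trees=100)
        pred = rf.predict_df(df)
        assert rs.auc(pred[df.response == 1], pred[df.response == 0]) == 1.0

    def test_deterministic_given_seed(self):
        tab = sim_table(2, n=400)
        a = fit_rf(tab, 9, n_trees=50).predict_df(tab.data)
        b = fit_rf(tab, 9, n_trees=50).predict_df(tab.data)
        np.testing.assert_array_equal(a, b)

    def test_label_permutation_null_auc_near_half(self):
        from sklearn.ensemble import RandomForestClassifier
        aucs = []
        for rep in range(20):
            tab = sim_table(100 + rep, n=400)
            rng = np.random.default_rng(rep)
            y = rng.permutation(tab.data.response.to_numpy())
            m = RandomForestClassifier(n_estimators=100, random_state=rep,
                                       oob_score=True, n_jobs=1)
            X = tab.data[tab.predictors + ["bias"]].to_numpy()
            m.fit(X, y)
            oob = m.oob_decision_function_[:, 1]
            aucs.append(rs.auc(oob[y == 1], oob[y == 0]))
        assert abs(np.mean(aucs) - 0.5) < 0.05


class TestMaxentLike:
    def test_sparse_truth_zeroes_noise_features(self):
        """1-SE penalty choice eliminates features absent from the truth."""
        frac_zeroed, true_kept = [], []
        for rep in range(20):
            tab = sim_table(200 + rep, n=1500, betas=(1.0, -0.8, 0.0))
            mx = fit_maxentlike(tab, rep)
            coefs = mx.model.coef_.ravel()
            noise = [i for i, t in enumerate(mx.feature_terms) if "x3" in t]
            true_lin = [i for i, t in enumerate(mx.feature_terms)
                        if t in (("x1",), ("x2",))]
            frac_zeroed.append(np.mean(np.abs(coefs[noise]) < 1e-8))
            true_kept.append(np.all(np.abs(coefs[true_lin]) > 1e-8))
        assert np.mean(frac_zeroed) >= 0.8
        assert all(true_kept)

    def test_infinite_penalty_limit_predicts_prevalence(self):
        tab = sim_table(3, n=800)
        mx = fit_maxentlike(tab, 0, Cs=np.array([1e-8]))
        pred = mx.predict_df(tab.data)
        np.testing.assert_allclose(pred, 0.5, atol=0.02)

    def test_invariant_to_affine_predictor_rescaling(self):
        tab = sim_table(4, n=600)
        mx = fit_maxentlike(tab, 0)
        df2 = tab.data.copy()
        df2["x1"] = 100.0 * df2["x1"] - 7.0
        tab2 = TrainingTable(df2, tab.predictors, "scaled")
        mx2 = fit_maxentlike(tab2, 0)
        np.testing.assert_allclose(mx.predict_df(tab.data),
                                   mx2.predict_df(df2), atol=1e-6)


class TestEnsemble:
    def test_prediction_bounds_and_mask(self, ensemble, case):
        smap = rs.predict_ensemble(ensemble, case["env"])
        ok = ~smap.mask
        assert smap.values[ok].min() >= 0 and smap.values[ok].max() <= 1

    def test_mean_matches_per_cell_loop_oracle(self, ensemble, case):
        env = case["env"]
        smap = rs.predict_ensemble(ensemble, env)
        df = pd.DataFrame({n: env.layers[n].ravel() for n in ensemble.predictors})
        df["bias"] = ensemble.bias_max
        per_comp = [c.predict_df(df).reshape(env.shape)
                    for c in ensemble.components]
        for r in range(0, env.n_rows, 7):
            for c in range(0, env.n_cols, 7):
                manual = sum(p[r, c] for p in per_comp) / len(per_comp)
                assert abs(smap.values[r, c] - manual) < 1e-12

    def test_component_order_invariance(self, ensemble, case):
        import copy
        swapped = copy.copy(ensemble)
        swapped.components = ensemble.components[::-1]
        a = rs.predict_ensemble(ensemble, case["env"])
        b = rs.predict_ensemble(swapped, case["env"])
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_layer_named_in_error(self, ensemble, case):
        env = case["env"].copy()
        del env.layers["pan"]
        with pytest.raises(KeyError, match="pan"):
            rs.predict_ensemble(ensemble, env)

    def test_all_components_rank_with_truth(self):
        """Single strong predictor: every component orders cells like the
        true suitability (Spearman >= 0.9)."""
        from conftest import build_case
        case = build_case(seed=31, beta={"tmax": -2.0}, beta_sq={},
                          n_target=400, corr_len=4.0)
        table = TrainingTable(case["table"].data, ["tmax"], "mono")
        ens = rs.fit_ensemble(table, seed=0, n_trees=200)
        rows = table.data["row"].to_numpy()
        cols = table.data["col"].to_numpy()
        truth = case["suit"].values[rows, cols]
        for comp in ens.components:
            rho = spearmanr(comp.predict_df(table.data), truth).statistic
            assert rho >= 0.9, comp.name
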