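"""Posterior recovery, items-based aggregation, shadow-feature selection and
final-forest evaluation."""

import numpy as np
import pandas as pd
import pytest

from animakin import (
    DEFAULT_BETAS,
    FeatureTable,
    StudyRecipe,
    boruta_select,
    build_item_table,
    confirmatory_spec,
    evaluate_final_forest,
    fit_hierarchical_model,
    fit_similarity_models,
    gen_study,
    vif_report,
)

# reduced recording length / sampler settings keep the suite fast while
# preserving the hierarchical structure under test
FAST = dict(chains=2, iterations=1500, warmup=500)


def fast_recipe(seed, betas):
    return StudyRecipe(
        n_animators=12, n_observers=40, duration_s=8.0, seed=seed, betas=betas
    )


def make_similarity_table(seed, beta_rot=-0.35, beta_acc=-0.5, collinear=False):
    """Trial table with known similarity-difference regression structure."""
    rng = np.random.default_rng(seed)
    n_obs, n_anim, trials_per = 30, 40, 25
    rows = []
    for o in range(n_obs):
        anim_ids = rng.choice(n_anim, size=trials_per, replace=False)
        for a in anim_ids:
            rows.append({"observer_id": f"o{o}", "animation_id": f"a{a}",
                         "is_mental": bool(a % 2)})
    df = pd.DataFrame(rows)
    n = len(df)
    df["acceleration_diff"] = rng.normal(0, 1, n)
    if collinear:
        df["jerk_diff"] = df["acceleration_diff"] + rng.normal(0, 0.05, n)
    else:
        df["jerk_diff"] = rng.normal(0, 1, n)
    df["rotation_diff"] = rng.normal(0, 1, n)
    u_s = dict(zip(df.observer_id.unique(),
                   rng.normal(0, 0.4, df.observer_id.nunique())))
    u_i = dict(zip(df.animation_id.unique(),
                   rng.normal(0, 0.4, df.animation_id.nunique())))
    nonmental = (~df.is_mental).astype(float)
    df["accuracy"] = (
        1.0
        + beta_acc * df.acceleration_diff
        + beta_rot * df.rotation_diff
        + 2.0 * nonmental
        + df.observer_id.map(u_s)
        + df.animation_id.map(u_i)
        + rng.normal(0, 1, n)
    )
    return FeatureTable(df)


class TestConfirmatoryModel:
    def test_sampler_defaults_match_analysis_plan(self):
        spec = confirmatory_spec()
        assert spec.chains == 4
        assert spec.iterations == 5000
        assert spec.warmup == 1000
        assert spec.prior_sd == 10.0
        assert "jerk:jerk_diff:nonmental" in spec.fixed_terms

    def test_jerk_coefficient_recovery_over_replicates(self):
        # generative jerk slope -1.0 in the mental (reference) condition;
        # the 95% CrI should cover it in at least 18 of 20 seeded replicates
        betas = {**DEFAULT_BETAS, "jerk": -1.0}
        covered = 0
        for rep in range(20):
            study = gen_study(fast_recipe(1000 + rep, betas))
            fit = fit_hierarchical_model(
                study.trial_table, confirmatory_spec(seed=rep, **FAST)
            )
            p = fit.params["jerk"]
            covered += p.ci_lo <= -1.0 <= p.ci_hi
        assert covered >= 18

    def test_null_model_credible_intervals_cover_zero(self):
        null_betas = {k: 0.0 for k in DEFAULT_BETAS}
        names = ["jerk", "jerk_diff", "nonmental", "jerk:nonmental",
                 "jerk_diff:nonmental", "jerk:jerk_diff"]
        covered = total = 0
        for rep in range(8):
            study = gen_study(fast_recipe(2000 + rep, null_betas))
            fit = fit_hierarchical_model(
                study.trial_table, confirmatory_spec(seed=rep, **FAST)
            )
            for name in names:
                p = fit.params[name]
                covered += p.ci_lo <= 0.0 <= p.ci_hi
                total += len([name])
        total = 8 * len(names)
        assert covered / total >= 0.85

    def test_convergence_diagnostics_reported(self):
        study = gen_study(fast_recipe(7, DEFAULT_BETAS))
        fit = fit_hierarchical_model(
            study.trial_table,
            confirmatory_spec(seed=1, chains=2, iterations=4000, warmup=1000),
        )
        assert fit.divergences == 0
        assert all(np.isfinite(p.rhat) for p in fit.params.values())
        assert fit.converged

    def test_posterior_summary_invariants(self):
        study = gen_study(fast_recipe(8, DEFAULT_BETAS))
        fit = fit_hierarchical_model(
            study.trial_table, confirmatory_spec(seed=2, **FAST)
        )
        for p in fit.params.values():
            assert p.ci_lo <= p.mean <= p.ci_hi
            assert 0.0 <= p.p_gt_zero <= 1.0

    def test_cross_check_against_reml_point_estimates(self):
        # independent oracle: statsmodels MixedLM on the same data should
        # land close to the posterior means for well-identified slopes
        import statsmodels.formula.api as smf

        study = gen_study(fast_recipe(9, DEFAULT_BETAS))
        df = study.trial_table.data.copy()
        fit = fit_hierarchical_model(
            study.trial_table,
            confirmatory_spec(
                seed=3,
                random_terms=(("observer_id", None),),
                **FAST,
            ),
        )
        m = smf.mixedlm(
            "accuracy ~ jerk * jerk_diff * nonmental", df, groups=df["observer_id"]
        ).fit()
        for term, sm_name in [("jerk", "jerk"), ("nonmental", "nonmental"),
                              ("jerk:nonmental", "jerk:nonmental")]:
            assert fit.params[term].mean == pytest.approx(
                m.params[sm_name], abs=0.15
            )


class TestItemTable:
    def test_averages_per_animation_and_drops_difference_scores(self):
        df = pd.DataFrame({
            "observer_id": ["o1", "o2", "o1"],
            "animation_id": ["a1", "a1", "a2"],
            "word": ["mocking", "mocking", "fighting"],
            "is_mental": [True, True, False],
            "accuracy": [2.0, 4.0, 5.0],
            "mean_jerk": [10.0, 10.0, 30.0],
            "jerk_diff": [1.0, 2.0, 3.0],
        })
        items = build_item_table(FeatureTable(df))
        assert len(items.data) == 2
        a1 = items.data.set_index("animation_id").loc["a1"]
        assert a1["accuracy"] == pytest.approx(3.0)
        assert "jerk_diff" not in items.data.columns
        assert "observer_id" not in items.data.columns


def planted_item_table(seed, n=200, informative=2.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f"f{i}": rng.normal(0, 1, n) for i in range(1, 6)})
    df["accuracy"] = informative * df["f1"] + rng.normal(0, 1, n)
    df["animation_id"] = [f"a{i}" for i in range(n)]
    return FeatureTable(df)


BORUTA_FAST = dict(n_trees=100, max_rounds=15, seed=0)


class TestBorutaSelect:
    def test_planted_signal_confirmed_noise_rejected(self):
        correct_f1 = correct_noise = 0
        reps = 4
        for rep in range(reps):
            table = planted_item_table(300 + rep)
            decisions = {
                d.feature: d.decision
                for d in boruta_select(
                    table, [f"f{i}" for i in range(1, 6)],
                    **{**BORUTA_FAST, "seed": rep},
                )
            }
            correct_f1 += decisions["f1"] == "confirmed"
            correct_noise += all(
                decisions[f] in ("rejected", "tentative") for f in
                ("f2", "f3", "f4", "f5")
            )
        assert correct_f1 == reps
        assert correct_noise == reps

    def test_duplicated_informative_features_both_confirmed(self):
        table = planted_item_table(11)
        table.data["f1_copy"] = table.data["f1"]
        decisions = {
            d.feature: d.decision
            for d in boruta_select(
                table, ["f1", "f1_copy", "f2", "f3"], **BORUTA_FAST
            )
        }
        assert decisions["f1"] == "confirmed"
        assert decisions["f1_copy"] == "confirmed"

    def test_decisions_invariant_to_column_order(self):
        table = planted_item_table(12)
        feats = ["f1", "f2", "f3", "f4"]
        d1 = {d.feature: d.decision
              for d in boruta_select(table, feats, **BORUTA_FAST)}
        d2 = {d.feature: d.decision
              for d in boruta_select(table, feats[::-1], **BORUTA_FAST)}
        assert d1 == d2

    def test_constant_outcome_rejected(self):
        table = planted_item_table(13)
        table.data["accuracy"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            boruta_select(table, ["f1", "f2"], **BORUTA_FAST)


def step_item_table(seed, n=200, effect=2.0, noise_sd=1.0):
    """Item table whose signal a tree ensemble can represent exactly:
    y = effect * sign(f1) + noise, generative R^2 = effect^2/(effect^2+sd^2)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f"f{i}": rng.normal(0, 1, n) for i in range(1, 6)})
    df["accuracy"] = effect * np.sign(df["f1"]) + rng.normal(0, noise_sd, n)
    df["animation_id"] = [f"a{i}" for i in range(n)]
    return FeatureTable(df)


class TestFinalForest:
    def test_heldout_r2_near_generative_r2(self):
        # effect 2, noise sd 1: generative R^2 = 4 / 5 = 0.8
        table = step_item_table(21)
        out = evaluate_final_forest(table, ["f1"], n_trees=300, seed=5)
        assert out["r_squared"] == pytest.approx(0.8, abs=0.1)
        assert out["p_value"] < 0.001
        assert out["n_train"] == 140 and out["n_test"] == 60

    def test_permuted_outcome_r2_concentrates_near_zero(self):
        # destroyed signal: no positive skill, held-out R^2 at or below zero
        table = step_item_table(22)
        rng = np.random.default_rng(0)
        r2s = []
        for rep in range(5):
            shuffled = table.copy()
            shuffled.data["accuracy"] = rng.permutation(
                shuffled.data["accuracy"].to_numpy()
            )
            out = evaluate_final_forest(
                shuffled, [f"f{i}" for i in range(1, 6)], n_trees=200, seed=rep
            )
            r2s.append(out["r_squared"])
        assert max(r2s) < 0.05
        assert np.mean(r2s) == pytest.approx(0.0, abs=0.25)

    def test_same_seed_same_split_and_score(self):
        table = planted_item_table(23)
        o1 = evaluate_final_forest(table, ["f1", "f2"], n_trees=50, seed=3)
        o2 = evaluate_final_forest(table, ["f1", "f2"], n_trees=50, seed=3)
        assert o1 == o2

    def test_empty_feature_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            evaluate_final_forest(planted_item_table(24), [])


class TestSimilarityModels:
    def test_rotation_difference_recovery(self):
        # coverage of the generative slope across seeded replicates, both
        # models; pooled posterior mean should sit near the true -0.35
        covered, means = 0, []
        reps = 5
        for rep in range(reps):
            table = make_similarity_table(31 + rep, beta_rot=-0.35)
            fit1, fit2, vifs = fit_similarity_models(table, seed=rep, **FAST)
            for fit in (fit1, fit2):
                p = fit.params["rotation_diff"]
                covered += p.ci_lo <= -0.35 <= p.ci_hi
                means.append(p.mean)
            assert all(v < 5 for v in vifs.values())
        # both fits share each dataset, so one unlucky draw costs two checks
        assert covered >= 2 * reps - 3
        assert np.mean(means) == pytest.approx(-0.35, abs=0.15)

    def test_collinear_difference_scores_flagged_by_vif(self):
        table = make_similarity_table(32, collinear=True)
        vifs = vif_report(
            table, ["acceleration_diff", "rotation_diff", "jerk_diff"]
        )
        assert vifs["acceleration_diff"] > 10
        assert vifs["jerk_diff"] > 10
        assert vifs["rotation_diff"] < 5

    def test_null_similarity_coefficients_cover_zero(self):
        table = make_similarity_table(33, beta_rot=0.0, beta_acc=0.0)
        fit1, _, _ = fit_similarity_models(table, seed=2, **FAST)
        for term in ("acceleration_diff", "rotation_diff"):
            p = fit1.params[term]
            assert p.ci_lo <= 0.0 <= p.ci_hi
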