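"""BLUE adjustment, ANOVA and heritability against hand and REML oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtgs.phenotype_adjustment import (
    VarianceComponents,
    anova_mean_squares,
    blue_table,
    broad_sense_heritability,
    estimate_variance_components,
    fit_blues_combined,
    fit_blues_single_env,
    trait_correlations,
)
from mtgs.synthetic_data import DesignSpec, SimParams, simulate_markers, simulate_trial


def _params(h2, gcor=0.5, gxe=1.0, traits=("A", "B")):
    return SimParams(
        trait_names=traits,
        heritabilities={t: h2 for t in traits},
        trait_means={t: 10.0 for t in traits},
        trait_sds={t: 2.0 for t in traits},
        genetic_correlations=np.array([[1.0, gcor], [gcor, 1.0]]),
        gxe_to_resid={t: gxe for t in traits},
    )


class TestHeritabilityFormula:
    def test_noise_free_limit_is_one(self):
        assert broad_sense_heritability(VarianceComponents(1.0, 0.0, 0.0, 3, 1)) == 1.0

    def test_closed_form_half(self):
        # 1 / (1 + 1/2 + 1/2) = 0.5
        assert broad_sense_heritability(VarianceComponents(1.0, 1.0, 1.0, 2, 1)) == pytest.approx(0.5)

    def test_all_zero_components_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            broad_sense_heritability(VarianceComponents(0.0, 0.0, 0.0, 3, 1))

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            broad_sense_heritability(VarianceComponents(-1.0, 0.0, 1.0, 2, 1))

    @given(
        sg=st.floats(0.01, 10), sgxe=st.floats(0, 10), se=st.floats(0, 10),
        n=st.integers(1, 10), bump=st.floats(0.01, 5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotonicity(self, sg, sgxe, se, n, bump):
        base = broad_sense_heritability(VarianceComponents(sg, sgxe, se, n, 1))
        assert broad_sense_heritability(VarianceComponents(sg + bump, sgxe, se, n, 1)) >= base
        assert broad_sense_heritability(VarianceComponents(sg, sgxe + bump, se, n, 1)) <= base
        assert broad_sense_heritability(VarianceComponents(sg, sgxe, se + bump, n, 1)) <= base
        assert broad_sense_heritability(VarianceComponents(sg, sgxe, se, n + 1, 1)) >= base


class TestSingleEnvBlues:
    def test_saturated_case_returns_raw_values(self):
        # one block, no checks, no covariate: BLUE is the plot value itself
        trial = pd.DataFrame(
            {
                "env": ["E1"] * 4,
                "block": ["B1"] * 4,
                "entry_id": ["g1", "g2", "g3", "g4"],
                "is_check": [False] * 4,
                "check_id": [None] * 4,
                "A": [1.0, 2.0, 3.5, -1.0],
            }
        )
        blues = fit_blues_single_env(trial, "E1", "A", include_covariate=False)
        np.testing.assert_allclose(blues.to_numpy(), [1.0, 2.0, 3.5, -1.0], atol=1e-8)

    def test_covariate_shift_invariance(self, small_trial):
        trial = small_trial[0]
        b1 = fit_blues_single_env(trial, "E1", "T1")
        shifted = trial.copy()
        shifted["days_to_anthesis"] = shifted["days_to_anthesis"] + 100.0
        b2 = fit_blues_single_env(shifted, "E1", "T1")
        np.testing.assert_allclose(b1.to_numpy(), b2.to_numpy(), atol=1e-6)

    def test_block_relabeling_invariance(self, small_trial):
        trial = small_trial[0]
        b1 = fit_blues_single_env(trial, "E1", "T1")
        relabeled = trial.copy()
        relabeled["block"] = relabeled["block"].map(lambda b: f"blk_{b}!")
        b2 = fit_blues_single_env(relabeled, "E1", "T1")
        np.testing.assert_allclose(b1.to_numpy(), b2.to_numpy(), atol=1e-8)

    def test_recovers_true_genetic_values(self):
        # with replicated entries the BLUE-truth correlation approaches
        # sqrt(H2); at H2=0.9 that is ~0.95
        markers = simulate_markers(103, 400, seed=31)
        design = DesignSpec(n_lines=100, n_checks=3, n_blocks_per_env=4,
                            environments=("E1",), n_rep=3)
        trial, truth = simulate_trial(markers, design, _params(0.9, gxe=0.05), seed=32)
        blues = fit_blues_single_env(trial, "E1", "A")
        bv = truth.breeding_values["A"].loc[blues.index]
        assert np.corrcoef(blues, bv)[0, 1] > 0.9

    def test_missing_env_errors(self, small_trial):
        with pytest.raises(ValueError, match="no records"):
            fit_blues_single_env(small_trial[0], "nowhere", "T1")


class TestCombinedBlues:
    def test_one_value_per_genotype(self, small_trial):
        trial, truth, markers, design = small_trial
        blues = fit_blues_combined(trial, "T1")
        entries = trial.loc[~trial["is_check"], "entry_id"].unique()
        assert set(blues.index) == set(entries)
        assert blues.notna().all()

    def test_no_interaction_limit_matches_mean_of_env_blues(self):
        markers = simulate_markers(43, 300, seed=33)
        design = DesignSpec(n_lines=40, n_checks=3, n_blocks_per_env=8,
                            environments=("E1", "E2", "E3"))
        trial, _ = simulate_trial(markers, design, _params(0.6, gxe=0.001), seed=34)
        # covariate off: per-env fits estimate 3 independent slopes, which
        # adds noise orthogonal to the interaction property under test
        combined = fit_blues_combined(trial, "A", include_covariate=False)
        per_env = pd.concat(
            [fit_blues_single_env(trial, e, "A", include_covariate=False)
             for e in design.environments], axis=1
        ).mean(axis=1)
        diff = (combined - per_env.loc[combined.index]).abs()
        assert np.corrcoef(combined, per_env.loc[combined.index])[0, 1] > 0.95
        assert diff.mean() < 0.25 * trial["A"].std()

    def test_recovers_true_genetic_values(self):
        markers = simulate_markers(103, 400, seed=35)
        design = DesignSpec(n_lines=100, n_checks=3, n_blocks_per_env=4,
                            environments=("E1", "E2", "E3"))
        trial, truth = simulate_trial(markers, design, _params(0.8), seed=36)
        blues = fit_blues_combined(trial, "A")
        bv = truth.breeding_values["A"].loc[blues.index]
        assert np.corrcoef(blues, bv)[0, 1] > 0.85

    def test_single_env_rejected(self, small_trial):
        trial = small_trial[0]
        sub = trial[trial["env"] == "E1"]
        with pytest.raises(ValueError, match="2 environments"):
            fit_blues_combined(sub, "T1")


class TestAnova:
    @staticmethod
    def _balanced_trial():
        # 2 envs x 2 genotypes x 3 replicate blocks, fully crossed
        rows = []
        y = iter([5.0, 6.0, 4.0, 7.0, 8.0, 6.5, 9.0, 10.0, 8.5, 11.0, 12.0, 13.0])
        for env in ("E1", "E2"):
            for g in ("g1", "g2"):
                for b in ("B1", "B2", "B3"):
                    rows.append([env, b, g, False, None, next(y)])
        return pd.DataFrame(rows, columns=["env", "block", "entry_id", "is_check", "check_id", "A"])

    def test_matches_hand_computed_two_way_anova(self):
        trial = self._balanced_trial()
        tab = anova_mean_squares(trial, "A")
        # textbook oracle: balanced two-way sums of squares by direct summation
        y = trial["A"].to_numpy().reshape(2, 2, 3)  # env x geno x rep
        grand = y.mean()
        ss_g = 6 * ((y.mean(axis=(0, 2)) - grand) ** 2).sum()
        ss_e = 6 * ((y.mean(axis=(1, 2)) - grand) ** 2).sum()
        cell = y.mean(axis=2)
        ss_gxe = 3 * ((cell - y.mean(axis=(1, 2))[:, None]
                       - y.mean(axis=(0, 2))[None, :] + grand) ** 2).sum()
        ss_res = ((y - cell[:, :, None]) ** 2).sum()
        assert tab.loc["Genotype (G)", "mean_sq"] == pytest.approx(ss_g / 1)
        assert tab.loc["Environment (E)", "mean_sq"] == pytest.approx(ss_e / 1)
        assert tab.loc["G x E", "mean_sq"] == pytest.approx(ss_gxe / 1)
        assert tab.loc["Residual", "mean_sq"] == pytest.approx(ss_res / 8)

    def test_large_env_effects_dominate(self):
        markers = simulate_markers(33, 200, seed=37)
        design = DesignSpec(n_lines=30, n_checks=3, n_blocks_per_env=3,
                            environments=("E1", "E2", "E3"))
        params = _params(0.4)
        params.env_effect_sd_scale = 10.0
        trial, _ = simulate_trial(markers, design, params, seed=38)
        tab = anova_mean_squares(trial, "A")
        assert tab.loc["Environment (E)", "mean_sq"] > 50 * tab.loc["Residual", "mean_sq"]
        assert tab.loc["Environment (E)", "p_value"] < 1e-6

    def test_null_genotype_type_one_error_controlled(self):
        # no genetic or GxE variance: genotype p-values should be uniform;
        # at the 5% level the rejection rate over 200 replicates stays inside
        # a binomial 99.9% envelope (0, 0.105]
        rng = np.random.default_rng(99)
        rejections_g = 0
        n_rep = 200
        for _ in range(n_rep):
            rows = []
            for env in ("E1", "E2"):
                mu_e = rng.normal(0, 1)
                for g in [f"g{i}" for i in range(12)]:
                    for b in ("B1", "B2"):
                        rows.append([env, b, g, False, None, mu_e + rng.normal()])
            trial = pd.DataFrame(rows, columns=["env", "block", "entry_id", "is_check", "check_id", "A"])
            tab = anova_mean_squares(trial, "A")
            rejections_g += tab.loc["Genotype (G)", "p_value"] < 0.05
        assert rejections_g / n_rep <= 0.105

    def test_single_env_errors(self):
        trial = self._balanced_trial()
        with pytest.raises(ValueError, match="single environment"):
            anova_mean_squares(trial[trial["env"] == "E1"], "A")


class TestVarianceComponents:
    def test_h2_recovery_around_truth(self):
        # mean estimate over replicate simulations should bracket the target
        target = 0.4
        ests = []
        for rep in range(12):
            markers = simulate_markers(53, 250, seed=500 + rep)
            design = DesignSpec(n_lines=50, n_checks=3, n_blocks_per_env=3,
                                environments=("E1", "E2", "E3"))
            trial, _ = simulate_trial(markers, design, _params(target), seed=600 + rep)
            vc = estimate_variance_components(trial, "A")
            ests.append(broad_sense_heritability(vc))
        assert 0.3 < np.mean(ests) < 0.5

    def test_em_reml_agrees_with_statsmodels_on_one_component(self):
        # independent oracle: statsmodels MixedLM on a random-intercept model
        import statsmodels.api as sm
        from mtgs.reml import dummy_matrix, fit_mixed_model

        rng = np.random.default_rng(7)
        groups = np.repeat(np.arange(12), 8)
        u = rng.normal(0, 1.5, 12)
        x = rng.normal(size=96)
        y = 2.0 + 0.5 * x + u[groups] + rng.normal(0, 0.8, 96)
        X = np.column_stack([np.ones(96), x])
        Z, _ = dummy_matrix(groups)
        ours = fit_mixed_model(y, X, {"grp": Z})
        sm_fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
        assert ours.sigma2["grp"] == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), rel=0.05)
        assert ours.sigma2["residual"] == pytest.approx(float(sm_fit.scale), rel=0.05)
        np.testing.assert_allclose(ours.beta, sm_fit.fe_params, atol=1e-3)


class TestTraitCorrelations:
    def test_diagonal_is_one_and_symmetric(self, small_trial):
        trial = small_trial[0]
        bt = blue_table(trial, "E1", ["T1", "T2"])
        r, p = trait_correlations(bt)
        assert r.loc["T1", "T1"] == 1.0
        assert r.loc["T1", "T2"] == pytest.approx(r.loc["T2", "T1"])
        assert 0 <= p.loc["T1", "T2"] <= 1

    def test_sign_flip_negates_correlation(self, small_trial):
        trial = small_trial[0]
        bt = blue_table(trial, "E1", ["T1", "T2"])
        r1, _ = trait_correlations(bt)
        flipped = bt.values.copy()
        flipped["T2"] = -flipped["T2"]
        r2, _ = trait_correlations(flipped)
        assert r1.loc["T1", "T2"] == pytest.approx(-r2.loc["T1", "T2"])

    def test_constant_column_yields_missing(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 5.0, 5.0, 5.0]})
        r, _ = trait_correlations(df)
        assert np.isnan(r.loc["a", "b"])

    def test_blue_level_correlation_attenuated_toward_zero(self):
        # genetic correlation 0.6 at h2~0.5 attenuates to roughly
        # 0.6 * h2_single_env at the per-env BLUE level
        markers = simulate_markers(239, 300, seed=41)
        design = DesignSpec(n_lines=236, n_checks=3, n_blocks_per_env=12,
                            environments=("E1",))
        trial, _ = simulate_trial(markers, design, _params(0.5, gcor=0.6), seed=42)
        bt = blue_table(trial, "E1", ["A", "B"])
        r, p = trait_correlations(bt)
        assert 0.1 < r.loc["A", "B"] < 0.6
        assert p.loc["A", "B"] < 0.05
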