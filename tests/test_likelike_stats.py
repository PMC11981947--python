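"""Cohort comparisons, binned effects, GLMM wrappers and residual regressions."""

import numpy as np
import pandas as pd
import pytest

from liketolike.glmm import GlmmResult
from liketolike.likelike_stats import (
    BinnedEffect,
    GlmmFit,
    GlmmSpec,
    centered_binned_effect,
    cohort_mean_test,
    extract_likelike_coefficients,
    fit_likelike_glmm,
    residual_anatomy_regression,
    somatic_distance_profile,
)


def _pair_frame(pre, post, cohort, metric, projection="V1->V1", n_syn=None, L_d=None):
    n = len(pre)
    return pd.DataFrame(
        {
            "pre_id": pre, "post_id": post, "cohort": cohort,
            "projection": [projection] * n, "metric": metric,
            "n_syn": n_syn if n_syn is not None else [1] * n,
            "L_d": L_d if L_d is not None else [10.0] * n,
        }
    )


class TestCohortMeanTest:
    @staticmethod
    def _build(diffs):
        """Each presyn: 12 connected targets with metric mu+d, 12 ADP with mu."""
        rows = []
        post = 0
        for k, d in enumerate(diffs):
            for _ in range(12):
                rows.append((k, post, "connected", 0.5 + d))
                post += 1
                rows.append((k, post, "adp_control", 0.5))
                post += 1
        pre, po, co, me = zip(*rows)
        return _pair_frame(list(pre), list(po), list(co), list(me))

    def test_identical_means_give_t0_p1(self):
        table = self._build([0.0] * 15)
        out = cohort_mean_test(table, "metric")
        row = out[(out["cohort_a"] == "connected") & (out["cohort_b"] == "adp_control")]
        assert np.isclose(row["t"].iloc[0], 0.0)
        assert np.isclose(row["p"].iloc[0], 1.0)

    def test_closed_form_paired_t(self):
        # 30 presyn, differences with mean 0.1 and sd 0.05:
        # t = 0.1 / (0.05 / sqrt(30)) ~ 10.95
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1, 30)
        d = (d - d.mean()) / d.std(ddof=1) * 0.05 + 0.1  # exact mean/sd
        out = cohort_mean_test(self._build(d), "metric")
        row = out[(out["cohort_a"] == "connected") & (out["cohort_b"] == "adp_control")]
        t_expected = 0.1 / (0.05 / np.sqrt(30))
        assert np.isclose(row["t"].iloc[0], t_expected, rtol=1e-6)
        assert row["p"].iloc[0] < 1e-9

    def test_presyn_with_ten_targets_excluded(self):
        # strictly more than ten connected targets required
        rows = []
        post = 0
        for k in range(3):
            n_conn = 10 if k == 0 else 12
            for _ in range(n_conn):
                rows.append((k, post, "connected", 0.6))
                post += 1
                rows.append((k, post, "adp_control", 0.5))
                post += 1
        pre, po, co, me = zip(*rows)
        out = cohort_mean_test(_pair_frame(list(pre), list(po), list(co), list(me)), "metric")
        row = out[(out["cohort_a"] == "connected") & (out["cohort_b"] == "adp_control")]
        assert row["n_presyn"].iloc[0] == 2

    def test_too_few_presyn_untestable(self):
        table = self._build([0.1])
        out = cohort_mean_test(table, "metric")
        row = out[(out["cohort_a"] == "connected") & (out["cohort_b"] == "adp_control")]
        assert not row["testable"].iloc[0]


class TestCenteredBinnedEffect:
    @staticmethod
    def _records(rng, n_presyn=25, n_per=120, slope=0.0, noise=1.0):
        rows = []
        for pre in range(n_presyn):
            x = rng.normal(0, 1, n_per)
            y = slope * x + rng.normal(0, noise, n_per) + rng.normal()  # presyn offset
            for j in range(n_per):
                rows.append(
                    {
                        "pre_id": pre, "post_id": 10_000 + pre * n_per + j,
                        "sim": x[j], "L_d": max(y[j] + 5.0, 0.0), "n_syn": 0,
                    }
                )
        return pd.DataFrame(rows)

    def test_null_bins_near_zero(self):
        rng = np.random.default_rng(1)
        recs = self._records(rng, slope=0.0)
        eff = centered_binned_effect(recs, "sim", mode="Ld", bins=8, n_boot=200, seed=0)
        ok = eff.included
        assert ok.any()
        assert np.all(np.abs(eff.bin_mean[ok]) < 3.5 * eff.bin_se[ok])

    def test_recovers_injected_slope(self):
        rng = np.random.default_rng(2)
        recs = self._records(rng, slope=2.0, noise=0.5)
        eff = centered_binned_effect(recs, "sim", mode="Ld", bins=8, n_boot=100, seed=0)
        ok = eff.included
        centers = 0.5 * (eff.bin_edges[:-1] + eff.bin_edges[1:])[ok]
        fit = np.polyfit(centers, eff.bin_mean[ok], 1)
        assert abs(fit[0] - 2.0) < 0.2

    def test_sparse_bin_excluded(self):
        rng = np.random.default_rng(3)
        recs = self._records(rng, n_presyn=12, n_per=20)
        # add an outlying cluster of 9 pairs far in x
        extra = recs.iloc[:9].copy()
        extra["sim"] = 40.0
        recs = pd.concat([recs, extra], ignore_index=True)
        eff = centered_binned_effect(recs, "sim", mode="Ld",
                                     bins=np.array([-5, 5, 50.0]), n_boot=50, seed=0)
        assert not eff.included[-1]  # 9 pairs <= 10

    def test_density_mode_restricts_to_positive_ld(self):
        recs = pd.DataFrame(
            {
                "pre_id": [0, 0, 0, 1, 1, 1],
                "post_id": range(6),
                "sim": [0.1, 0.2, 0.3, 0.1, 0.2, 0.3],
                "L_d": [0.0, 10.0, 20.0, 0.0, 10.0, 20.0],
                "n_syn": [0, 1, 2, 0, 1, 2],
            }
        )
        eff = centered_binned_effect(recs, "sim", mode="density", bins=3, n_boot=10, seed=0)
        assert eff.n_pairs.sum() == 4  # the L_d = 0 rows are excluded


class TestGlmmWrappers:
    def test_poisson_recovery_through_pair_table(self, small_pair_world):
        pairs = small_pair_world["pairs"]
        fit = fit_likelike_glmm(pairs, GlmmSpec(response="N_syn_per_Ld", interaction=False))
        i = fit.result.exog_names.index("sim")
        beta_true = small_pair_world["config"].beta_synaptic
        assert abs(fit.result.params[i] - beta_true) < 3 * fit.result.bse[i]

    def test_tweedie_recovery_through_pair_table(self, small_pair_world):
        pairs = small_pair_world["pairs"]
        fit = fit_likelike_glmm(
            pairs, GlmmSpec(response="L_d", interaction=False, xi=1.4)
        )
        i = fit.result.exog_names.index("sim")
        beta_true = small_pair_world["config"].beta_axonal
        assert abs(fit.result.params[i] - beta_true) < 3.5 * fit.result.bse[i]

    def test_offset_formulation_equals_density_slopes(self, small_pair_world):
        # the conversion-rate model is algebraically a density model; the
        # dedicated equivalence check lives with the engine tests, here we
        # confirm the wrapper honours the offset (slopes differ from the
        # marginal count model, which absorbs the axonal scale too)
        pairs = small_pair_world["pairs"]
        marginal = fit_likelike_glmm(pairs, GlmmSpec(response="N_syn", interaction=False))
        rate = fit_likelike_glmm(pairs, GlmmSpec(response="N_syn_per_Ld", interaction=False))
        i = marginal.result.exog_names.index("sim")
        cfg = small_pair_world["config"]
        assert marginal.result.params[i] > rate.result.params[i]  # includes axonal part
        assert abs(marginal.result.params[i] - (cfg.beta_axonal + cfg.beta_synaptic)) < 0.2


class TestExtractCoefficients:
    @staticmethod
    def _toy_fit(n_synapses=(100, 100), n_presyn=(8, 8), shares=(0.2, 0.2)):
        names = ["intercept", "sim", "proj[B]", "sim:proj[B]"]
        params = np.array([0.0, 0.2, 0.1, 0.1])
        cov = np.diag([0.01, 0.0004, 0.01, 0.0009])
        result = GlmmResult(
            family="poisson", params=params, bse=np.sqrt(np.diag(cov)),
            exog_names=names, random_effects=np.zeros(2), group_labels=["a", "b"],
            sigma2=0.1, phi=1.0, xi=None, converged=True, n_obs=100,
            cov_params=cov,
        )
        from liketolike.likelike_stats import _conditional_slopes

        slope_table = _conditional_slopes(result, ["A", "B"], "A")
        stats = pd.DataFrame(
            {
                "projection": ["A", "B"],
                "n_pairs": [50, 50],
                "n_presyn": list(n_presyn),
                "n_synapses": list(n_synapses),
                "max_presyn_share": list(shares),
            }
        )
        return GlmmFit(
            spec=GlmmSpec(response="N_syn"), result=result, projections=["A", "B"],
            slope_table=slope_table, n_pairs=100, data_stats=stats,
        )

    def test_conditional_slope_algebra(self):
        out = extract_likelike_coefficients(self._toy_fit(), apply_filters=False)
        a = out.set_index("projection")
        assert np.isclose(a.loc["A", "slope"], 0.2)
        assert np.isclose(a.loc["B", "slope"], 0.2 + 0.1)
        # delta method with diagonal covariance
        assert np.isclose(a.loc["B", "se"], np.sqrt(0.0004 + 0.0009))

    def test_low_synapse_projection_omitted(self):
        out = extract_likelike_coefficients(self._toy_fit(n_synapses=(25, 100)))
        a = out.set_index("projection")
        assert not a.loc["A", "reported"]
        assert np.isnan(a.loc["A", "slope"])
        assert a.loc["B", "reported"]

    def test_dominant_presyn_projection_omitted(self):
        out = extract_likelike_coefficients(self._toy_fit(shares=(0.6, 0.2)))
        assert not out.set_index("projection").loc["A", "reported"]

    def test_few_presyn_projection_omitted(self):
        out = extract_likelike_coefficients(self._toy_fit(n_presyn=(4, 8)))
        assert not out.set_index("projection").loc["A", "reported"]


class TestResidualRegression:
    @staticmethod
    def _pairs(rng, n=5000, cleft_effect=0.0, nsyn_effect=0.0):
        L = rng.gamma(2, 50, n)
        n_syn = rng.poisson(1.5, n) + 1
        cleft = rng.lognormal(8.0, 0.5, n)
        sim = 0.002 * L + cleft_effect * np.log10(cleft) + nsyn_effect * n_syn
        sim = sim + rng.normal(0, 0.05, n)
        return pd.DataFrame(
            {"sim": sim, "L_d": L, "n_syn": n_syn, "mean_cleft_volume": cleft}
        )

    def test_pure_ld_dependence_gives_null_step2(self):
        rng = np.random.default_rng(5)
        out = residual_anatomy_regression(self._pairs(rng), ["sim"])
        for _, r in out.iterrows():
            assert abs(r["coef"]) < 3 * r["se"]

    def test_cleft_volume_effect_recovered(self):
        rng = np.random.default_rng(6)
        out = residual_anatomy_regression(
            self._pairs(rng, cleft_effect=0.02), ["sim"]
        ).set_index("predictor")
        assert out.loc["log10_cleft", "coef"] > 0
        assert out.loc["log10_cleft", "p"] < 0.05

    def test_multisynaptic_bonus_recovered(self):
        rng = np.random.default_rng(7)
        out = residual_anatomy_regression(
            self._pairs(rng, nsyn_effect=0.05), ["sim"]
        ).set_index("predictor")
        assert out.loc["n_syn", "coef"] > 0
        assert out.loc["n_syn", "p"] < 0.05

    def test_constant_predictor_reported_absent(self):
        rng = np.random.default_rng(8)
        pairs = self._pairs(rng, n=200)
        pairs["n_syn"] = 2
        out = residual_anatomy_regression(pairs, ["sim"]).set_index("predictor")
        assert np.isnan(out.loc["n_syn", "coef"])


class TestSomaticDistanceProfile:
    def test_bin_membership(self):
        recs = pd.DataFrame(
            {"somatic_distance": [150.0], "n_syn": [1], "sim": [0.5],
             "pre_id": [0], "post_id": [1]}
        )
        out = somatic_distance_profile(recs, "sim")
        row = out[(out["group"] == "connected") & (out["n"] > 0)]
        assert row["bin_left"].iloc[0] == 100.0
        assert row["bin_right"].iloc[0] == 200.0

    def test_hand_checked_toy_table(self):
        recs = pd.DataFrame(
            {
                "somatic_distance": [50, 60, 150, 160, 250, 260.0],
                "n_syn": [1, 0, 1, 0, 1, 0],
                "sim": [0.4, 0.1, 0.6, 0.2, 0.8, 0.3],
                "pre_id": [0] * 6,
                "post_id": range(6),
            }
        )
        out = somatic_distance_profile(recs, "sim").set_index(
            ["bin_left", "group"]
        )
        assert np.isclose(out.loc[(0.0, "connected"), "mean"], 0.4)
        assert np.isclose(out.loc[(100.0, "unconnected"), "mean"], 0.2)
        assert np.isclose(out.loc[(200.0, "connected"), "mean"], 0.8)

    def test_distance_independent_gap_is_flat(self):
        rng = np.random.default_rng(9)
        n = 4000
        d = rng.uniform(0, 400, n)
        conn = rng.random(n) < 0.3
        sim = 0.1 + 0.15 * conn + rng.normal(0, 0.1, n)
        recs = pd.DataFrame(
            {"somatic_distance": d, "n_syn": conn.astype(int), "sim": sim,
             "pre_id": np.zeros(n, int), "post_id": np.arange(n)}
        )
        out = somatic_distance_profile(recs, "sim")
        piv = out.pivot_table(index="bin_left", columns="group", values="mean")
        gaps = (piv["connected"] - piv["unconnected"]).dropna()
        assert gaps.std() < 0.05
        assert np.all(np.abs(gaps - 0.15) < 0.05)
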