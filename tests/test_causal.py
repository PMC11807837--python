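"""Backdoor control sets, standardization contract, OLS invariances and the
predictive (AICc) companion model."""

import numpy as np
import pandas as pd
import pytest

from traitshift.causal import (
    BackdoorEffectEstimator,
    backdoor_controls,
    default_dag,
    fit_predictive_model,
    run_effect_grid,
    transform_and_standardize,
)


class TestBackdoorControls:
    @pytest.mark.parametrize(
        "exposure,expected",
        [
            ("forest_loss", []),
            ("n_patches", ["forest_loss"]),
            ("edge_density", ["forest_loss", "n_patches"]),
            ("degradation", ["edge_density", "forest_loss", "n_patches"]),
        ],
    )
    def test_minimal_sets(self, exposure, expected):
        assert backdoor_controls(default_dag(), exposure) == expected

    def test_unknown_exposure(self):
        with pytest.raises(KeyError):
            backdoor_controls(default_dag(), "climate")


class TestStandardization:
    def test_mean_zero_unit_sd_per_group(self, rng):
        df = pd.DataFrame({"forest_loss": rng.uniform(0, 100, 60), "outcome": rng.normal(size=60)})
        grp = pd.Series(["a"] * 30 + ["b"] * 30, index=df.index)
        out, dropped = transform_and_standardize(df, group=grp)
        assert not dropped
        for g in ("a", "b"):
            sub = out[grp == g]
            assert np.allclose(sub.mean(), 0, atol=1e-12)
            assert np.allclose(sub.std(ddof=0), 1, atol=1e-12)

    def test_log1p_of_zero_loss_is_zero(self):
        df = pd.DataFrame({"forest_loss": [0.0, 10.0, 50.0]})
        out, _ = transform_and_standardize(df)
        expected = np.log1p(df["forest_loss"])
        expected = (expected - expected.mean()) / expected.std(ddof=0)
        assert np.allclose(out["forest_loss"], expected)

    def test_constant_predictor_dropped(self):
        df = pd.DataFrame({"edge_density": [0.4, 0.4, 0.4], "outcome": [1.0, 2.0, 3.0]})
        out, dropped = transform_and_standardize(df)
        assert dropped == ["edge_density"]
        assert "edge_density" not in out


class TestEstimator:
    def test_outcome_equal_to_exposure(self, rng):
        x = rng.standard_normal(30)
        data = pd.DataFrame({"forest_loss": x})
        est = BackdoorEffectEstimator(exposure="forest_loss", spatial=False).fit(data, x)
        assert est.beta_ == pytest.approx(1.0, abs=1e-10)
        assert est.r2_adj_ == pytest.approx(1.0, abs=1e-10)

    def test_control_order_irrelevant(self, rng):
        n = 80
        df = pd.DataFrame(rng.standard_normal((n, 3)), columns=["degradation", "forest_loss", "n_patches"])
        y = df["degradation"] + 0.5 * df["forest_loss"] + rng.standard_normal(n)
        a = BackdoorEffectEstimator("degradation", controls=("forest_loss", "n_patches"), spatial=False).fit(df, y)
        b = BackdoorEffectEstimator("degradation", controls=("n_patches", "forest_loss"), spatial=False).fit(df, y)
        assert a.beta_ == pytest.approx(b.beta_, abs=1e-12)

    def test_standardized_beta_invariant_to_raw_units(self, rng):
        n = 100
        raw = pd.DataFrame({
            "forest_loss": rng.uniform(0, 100, n),
            "n_patches": rng.integers(1, 50, n).astype(float),
            "edge_density": rng.uniform(0, 1, n),
            "degradation": rng.uniform(0.02, 0.08, n),
            "outcome": rng.standard_normal(n),
        })
        rescaled = raw.copy()
        rescaled["edge_density"] *= 100  # percent instead of fraction

        def beta(df):
            std, _ = transform_and_standardize(df, log_variables=())
            est = BackdoorEffectEstimator("edge_density", spatial=False)
            return est.fit(std, std["outcome"]).beta_

        assert beta(raw) == pytest.approx(beta(rescaled), abs=1e-10)

    def test_rank_deficiency_is_named(self, rng):
        df = pd.DataFrame({"forest_loss": rng.standard_normal(20)})
        df["n_patches"] = df["forest_loss"]
        with pytest.raises(ValueError, match="rank"):
            BackdoorEffectEstimator("n_patches", controls=("forest_loss",), spatial=False).fit(
                df, rng.standard_normal(20)
            )


@pytest.fixture(scope="module")
def grid(small_tables):
    community, traits, dist, _ = small_tables
    return run_effect_grid(
        community, traits, dist,
        trait_names=["wood_density", "seed_mass"],
        statistics=("cwm",),
        scales=[2000],
        spatial=False,
    )


class TestEffectGrid:
    def test_combinatorics(self, grid):
        # 4 exposures x 2 traits x 1 statistic x 2 regions x 1 scale
        assert len(grid) == 16

    def test_no_failures_and_estimates_finite(self, grid):
        assert grid["error"].isna().all()
        assert np.isfinite(grid["beta"]).all()
        assert (grid["ci_low"] <= grid["beta"]).all() and (grid["beta"] <= grid["ci_high"]).all()

    def test_forest_loss_depresses_wood_density(self, grid, small_tables):
        truth = small_tables[3]
        sub = grid[(grid["exposure"] == "forest_loss") & (grid["trait"] == "wood_density")]
        expected = truth.cwm_effects.query(
            "trait=='wood_density' and scale==2000 and exposure=='forest_loss'"
        )["plim_backdoor"].iloc[0]
        assert (sub["beta"] < 0).all()
        assert sub["beta"].mean() == pytest.approx(expected, abs=0.2)

    def test_rerun_is_identical(self, grid, small_tables):
        community, traits, dist, _ = small_tables
        again = run_effect_grid(
            community, traits, dist,
            trait_names=["wood_density", "seed_mass"],
            statistics=("cwm",),
            scales=[2000],
            spatial=False,
        )
        pd.testing.assert_frame_equal(grid, again)


class TestPredictiveModel:
    def test_selects_generative_variable(self, rng):
        """AICc always keeps the generative exposure and prunes noise exposures
        at the rate information criteria allow (each noise variable enters with
        probability ~ P(chi2_1 > 2) ~ 0.16, so the exact model in ~ 0.84^3 ~ 60%
        of runs)."""
        exact = 0
        sizes = []
        for s in range(40):
            r = np.random.default_rng(s)
            n = 120
            df = pd.DataFrame(r.standard_normal((n, 4)), columns=["forest_loss", "n_patches", "edge_density", "degradation"])
            df["outcome"] = 0.7 * df["forest_loss"] + r.standard_normal(n)
            res = fit_predictive_model(df)
            assert "forest_loss" in res["chosen"]
            exact += res["chosen"] == ("forest_loss",)
            sizes.append(len(res["chosen"]))
        assert exact >= 16  # >= 40%: clearly prunes, at AICc's own rate
        assert np.mean(sizes) < 2.2

    def test_pure_noise_outcome(self, rng):
        n = 100
        df = pd.DataFrame(rng.standard_normal((n, 4)), columns=["forest_loss", "n_patches", "edge_density", "degradation"])
        df["outcome"] = rng.standard_normal(n)
        res = fit_predictive_model(df)
        assert len(res["chosen"]) <= 1
        assert res["r2_adj"] < 0.1

    def test_chosen_model_not_worse_than_loss_only(self, small_tables):
        community, traits, dist, _ = small_tables
        env = dist.at_scale(2000)
        w = community.abundance.to_numpy()
        t = traits.data["wood_density"].to_numpy()
        env = env.loc[community.abundance.index]
        env["outcome"] = np.nansum(w * t, axis=1) / w.sum(axis=1)
        std, _ = transform_and_standardize(env)
        res = fit_predictive_model(std)
        loss_only = [r for r in res["trail"] if r["subset"] == ("forest_loss",)][0]
        assert res["r2_adj"] >= loss_only["r2_adj"] - 0.05
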