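"""Niche centroids, the permutation null, classification invariances, and
the trait signal in SES values."""

import numpy as np
import pandas as pd
import pytest

from traitshift.io import CommunityData, DisturbanceTable
from traitshift.niche import (
    NicheNullModel,
    classify_species,
    null_snc_distribution,
    species_niche_centroid,
    trait_snc_regression,
    winner_loser_contrast,
)
from traitshift.synthetic import ScenarioConfig, simulate_scenario


class TestCentroid:
    def test_single_plot(self):
        assert species_niche_centroid([5], [37.0]) == 37.0

    def test_equal_abundance_two_plots(self):
        assert species_niche_centroid([2, 2], [20.0, 40.0]) == 30.0

    def test_matches_brute_force(self, rng):
        w = rng.integers(0, 6, 30).astype(float)
        w[0] += 1
        fl = rng.uniform(0, 100, 30)
        brute = np.sum(w * fl) / np.sum(w)
        assert species_niche_centroid(w, fl) == pytest.approx(brute, abs=1e-12)

    def test_zero_abundance_rejected(self):
        with pytest.raises(ValueError):
            species_niche_centroid([0, 0], [1.0, 2.0])


class TestNull:
    def test_permutation_invariant_vector_degenerates(self, rng):
        w = np.full(10, 3.0)
        fl = rng.uniform(0, 100, 10)
        null = null_snc_distribution(w, fl, 200, rng)
        assert np.allclose(null, species_niche_centroid(w, fl))
        cls = classify_species(species_niche_centroid(w, fl), null)
        assert cls.status == "neutral" and np.isnan(cls.ses)

    def test_uniform_forest_loss_constant_null(self, rng):
        null = null_snc_distribution([1, 0, 2, 5], np.full(4, 42.0), 100, rng)
        assert np.allclose(null, 42.0)

    def test_null_mean_approaches_regional_mean(self, rng):
        w = rng.integers(0, 5, 40).astype(float)
        w[:4] += 1
        fl = rng.uniform(0, 100, 40)
        null = null_snc_distribution(w, fl, 20_000, rng)
        se = null.std() / np.sqrt(len(null))
        assert abs(null.mean() - fl.mean()) < 3 * se + 1e-9

    def test_tiny_region_rejected(self, rng):
        with pytest.raises(ValueError):
            null_snc_distribution([1], [10.0], 100, rng)


class TestClassification:
    def test_median_observation_is_neutral(self, rng):
        null = rng.normal(50, 5, 1000)
        cls = classify_species(float(np.median(null)), null)
        assert cls.status == "neutral"
        assert abs(cls.ses) < 0.1

    def test_extreme_observation_is_winner(self, rng):
        null = rng.normal(50, 5, 1000)
        cls = classify_species(80.0, null)
        assert cls.status == "winner" and cls.ses > 3 and cls.quantile_position > 0.95

    def test_ses_invariant_to_abundance_scaling(self, rng):
        w = rng.integers(0, 4, 25).astype(float)
        w[:3] += 1
        fl = rng.uniform(0, 100, 25)
        snc = species_niche_centroid(w, fl)
        n1 = null_snc_distribution(w, fl, 2000, np.random.default_rng(1))
        n2 = null_snc_distribution(7 * w, fl, 2000, np.random.default_rng(1))
        assert species_niche_centroid(7 * w, fl) == pytest.approx(snc, abs=1e-10)
        c1, c2 = classify_species(snc, n1), classify_species(snc, n2)
        assert c1.ses == pytest.approx(c2.ses, abs=1e-10)

    def test_planted_specialist_is_winner(self, rng):
        fl = np.sort(rng.uniform(0, 100, 40))
        w = np.zeros(40)
        w[-10:] = rng.integers(1, 6, 10)  # occurs only in the top-loss quartile
        snc = species_niche_centroid(w, fl)
        wins = 0
        for s in range(30):
            null = null_snc_distribution(w, fl, 1000, np.random.default_rng(s))
            wins += classify_species(snc, null).status == "winner"
        assert wins == 30


@pytest.fixture(scope="module")
def sorted_niche():
    """Strong wood-density sorting, one region, to probe the trait signal."""
    cfg = ScenarioConfig(
        seed=31, n_regions=1, plots_per_region=50, n_species_pool=400, scales=(2000,),
        trait_effect={"wood_density": -0.7}, degradation_effect={},
    )
    abundance, meta, traits, dist, _ = simulate_scenario(cfg)
    community = CommunityData(abundance, meta)
    dt = DisturbanceTable(
        dist.drop(columns="degradation"),
        (meta["plot_area"] / meta["basal_area"]).rename("degradation"),
    )
    model = NicheNullModel(n_iter=1000, min_plots=5, random_state=31).fit(community, dt)
    return model.results_, traits


def test_trait_snc_regression_recovers_sorting(sorted_niche):
    results, traits = sorted_niche
    res = trait_snc_regression(results, traits["wood_density"], weight_by_abundance=True)
    assert res["fit"]["slope"] < 0
    assert res["fit"]["ci_high"] < 0
    # weighting by abundance should not lose explanatory power under
    # dominance-driven sorting
    assert res["weighted"]["r2_adj"] >= res["unweighted"]["r2_adj"] - 0.02


def test_unrelated_trait_has_null_slope(sorted_niche):
    results, traits = sorted_niche
    res = trait_snc_regression(results, traits["lma"], weight_by_abundance=False)
    assert res["fit"]["ci_low"] < 0 < res["fit"]["ci_high"]


def test_winner_loser_contrast_direction(sorted_niche):
    results, traits = sorted_niche
    out = winner_loser_contrast(results, traits["wood_density"], weight_by_abundance=True)
    assert out["groups"]["loser"]["mean"] > out["groups"]["winner"]["mean"]
    assert out["p"] < 0.05


def test_contrast_runs_without_winners(sorted_niche):
    results, traits = sorted_niche
    no_winners = results[results["status"] != "winner"]
    out = winner_loser_contrast(no_winners, traits["wood_density"])
    assert out["dropped_groups"] == ["winner"]
    assert set(out["groups"]) == {"loser", "neutral"}


def test_results_schema_and_bounds(sorted_niche):
    results, _ = sorted_niche
    assert (results["null_sd"] >= 0).all()
    assert results["quantile_position"].between(0, 1).all()
    winners = results[results["status"] == "winner"]
    losers = results[results["status"] == "loser"]
    assert (winners["quantile_position"] > 0.95).all()
    assert (winners["ses"] > 0).all() and (losers["ses"] < 0).all()
    # SNC bounded by occupied-plot forest loss range is implied by the weighted mean
    assert results["snc_obs"].between(0, 100).all()
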