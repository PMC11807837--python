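# traitshift

Causal, trait-based analysis of tree communities in human-modified tropical
forest landscapes.

When tropical forest is cleared, the tree communities that remain do not just
lose species — their *functional profile* shifts: light-wooded, small-seeded,
animal-ingestion-dispersed "winner" species proliferate while dense-wooded,
large-seeded "loser" species carried by scatter-hoarding animals decline.
`traitshift` implements the statistical machinery to quantify that
replacement from standard plot-network data (stem counts, species traits,
buffer-based landscape metrics), for ecologists working with multi-region
plot inventories:

1. **Backdoor-adjusted disturbance effects on community trait profiles.**
   The assumed within-region causal graph is
   `loss → patches → edge → degradation`, all four pointing at the community
   outcome. The total standardized effect of each exposure on a community
   statistic — the community-weighted mean CWM(t) = Σⱼ wⱼtⱼ / Σⱼ wⱼ, or the
   lower/upper 5% percentile of the abundance-weighted trait distribution —
   is estimated by OLS with the exposure's backdoor control set ({} for
   forest loss, {loss} for patches, {loss, patches} for edge density,
   {loss, patches, edge} for degradation), per region, trait and buffer
   scale (500/1,000/2,000 m). Residual spatial autocorrelation is absorbed
   with Moran's eigenvector maps chosen from four candidate spatial
   weighting matrices (Gabriel graph / minimum spanning tree × binary /
   linear-decay weights).
2. **Winner–loser classification.** A species' forest-loss niche centroid
   SNC = Σᵢ wᵢFLᵢ / Σᵢ wᵢ is compared with a permutation null (its abundance
   vector shuffled across the region's plots); SES = (SNC − null mean) /
   null sd, and species beyond the null's 95% envelope are winners (high
   loss) or losers (low loss). Trait structure in the shifts is tested with
   abundance-weighted SES–trait regressions and winner/loser ANOVA.
3. **Double-constrained correspondence analysis (dc-CA).** Site scores are
   constrained by disturbance predictors and species scores by traits; each
   eigenvalue is the squared weighted fourth-corner correlation of a
   composite gradient/composite trait pair. Significance uses the *max
   test* — the larger of the plot-level and species-level permutation p
   values — which controls the type 1 error inflation of plain CWM
   regression; terms are screened marginally and sequentially with
   Bonferroni correction, with region as covariate.

A synthetic-data generator (`traitshift.synthetic`) reproduces the assumed
causal and community-assembly structure with closed-form ground truth
(`SyntheticTruth`), so every stage of the pipeline is exercised and
validated without any data download.

## Worked example

```python
from traitshift import (ScenarioConfig, simulate_scenario, NicheNullModel,
                        run_effect_grid)
from traitshift.io import CommunityData, DisturbanceTable, TraitTable

cfg = ScenarioConfig(seed=42, n_regions=2, plots_per_region=40,
                     n_species_pool=400)
abundance, meta, traits, landscape, truth = simulate_scenario(cfg)
community = CommunityData(abundance, meta)
disturbance = DisturbanceTable(
    landscape.drop(columns="degradation"),
    (meta["plot_area"] / meta["basal_area"]).rename("degradation"))

effects = run_effect_grid(community, TraitTable(traits), disturbance,
                          trait_names=["wood_density"], statistics=("cwm",),
                          scales=[2000], exposures=("forest_loss",))
print(effects[["region", "beta", "ci_low", "ci_high", "r2_adj", "mem_terms"]])
```

prints

```
region   beta  ci_low  ci_high  r2_adj  mem_terms
    R1 -0.721  -0.948   -0.493   0.507          0
    R2 -0.600  -0.863   -0.337   0.343          0
```

Each row is one region's standardized total effect of forest loss (at the
2,000 m buffer) on CWM wood density with its 95% CI and the adjusted R² of
the model (no spatial eigenvectors were needed: `mem_terms = 0`). Both CIs
exclude zero: forest loss significantly lightens community wood. The
generator's true standardized effect for this scenario is −0.68
(`truth.cwm_effects`), inside both intervals. Classifying species,

```python
niche = NicheNullModel(n_iter=1000, random_state=42).fit(community, disturbance)
print(niche.results_["status"].value_counts(normalize=True))
```

```
neutral    0.581
loser      0.320
winner     0.100
```

most species are neutral, with an asymmetric winner/loser split — the
hallmark pattern of trait-mediated replacement under deforestation.

A Typer CLI mirrors the library: `traitshift simulate|metrics|causal|niche|dcca|run`
(e.g. `traitshift run --seed 1 --out outdir/` writes `profile.csv`,
`effects.csv`, `niche.csv`, `dcca_terms.csv` and a consolidated
`report.json`).

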