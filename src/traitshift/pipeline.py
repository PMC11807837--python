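"""End-to-end orchestration: simulate -> load/filter -> metrics -> causal grid ->
niche null model -> dc-CA, from one configuration, with a consolidated report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .causal import EXPOSURES, run_effect_grid, transform_and_standardize
from .dcca import term_screen
from .metrics import community_profile
from .niche import NicheNullModel
from .synthetic import LOG_TRAITS, ScenarioConfig, simulate_scenario

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "simulate_to_dir"]


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``input_dir`` points at plots/abundance/traits/landscape CSVs, or
    ``simulate`` holds a ScenarioConfig (the default).  Reduced iteration
    defaults (1,000 null iterations, 199 permutations) keep a full run at
    desk scale; ``paper_scale`` restores 10,000 / 999.
    """

    input_dir: str | None = None
    simulate: ScenarioConfig | None = None
    out_dir: str = "traitshift-out"
    trait_names: list[str] | None = None
    statistics: tuple[str, ...] = ("cwm", "p05", "p95")
    scales: list[int] | None = None
    exposures: tuple[str, ...] = EXPOSURES
    min_species_level: float = 0.50
    min_total: float = 0.80
    min_plots: int = 5
    iterations: int = 1000
    n_perm: int = 199
    alpha: float = 0.05
    spatial: bool = True
    paper_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_dir is None:
            self.simulate = ScenarioConfig(seed=self.seed)
        if self.paper_scale:
            self.iterations = 10_000
            self.n_perm = 999

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = ScenarioConfig(**sim)
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def simulate_to_dir(scenario: ScenarioConfig, outdir) -> None:
    """Write a synthetic scenario as the pipeline's canonical CSV inputs."""
    abundance, meta, traits, disturbance, truth = simulate_scenario(scenario)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    community = tio.CommunityData(abundance, meta)
    tt = tio.TraitTable(traits)
    deg = community.plot_meta["plot_area"] / community.plot_meta["basal_area"]
    dt = tio.DisturbanceTable(disturbance.drop(columns="degradation"), deg.rename("degradation"))
    tio.write_tables(outdir, community, tt, dt)
    truth.to_json(outdir / "truth.json")


def _dcca_inputs(community, traits, disturbance, scales):
    """Complete-trait species subset, one-column env tables per term, region strata."""
    tv = traits.analysis_traits().copy()
    for col in tv.columns:
        if col in LOG_TRAITS:
            tv[col] = np.log(tv[col])
    tv = tv.drop(columns=["abiotic"], errors="ignore")  # full one-hot is collinear
    tv = tv.reindex(community.abundance.columns).dropna()
    abundance = community.abundance[tv.index]
    abundance = abundance.loc[abundance.sum(axis=1) > 0, abundance.sum(axis=0) > 0]
    tv = tv.loc[abundance.columns]
    region = community.plot_meta.loc[abundance.index, "region"]
    covariates = pd.get_dummies(region, drop_first=True).astype(float)

    env_by_term: dict[str, pd.DataFrame] = {}
    sequential: dict[str, list[str]] = {}
    largest = max(scales)
    for var in ("forest_loss", "n_patches", "edge_density"):
        for scale in scales:
            env = disturbance.at_scale(scale).reindex(abundance.index)
            col, _ = transform_and_standardize(env, [var])
            env_by_term[f"{var}@{scale}"] = col
    env = disturbance.at_scale(largest).reindex(abundance.index)
    col, _ = transform_and_standardize(env, ["degradation"])
    env_by_term["degradation"] = col
    # sequential conditioning mirrors the backdoor model set, at the largest scale
    sequential[f"n_patches@{largest}"] = [f"forest_loss@{largest}"]
    sequential[f"edge_density@{largest}"] = [f"forest_loss@{largest}", f"n_patches@{largest}"]
    sequential["degradation"] = [
        f"forest_loss@{largest}",
        f"n_patches@{largest}",
        f"edge_density@{largest}",
    ]
    return abundance, tv, env_by_term, sequential, covariates, region


def run_all(config: RunConfig) -> dict:
    """Run every stage, write stage outputs under ``config.out_dir``, return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.input_dir is None:
        simdir = out / "inputs"
        simulate_to_dir(config.simulate, simdir)
    else:
        simdir = Path(config.input_dir)
    paths = {
        "plots": simdir / "plots.csv",
        "abundance": simdir / "abundance.csv",
        "traits": simdir / "traits.csv",
        "landscape": simdir / "landscape.csv",
    }
    community, traits, disturbance, load_report = tio.load_and_validate(paths)
    scales = config.scales or disturbance.scales

    # community profiles
    from .causal import _trait_values_for_analysis

    tv = _trait_values_for_analysis(traits)
    profile = community_profile(community.abundance, tv)
    profile.to_csv(out / "profile.csv", index=False)

    # causal grid
    effects = run_effect_grid(
        community,
        traits,
        disturbance,
        trait_names=config.trait_names,
        statistics=config.statistics,
        scales=scales,
        exposures=config.exposures,
        spatial=config.spatial,
        n_perm=min(config.n_perm, 199),
        random_state=config.seed,
        min_species_level=config.min_species_level,
        min_total=config.min_total,
    )
    effects.to_csv(out / "effects.csv", index=False)

    # niche null model at the largest scale
    niche = NicheNullModel(
        n_iter=config.iterations, min_plots=config.min_plots, random_state=config.seed
    ).fit(community, disturbance, scale=max(scales))
    niche.results_.to_csv(out / "niche.csv", index=False)

    # dc-CA term screen
    abundance, tvc, env_by_term, sequential, covariates, region = _dcca_inputs(
        community, traits, disturbance, scales
    )
    screen = term_screen(
        abundance,
        tvc,
        env_by_term,
        covariates=covariates,
        strata=region,
        sequential=sequential,
        n_perm=config.n_perm,
        alpha=config.alpha,
        rng=rng,
    )
    screen.to_csv(out / "dcca_terms.csv", index=False)

    ok = effects[effects["error"].isna()] if "error" in effects else effects
    per_exposure = (
        ok.groupby("exposure")["significant"].mean().round(4).to_dict() if len(ok) else {}
    )
    status_frac = (
        niche.results_.groupby("region")["status"]
        .value_counts(normalize=True)
        .rename("fraction")
        .reset_index()
    )
    report = {
        "config": config.to_jsonable(),
        "data": load_report,
        "effects": {
            "n_cells": int(len(effects)),
            "n_failed": int(effects["error"].notna().sum()) if "error" in effects else 0,
            "significant_fraction_by_exposure": per_exposure,
        },
        "niche": {
            "n_species_region": int(len(niche.results_)),
            "winner_fraction": float((niche.results_["status"] == "winner").mean()),
            "loser_fraction": float((niche.results_["status"] == "loser").mean()),
            "by_region": status_frac.to_dict(orient="records"),
        },
        "dcca_terms": screen.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
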