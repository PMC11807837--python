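"""Synthetic landscapes, trait pools and tree communities with known causal structure.

The generator emulates a multi-region study of human-modified tropical
forest: per-plot landscape disturbance measured in nested buffers (forest
loss, number of forest patches, edge density), a local degradation index
proxied by inverse basal area, a species pool with resource-use and
regeneration traits, and plot-level stem counts whose composition shifts
along the disturbance gradient through trait-mediated sorting.

The causal skeleton is a linear-Gaussian structural model on standardized
latent variables:

    loss -> patches,  loss -> edge,  patches -> edge,
    {loss, patches, edge} -> degradation,
    loss -> community trait sorting,  degradation -> community trait sorting.

Every structural coefficient is a configuration parameter, so the implied
total standardized effect of each exposure on each community-weighted mean
(CWM) is available in closed form (`SyntheticTruth`), giving downstream
estimators a recoverable target.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "simulate_landscape",
    "simulate_trait_pool",
    "simulate_communities",
    "simulate_scenario",
]

CONTINUOUS_TRAITS = ("wood_density", "seed_mass", "lma", "h_max")
SYNDROMES = ("abiotic", "endozoochory", "synzoochory")
#: traits whose sorting axis (and downstream analysis) uses the log scale
LOG_TRAITS = frozenset({"seed_mass"})

_DEFAULT_DAG = {"a1": 0.8, "b1": 0.5, "b2": 0.5, "c1": 0.4, "c2": 0.2, "c3": 0.3}
_DEFAULT_NOISE = {
    "n_patches": 0.45,
    "edge_density": 0.6,
    "degradation": 0.7,
    "basal_area": 0.02,
}
# Sorting strengths of the default ("paper-like") scenario: forest loss
# depresses community wood density and seed mass, local degradation adds a
# smaller independent push in the same direction.
_DEFAULT_TRAIT_EFFECT = {"wood_density": -0.5, "seed_mass": -0.5}
_DEFAULT_DEGRADATION_EFFECT = {"wood_density": -0.25, "seed_mass": -0.15}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study.

    The defaults describe a six-region, 45-plots-per-region study with a
    ~1,200-species hyperdominant pool, matching the dimensions of the kind
    of multi-region tropical plot network this package targets.
    """

    n_regions: int = 6
    plots_per_region: int = 45
    n_species_pool: int = 1207
    scales: tuple[int, ...] = (500, 1000, 2000)
    #: raw structural coefficients of the landscape DAG
    #: a1: loss->patches (log-log slope); b1: loss->edge; b2: patches->edge;
    #: c1..c3: {loss, patches, edge}->degradation (per-sd of parent)
    dag_coefficients: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DAG))
    #: per-trait standardized slope of trait x forest-loss sorting
    trait_effect: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_TRAIT_EFFECT))
    #: per-trait standardized slope of trait x degradation sorting
    degradation_effect: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DEGRADATION_EFFECT)
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    #: range (m) of the exponential-kernel spatial field on forest loss; 0 = none
    spatial_range: float = 0.0
    #: sd of lognormal species baseline abundances (hyperdominance strength)
    abundance_lognormal_sd: float = 1.5
    #: expected number of adult stems per plot
    stems_per_plot: float = 120.0
    #: buffer scale whose forest loss drives community sorting (default: largest)
    sorting_scale: int | None = None
    #: scale mixing: smaller buffers get extra independent noise,
    #: tau_s = scale_mixing * (1 - s / max(scales))
    scale_mixing: float = 0.4
    plot_area_ha: float = 0.25
    count_model: str = "poisson"  # or "negbin"
    negbin_dispersion: float = 5.0
    seed: int = 0

    # location/scale constants of the observation equations (latent -> data)
    loss_log_mean: float = 2.6
    loss_log_sd: float = 0.6
    patches_log_mean: float = 2.5
    edge_mean: float = 0.45
    edge_sd: float = 0.12
    degradation_mean: float = 0.05
    degradation_sd: float = 0.009

    def __post_init__(self) -> None:
        for name in ("n_regions", "plots_per_region", "n_species_pool"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd entries must be >= 0")
        if self.spatial_range < 0:
            raise ValueError("spatial_range must be >= 0")
        self.scales = tuple(int(s) for s in self.scales)
        if self.sorting_scale is None:
            self.sorting_scale = max(self.scales)
        if self.sorting_scale not in self.scales:
            raise ValueError("sorting_scale must be one of scales")
        if self.count_model not in ("poisson", "negbin"):
            raise ValueError("count_model must be 'poisson' or 'negbin'")

    def rng(self, stream: str) -> np.random.Generator:
        """One independent, reproducible RNG stream per sub-generator."""
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), key]))

    def scale_mix(self, scale: int) -> float:
        return float(self.scale_mixing * (1.0 - scale / max(self.scales)))


# ---------------------------------------------------------------------------
# closed-form standardized landscape system
# ---------------------------------------------------------------------------


def _landscape_system(config: ScenarioConfig) -> dict:
    """Standardized structural coefficients and implied covariances.

    Each latent (loss L, patches P, edge E, degradation D) is expressed as a
    linear combination of four independent unit shocks, from which unit
    variances are enforced and all covariances follow by dot products.
    """
    d = config.dag_coefficients
    a1, b1, b2 = d["a1"], d["b1"], d["b2"]
    c1, c2, c3 = d["c1"], d["c2"], d["c3"]
    sig_p = config.noise_sd.get("n_patches", 0.0)
    sig_e = config.noise_sd.get("edge_density", 0.0)
    sig_d = config.noise_sd.get("degradation", 0.0)

    wL = np.array([1.0, 0.0, 0.0, 0.0])
    # patches: log-log link on observed scales, log1p(patches) linear in
    # log1p(loss) with raw slope a1; standardized coefficient follows.
    wP_raw = a1 * config.loss_log_sd * wL + np.array([0.0, sig_p, 0.0, 0.0])
    sP = float(np.linalg.norm(wP_raw))
    if sP == 0:
        raise ValueError("patches equation is degenerate (a1 and its noise both zero)")
    wP = wP_raw / sP
    # edge and degradation coefficients act per sd of the (standardized) parent
    wE_raw = b1 * wL + b2 * wP + np.array([0.0, 0.0, sig_e, 0.0])
    sE = float(np.linalg.norm(wE_raw))
    if sE == 0:
        raise ValueError("edge equation is degenerate")
    wE = wE_raw / sE
    wD_raw = c1 * wL + c2 * wP + c3 * wE + np.array([0.0, 0.0, 0.0, sig_d])
    sD = float(np.linalg.norm(wD_raw))
    if sD == 0:
        raise ValueError("degradation equation is degenerate")
    wD = wD_raw / sD

    coef = {
        ("forest_loss", "n_patches"): a1 * config.loss_log_sd / sP,
        ("forest_loss", "edge_density"): b1 / sE,
        ("n_patches", "edge_density"): b2 / sE,
        ("forest_loss", "degradation"): c1 / sD,
        ("n_patches", "degradation"): c2 / sD,
        ("edge_density", "degradation"): c3 / sD,
    }
    shocks = {"forest_loss": wL, "n_patches": wP, "edge_density": wE, "degradation": wD}
    return {"coef": coef, "shocks": shocks, "scale_sd": {"P": sP, "E": sE, "D": sD}}


def _path_sum(coef: Mapping[tuple[str, str], float], source: str, target: str) -> float:
    """Total standardized effect as the sum over directed paths of coefficient products."""
    g = nx.DiGraph()
    for (u, v), w in coef.items():
        g.add_edge(u, v, weight=w)
    if source == target:
        return 1.0
    if source not in g or target not in g:
        return 0.0
    total = 0.0
    for path in nx.all_simple_paths(g, source, target):
        prod = 1.0
        for u, v in zip(path[:-1], path[1:]):
            prod *= g[u][v]["weight"]
        total += prod
    return total


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

EXPOSURES = ("forest_loss", "n_patches", "edge_density", "degradation")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated scenario.

    ``cwm_effects`` has one row per trait x region x scale x exposure with
    ``total_effect`` (true causal effect of that exposure, measured at that
    buffer scale, on the CWM of the trait, in standardized units) and
    ``plim_backdoor`` (what the backdoor-adjusted OLS converges to; equal to
    the causal effect at the sorting scale, attenuated by cross-scale buffer
    correlation elsewhere).  ``landscape_effects`` holds total standardized
    effects among the four disturbance variables.  ``niche_shift`` is the
    per-species derivative of log expected abundance with respect to the
    standardized sorting gradient — the species' true position along the
    forest-loss axis.
    """

    landscape_effects: dict[str, float]
    cwm_effects: pd.DataFrame
    niche_shift: pd.Series
    sorting_scale: int

    def to_json(self, path) -> None:
        payload = {
            "landscape_effects": self.landscape_effects,
            "sorting_scale": self.sorting_scale,
            "cwm_effects": self.cwm_effects.to_dict(orient="records"),
            "niche_shift": self.niche_shift.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def landscape_total_effects(config: ScenarioConfig) -> dict[str, float]:
    """Closed-form total standardized effects among the landscape variables."""
    sys = _landscape_system(config)
    out: dict[str, float] = {}
    for src in EXPOSURES:
        for dst in EXPOSURES:
            if src != dst:
                out[f"{src}->{dst}"] = _path_sum(sys["coef"], src, dst)
    return out


def _cwm_truth(config: ScenarioConfig) -> pd.DataFrame:
    sys = _landscape_system(config)
    coef = dict(sys["coef"])
    rows = []
    traits = sorted(set(config.trait_effect) | set(config.degradation_effect))
    for trait in traits:
        beta = config.trait_effect.get(trait, 0.0)
        delta = config.degradation_effect.get(trait, 0.0)
        full = dict(coef)
        full[("forest_loss", "cwm")] = beta
        full[("degradation", "cwm")] = delta
        causal = {exp: _path_sum(full, exp, "cwm") for exp in EXPOSURES}
        for scale in config.scales:
            rho = float(np.sqrt(1.0 - config.scale_mix(scale) ** 2))
            at_sorting = scale == config.sorting_scale
            for exposure in EXPOSURES:
                if exposure == "degradation":
                    total = causal[exposure]  # degradation is a plot-level variable
                    plim = total
                elif at_sorting:
                    total = causal[exposure]
                    plim = total
                elif exposure == "forest_loss":
                    total = 0.0  # off-scale loss causes nothing downstream
                    plim = rho * causal[exposure]
                else:
                    total = 0.0
                    plim = 0.0
                for region in range(config.n_regions):
                    rows.append(
                        dict(
                            trait=trait,
                            region=f"R{region + 1}",
                            scale=scale,
                            exposure=exposure,
                            total_effect=total,
                            plim_backdoor=plim,
                        )
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------


def _region_ids(config: ScenarioConfig) -> pd.Series:
    labels = [f"R{r + 1}" for r in range(config.n_regions) for _ in range(config.plots_per_region)]
    plots = [f"p{idx:03d}" for idx in range(len(labels))]
    return pd.Series(labels, index=pd.Index(plots, name="plot"), name="region")


def _spatial_field(coords: np.ndarray, rng: np.random.Generator, range_m: float) -> np.ndarray:
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    cov = np.exp(-d / range_m)
    cov[np.diag_indices_from(cov)] += 1e-8
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(len(coords))


def simulate_landscape(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-plot coordinates and the plot x scale disturbance table.

    Returns ``(disturbance, plot_meta)``: a long table with columns
    (plot, scale, forest_loss, n_patches, edge_density, degradation) and a
    plot table with (region, x, y, plot_area).  Forest loss is a percentage
    in [0, 100]; patches a positive integer; edge density in [0, 1];
    degradation a positive inverse-basal-area index (ha m^-2).
    """
    region = _region_ids(config)
    n = len(region)
    sys = _landscape_system(config)
    sP, sE, sD = (sys["scale_sd"][k] for k in ("P", "E", "D"))
    d = config.dag_coefficients

    rng_xy = config.rng("coords")
    xy = np.empty((n, 2))
    for r, label in enumerate(sorted(region.unique())):
        mask = (region == label).to_numpy()
        xy[mask, 0] = r * 50_000 + rng_xy.uniform(0, 4000, mask.sum())
        xy[mask, 1] = rng_xy.uniform(0, 4000, mask.sum())
    plot_meta = pd.DataFrame(
        {"region": region, "x": xy[:, 0], "y": xy[:, 1], "plot_area": config.plot_area_ha}
    )

    rng_loss = config.rng("loss")
    z0 = rng_loss.standard_normal(n)
    if config.spatial_range > 0:
        gp = np.empty(n)
        for label in sorted(region.unique()):
            mask = (region == label).to_numpy()
            gp[mask] = _spatial_field(xy[mask], rng_loss, config.spatial_range)
        z0 = (z0 + gp) / np.sqrt(2.0)

    rng_p = config.rng("patches")
    rng_e = config.rng("edge")
    rng_d = config.rng("degradation")
    latents: dict[int, dict[str, np.ndarray]] = {}
    rows = []
    for scale in sorted(config.scales):
        tau = config.scale_mix(scale)
        zL = np.sqrt(1.0 - tau**2) * z0 + tau * rng_loss.standard_normal(n)
        log_loss = config.loss_log_mean + config.loss_log_sd * zL
        loss = np.clip(np.expm1(log_loss), 0.0, 100.0)

        zP = (d["a1"] * config.loss_log_sd * zL + config.noise_sd.get("n_patches", 0.0) * rng_p.standard_normal(n)) / sP
        patches = np.maximum(1, np.rint(np.expm1(config.patches_log_mean + sP * zP))).astype(int)

        zE = (d["b1"] * zL + d["b2"] * zP + config.noise_sd.get("edge_density", 0.0) * rng_e.standard_normal(n)) / sE
        edge = np.clip(config.edge_mean + config.edge_sd * zE, 0.0, 1.0)
        latents[scale] = {"L": zL, "P": zP, "E": zE}
        rows.append(
            pd.DataFrame(
                {
                    "plot": region.index,
                    "scale": scale,
                    "forest_loss": loss,
                    "n_patches": patches,
                    "edge_density": edge,
                }
            )
        )

    src = latents[config.sorting_scale]
    zD = (
        d["c1"] * src["L"]
        + d["c2"] * src["P"]
        + d["c3"] * src["E"]
        + config.noise_sd.get("degradation", 0.0) * rng_d.standard_normal(n)
    ) / sD
    degradation = np.maximum(config.degradation_mean + config.degradation_sd * zD, 5e-3)
    disturbance = pd.concat(rows, ignore_index=True)
    disturbance["degradation"] = disturbance["plot"].map(
        pd.Series(degradation, index=region.index)
    )
    return disturbance, plot_meta


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

# multinomial-logit link of dispersal syndrome on standardized log seed mass;
# synzoochory is enriched at large seeds, endozoochory at small ones
SYNDROME_INTERCEPTS = {"abiotic": 0.0, "endozoochory": 0.7, "synzoochory": -1.2}
SYNDROME_SLOPES = {"abiotic": 0.0, "endozoochory": -0.6, "synzoochory": 1.0}


def syndrome_probabilities(z_log_seed_mass: np.ndarray) -> np.ndarray:
    """Configured multinomial probabilities (n x 3, syndrome order as SYNDROMES)."""
    logits = np.stack(
        [SYNDROME_INTERCEPTS[s] + SYNDROME_SLOPES[s] * z_log_seed_mass for s in SYNDROMES],
        axis=1,
    )
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    return p / p.sum(axis=1, keepdims=True)


def simulate_trait_pool(config: ScenarioConfig) -> pd.DataFrame:
    """Draw the species trait pool.

    Wood density (g cm^-3) is truncated normal on (0.1, 1.2); seed mass (mg)
    and maximum height (m) lognormal; LMA (g m^-2) truncated normal above 20.
    Dispersal syndrome follows a multinomial logit on log seed mass.
    """
    if config.n_species_pool < 2:
        raise ValueError("n_species_pool must be >= 2")
    rng = config.rng("traits")
    n = config.n_species_pool
    species = pd.Index([f"sp{j:04d}" for j in range(n)], name="species")

    mu, sd = 0.58, 0.15
    wd = stats.truncnorm.rvs((0.1 - mu) / sd, (1.2 - mu) / sd, loc=mu, scale=sd, size=n, random_state=rng)
    seed_mass = np.exp(rng.normal(np.log(80.0), 1.5, n))  # mg
    lma_mu, lma_sd = 90.0, 25.0
    lma = stats.truncnorm.rvs((20.0 - lma_mu) / lma_sd, np.inf, loc=lma_mu, scale=lma_sd, size=n, random_state=rng)
    h_max = np.exp(rng.normal(np.log(20.0), 0.4, n))

    z_sm = (np.log(seed_mass) - np.log(seed_mass).mean()) / np.log(seed_mass).std()
    probs = syndrome_probabilities(z_sm)
    rng_syn = config.rng("syndrome")
    draws = rng_syn.random(n)
    cum = probs.cumsum(axis=1)
    idx = (draws[:, None] > cum).sum(axis=1)
    syndrome = np.array(SYNDROMES)[idx]

    return pd.DataFrame(
        {
            "wood_density": wd,
            "seed_mass": seed_mass,
            "lma": lma,
            "h_max": h_max,
            "syndrome": syndrome,
        },
        index=species,
    )


def sorting_axes(traits: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    """Standardized per-species sorting axes (log scale where the analysis logs)."""
    cols = {}
    for name in names:
        if name in CONTINUOUS_TRAITS:
            v = np.log(traits[name].to_numpy()) if name in LOG_TRAITS else traits[name].to_numpy()
        elif name in SYNDROMES:
            v = (traits["syndrome"] == name).to_numpy(float)
        else:
            raise KeyError(f"unknown trait {name!r}")
        sd = v.std()
        if sd == 0:
            raise ValueError(f"trait {name!r} has zero variance in the pool")
        cols[name] = (v - v.mean()) / sd
    return pd.DataFrame(cols, index=traits.index)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------


def _within_region_z(values: pd.Series, region: pd.Series) -> pd.Series:
    def z(v):
        s = v.std(ddof=0)
        return (v - v.mean()) / s if s > 0 else v * 0.0

    return values.groupby(region).transform(z)


def simulate_communities(
    config: ScenarioConfig,
    disturbance: pd.DataFrame,
    plot_meta: pd.DataFrame,
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate stem counts, basal areas, and the ground-truth object.

    Expected log abundance of species j in plot i is a lognormal species
    baseline (hyperdominance) plus, for each sorted trait t, the product of
    the species' standardized trait and a unit-variance plot gradient
    ``g = beta_t * z(forest loss) + delta_t * z(degradation) + residual``.
    Counts are Poisson (optionally negative binomial) around expectations
    rescaled to ``stems_per_plot``.  Basal area decreases in degradation so
    that plot_area / basal_area recovers the generator's degradation index
    up to multiplicative noise.

    Returns ``(abundance, plot_meta_with_basal_area, truth)``.
    """
    plots = plot_meta.index
    sub = disturbance[disturbance["scale"] == config.sorting_scale].set_index("plot")
    if not sub.index.equals(plots):
        sub = sub.reindex(plots)
        if sub["forest_loss"].isna().any():
            raise ValueError("disturbance table does not cover all plots at the sorting scale")
    region = plot_meta["region"]
    x = _within_region_z(np.log1p(sub["forest_loss"]), region).to_numpy()
    dvar = _within_region_z(sub["degradation"], region).to_numpy()
    cov_xd = float(np.mean(x * dvar))

    sorted_traits = sorted(set(config.trait_effect) | set(config.degradation_effect))
    axes = sorting_axes(traits, sorted_traits) if sorted_traits else pd.DataFrame(index=traits.index)

    rng_b = config.rng("baseline")
    b0 = rng_b.normal(0.0, config.abundance_lognormal_sd, len(traits))

    rng_g = config.rng("gradient")
    n = len(plots)
    log_lam = np.tile(b0, (n, 1))
    niche = np.zeros(len(traits))
    for t in sorted_traits:
        beta = config.trait_effect.get(t, 0.0)
        delta = config.degradation_effect.get(t, 0.0)
        resid_var = 1.0 - beta**2 - delta**2 - 2.0 * beta * delta * cov_xd
        if resid_var < -1e-9:
            raise ValueError(f"sorting effects for {t!r} imply gradient variance > 1")
        g = beta * x + delta * dvar + np.sqrt(max(resid_var, 0.0)) * rng_g.standard_normal(n)
        tj = axes[t].to_numpy()
        log_lam += np.outer(g, tj)
        niche += beta * tj

    lam = np.exp(log_lam)
    lam *= config.stems_per_plot / lam.sum(axis=1, keepdims=True)
    rng_c = config.rng("counts")
    if config.count_model == "poisson":
        counts = rng_c.poisson(lam)
    else:
        k = config.negbin_dispersion
        counts = rng_c.poisson(lam * rng_c.gamma(k, 1.0 / k, size=lam.shape))
    abundance = pd.DataFrame(counts, index=plots, columns=traits.index)

    rng_ba = config.rng("basal")
    ba_noise = np.exp(config.noise_sd.get("basal_area", 0.0) * rng_ba.standard_normal(n))
    meta = plot_meta.copy()
    meta["basal_area"] = meta["plot_area"] / sub["degradation"].to_numpy() * ba_noise

    truth = SyntheticTruth(
        landscape_effects=landscape_total_effects(config),
        cwm_effects=_cwm_truth(config),
        niche_shift=pd.Series(niche, index=traits.index, name="niche_shift"),
        sorting_scale=config.sorting_scale,
    )
    return abundance, meta, truth


def simulate_scenario(config: ScenarioConfig):
    """Full simulation: (abundance, plot_meta, traits, disturbance, truth)."""
    disturbance, plot_meta = simulate_landscape(config)
    traits = simulate_trait_pool(config)
    abundance, plot_meta, truth = simulate_communities(config, disturbance, plot_meta, traits)
    return abundance, plot_meta, traits, disturbance, truth
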