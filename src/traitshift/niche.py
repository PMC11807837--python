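"""Species forest-loss niches, permutation null model, and winner/loser contrasts.

A species' niche centroid (SNC) is the abundance-weighted mean forest loss
over the plots it occupies.  The null model redistributes the species'
abundance vector uniformly at random across the region's plots and
recomputes the centroid (default 10,000 iterations, one RNG stream per
species so results are stable when species are added).  The standardized
effect size SES = (observed - null mean) / null sd; species whose observed
centroid exceeds 95% of null values are winners, those below 95% of null
values losers, the rest neutral.  Trait signal in the niche shifts is then
assessed with (abundance-weighted) regressions of SES on traits and a
winner/loser/neutral one-way ANOVA per trait.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .io import CommunityData, DisturbanceTable, filter_species_min_occupancy

__all__ = [
    "species_niche_centroid",
    "null_snc_distribution",
    "classify_species",
    "NicheNullModel",
    "trait_snc_regression",
    "winner_loser_contrast",
]


def species_niche_centroid(abundance_row, forest_loss_per_plot) -> float:
    """Abundance-weighted mean forest loss over the plots a species occupies."""
    w = np.asarray(abundance_row, dtype=float)
    fl = np.asarray(forest_loss_per_plot, dtype=float)
    if w.shape != fl.shape:
        raise ValueError("abundance and forest-loss vectors must align")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("species has zero total abundance")
    return float(np.sum(w * fl) / tot)


def null_snc_distribution(
    abundance_row,
    forest_loss_per_plot,
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null SNC sample: the abundance vector permuted across the region's plots."""
    w = np.asarray(abundance_row, dtype=float)
    fl = np.asarray(forest_loss_per_plot, dtype=float)
    if fl.size < 2:
        raise ValueError("the region must contain at least 2 plots")
    rng = rng or np.random.default_rng()
    perms = rng.permuted(np.broadcast_to(fl, (n_iter, fl.size)).copy(), axis=1)
    return perms @ w / w.sum()


@dataclass
class NicheClassification:
    ses: float
    quantile_position: float
    status: str


def classify_species(snc_obs: float, null_sample: np.ndarray) -> NicheClassification:
    """SES, null-quantile position and winner/loser/neutral status.

    Ties with null values count as non-exceedance (conservative); a
    degenerate null (sd = 0) yields 'neutral' with undefined SES.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("null sample is empty")
    mu = float(null_sample.mean())
    sd = float(null_sample.std(ddof=0))
    q = float(np.mean(null_sample < snc_obs))
    q_above = float(np.mean(null_sample > snc_obs))
    # a permutation-invariant abundance vector gives a constant null up to
    # float summation order; treat that as degenerate
    if sd <= 1e-10 * max(1.0, abs(mu)):
        return NicheClassification(float("nan"), q, "neutral")
    ses = (snc_obs - mu) / sd
    if q > 0.95:
        status = "winner"
    elif q_above > 0.95:
        status = "loser"
    else:
        status = "neutral"
    return NicheClassification(ses, q, status)


class NicheNullModel(BaseEstimator):
    """Per-region winner/loser classification along the forest-loss gradient.

    Parameters
    ----------
    n_iter : null-model iterations per species-region combination.
    min_plots : minimum within-region occupancy for a species to be assessed.
    random_state : global seed; each species gets an independent stream
        derived from it and a hash of the species id, so previously computed
        species are unaffected by additions.
    """

    def __init__(self, n_iter: int = 10_000, min_plots: int = 5, random_state: int = 0):
        self.n_iter = n_iter
        self.min_plots = min_plots
        self.random_state = random_state

    def _species_rng(self, species: str, region: str) -> np.random.Generator:
        key = zlib.crc32(f"{species}|{region}".encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([int(self.random_state), key]))

    def fit(self, community: CommunityData, disturbance: DisturbanceTable, scale: int | None = None):
        """Compute `results_`: one row per retained species x region."""
        scale = scale or max(disturbance.scales)
        env = disturbance.at_scale(scale)["forest_loss"]
        eligible = filter_species_min_occupancy(community, self.min_plots)
        rows = []
        for region, meta in community.plot_meta.groupby("region"):
            plots = meta.index
            fl = env.reindex(plots).to_numpy(float)
            sub = community.abundance.loc[plots]
            for sp in eligible[str(region)]:
                w = sub[sp].to_numpy(float)
                snc = species_niche_centroid(w, fl)
                null = null_snc_distribution(
                    w, fl, self.n_iter, self._species_rng(sp, str(region))
                )
                cls = classify_species(snc, null)
                rows.append(
                    dict(
                        species=sp,
                        region=str(region),
                        scale=scale,
                        n_plots_occupied=int((w > 0).sum()),
                        total_abundance=float(w.sum()),
                        snc_obs=snc,
                        null_mean=float(null.mean()),
                        null_sd=float(null.std(ddof=0)),
                        ses=cls.ses,
                        quantile_position=cls.quantile_position,
                        status=cls.status,
                    )
                )
        self.results_ = pd.DataFrame(rows)
        self.scale_ = scale
        return self


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("all trait values equal; regression undefined")
    return (v - v.mean()) / sd


def trait_snc_regression(
    niche_results: pd.DataFrame,
    trait_values: pd.Series,
    weight_by_abundance: bool = True,
    response: str = "ses",
) -> dict:
    """Least-squares fit of SES (or raw SNC) on a standardized species trait.

    Returns both the weighted (weights = species total abundance) and the
    unweighted fit: slope, 95% CI, and adjusted R2 for each.
    """
    df = niche_results.join(trait_values.rename("trait"), on="species").dropna(
        subset=["trait", response]
    )
    if len(df) < 3:
        raise ValueError("need at least 3 species with trait data")
    x = sm.add_constant(_standardize(df["trait"].to_numpy(float)))
    y = df[response].to_numpy(float)

    def _fit(weights):
        model = sm.WLS(y, x, weights=weights).fit()
        ci = model.conf_int()
        return dict(
            slope=float(model.params[1]),
            ci_low=float(ci[1][0]),
            ci_high=float(ci[1][1]),
            r2_adj=float(model.rsquared_adj),
            n=int(len(y)),
        )

    out = {"unweighted": _fit(np.ones(len(y)))}
    out["weighted"] = _fit(df["total_abundance"].to_numpy(float))
    out["fit"] = out["weighted"] if weight_by_abundance else out["unweighted"]
    return out


def winner_loser_contrast(
    niche_results: pd.DataFrame,
    trait_values: pd.Series,
    weight_by_abundance: bool = True,
) -> dict:
    """One-way (weighted) ANOVA of a trait across winner/loser/neutral groups.

    Empty groups are dropped with a notice; returns group summaries and the
    F test of the remaining groups.
    """
    df = niche_results.join(trait_values.rename("trait"), on="species").dropna(subset=["trait"])
    groups = [g for g in ("winner", "loser", "neutral") if (df["status"] == g).any()]
    dropped = [g for g in ("winner", "loser", "neutral") if g not in groups]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty status groups")
    sub = df[df["status"].isin(groups)]
    w = sub["total_abundance"].to_numpy(float) if weight_by_abundance else np.ones(len(sub))
    y = sub["trait"].to_numpy(float)
    dummies = pd.get_dummies(sub["status"], drop_first=True).to_numpy(float)
    full = sm.WLS(y, sm.add_constant(dummies), weights=w).fit()
    null = sm.WLS(y, np.ones((len(y), 1)), weights=w).fit()
    df_num = dummies.shape[1]
    df_den = len(y) - dummies.shape[1] - 1
    f = ((null.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    summaries = {
        g: dict(
            n=int((sub["status"] == g).sum()),
            mean=float(np.average(y[sub["status"] == g], weights=w[sub["status"] == g])),
        )
        for g in groups
    }
    return dict(F=float(f), p=p, groups=summaries, dropped_groups=dropped)
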