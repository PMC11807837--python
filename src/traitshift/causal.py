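"""Backdoor-adjusted estimation of disturbance effects on community trait profiles.

The assumed within-region causal graph is

    forest_loss -> n_patches -> edge_density -> degradation -> outcome
    forest_loss -> edge_density, forest_loss -> degradation,
    n_patches -> degradation, and every disturbance -> outcome.

Total effects are estimated by OLS of the standardized outcome on the
standardized exposure plus the exposure's backdoor control set (its
ancestors in the graph): nothing for forest loss; forest loss for the
number of patches; forest loss and patches for edge density; all three
landscape variables for degradation.  Forest loss, patch counts and seed
mass are log-transformed before standardization.  Residual spatial
autocorrelation is absorbed with Moran-eigenvector filters chosen by
:class:`traitshift.spatial.MoranSpatialFilter`; significance is a 95%
t-based confidence interval excluding zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .io import CommunityData, DisturbanceTable, TraitTable, filter_plots_by_trait_coverage
from .metrics import community_profile
from .spatial import FilterDecision, MoranSpatialFilter
from .synthetic import LOG_TRAITS

logger = logging.getLogger(__name__)

__all__ = [
    "default_dag",
    "backdoor_controls",
    "transform_and_standardize",
    "BackdoorEffectEstimator",
    "EffectEstimate",
    "run_effect_grid",
    "fit_predictive_model",
]

EXPOSURES = ("forest_loss", "n_patches", "edge_density", "degradation")
LOG_PREDICTORS = ("forest_loss", "n_patches")


def default_dag() -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from(
        [
            ("forest_loss", "n_patches"),
            ("forest_loss", "edge_density"),
            ("n_patches", "edge_density"),
            ("forest_loss", "degradation"),
            ("n_patches", "degradation"),
            ("edge_density", "degradation"),
        ]
    )
    for v in EXPOSURES:
        g.add_edge(v, "outcome")
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("causal graph must be acyclic")
    return g


def backdoor_controls(dag: nx.DiGraph, exposure: str) -> list[str]:
    """Minimal control set for the *total* effect of ``exposure`` on the outcome.

    With all confounding running through upstream disturbance variables, the
    exposure's non-outcome ancestors close every backdoor path while leaving
    all mediated (causal) paths open.
    """
    if exposure not in dag:
        raise KeyError(f"exposure {exposure!r} not a DAG node")
    controls = sorted(nx.ancestors(dag, exposure) - {"outcome"})
    desc = nx.descendants(dag, exposure)
    assert not (set(controls) & desc), "control set may not contain descendants of the exposure"
    return controls


def transform_and_standardize(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    group: pd.Series | None = None,
    log_variables: tuple[str, ...] = LOG_PREDICTORS,
) -> tuple[pd.DataFrame, list[str]]:
    """log1p the skewed disturbance metrics, then z-score (within group if given).

    Zero-variance variables are dropped with a warning; returns the
    transformed table and the list of dropped columns.
    """
    variables = list(variables or table.columns)
    out = table[variables].astype(float).copy()
    dropped = []
    for col in variables:
        v = out[col]
        if col in log_variables:
            v = np.log1p(v)
        def z(s):
            sd = s.std(ddof=0)
            return (s - s.mean()) / sd if sd > 0 else s * np.nan
        v = v.groupby(group.reindex(v.index)).transform(z) if group is not None else z(v)
        if v.isna().all() or float(np.nanstd(v)) == 0:
            dropped.append(col)
            logger.warning("variable %r has zero variance; dropped", col)
            out = out.drop(columns=[col])
        else:
            out[col] = v
    return out, dropped


@dataclass
class EffectEstimate:
    """Standardized total-effect estimate for one exposure/outcome cell."""

    exposure: str
    outcome: str
    region: str | None
    scale: int | None
    beta: float
    ci_low: float
    ci_high: float
    r2_adj: float
    r2_adj_spatial: float | None
    n_plots: int
    control_set: tuple[str, ...]
    mem_terms: int
    spatial_candidate: str | None = None
    error: str | None = None

    @property
    def significant(self) -> bool:
        return bool(self.ci_low > 0 or self.ci_high < 0)

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["control_set"] = "+".join(self.control_set)
        d["significant"] = self.significant
        return d


class BackdoorEffectEstimator(BaseEstimator):
    """OLS total-effect estimator with backdoor controls and MEM filtering.

    Expects standardized data.  ``fit(X, y)`` takes a DataFrame ``X``
    containing the exposure and its controls (extra columns ignored) and the
    outcome vector ``y``; pass plot coordinates via ``coords`` to enable the
    residual spatial-autocorrelation step.
    """

    def __init__(
        self,
        exposure: str = "forest_loss",
        controls: tuple[str, ...] | None = None,
        dag: nx.DiGraph | None = None,
        spatial: bool = True,
        alpha: float = 0.05,
        n_perm: int = 99,
        random_state: int | None = 0,
    ):
        self.exposure = exposure
        self.controls = controls
        self.dag = dag
        self.spatial = spatial
        self.alpha = alpha
        self.n_perm = n_perm
        self.random_state = random_state

    def _controls(self) -> list[str]:
        if self.controls is not None:
            return list(self.controls)
        return backdoor_controls(self.dag or default_dag(), self.exposure)

    def fit(self, X: pd.DataFrame, y, coords: np.ndarray | None = None):
        controls = self._controls()
        cols = [self.exposure] + [c for c in controls if c in X.columns]
        design = sm.add_constant(X[cols].to_numpy(float))
        y = np.asarray(y, dtype=float)
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise ValueError(f"rank-deficient design among {['const'] + cols}")
        base = sm.OLS(y, design).fit()
        self.r2_adj_ = float(base.rsquared_adj)
        self.decision_: FilterDecision | None = None
        model = base
        if self.spatial and coords is not None and len(y) >= 4:
            sel = MoranSpatialFilter(
                alpha=self.alpha, n_perm=self.n_perm, random_state=self.random_state
            ).fit(np.asarray(coords, float), residuals=base.resid)
            self.decision_ = sel.decision_
            if sel.decision_.selected:
                full = np.column_stack([design, sel.decision_.eigenvectors])
                model = sm.OLS(y, full).fit()
        self.model_ = model
        self.beta_ = float(model.params[1])
        ci = model.conf_int(alpha=0.05)
        self.ci_ = (float(ci[1][0]), float(ci[1][1]))
        self.r2_adj_spatial_ = float(model.rsquared_adj)
        self.mem_terms_ = self.decision_.n_selected if self.decision_ else 0
        self.n_obs_ = int(len(y))
        self.control_set_ = tuple(c for c in controls if c in X.columns)
        return self

    def estimate(self, outcome: str = "outcome", region=None, scale=None) -> EffectEstimate:
        return EffectEstimate(
            exposure=self.exposure,
            outcome=outcome,
            region=region,
            scale=scale,
            beta=self.beta_,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            r2_adj=self.r2_adj_,
            r2_adj_spatial=self.r2_adj_spatial_,
            n_plots=self.n_obs_,
            control_set=self.control_set_,
            mem_terms=self.mem_terms_,
            spatial_candidate=self.decision_.chosen if self.decision_ else None,
        )


def _trait_values_for_analysis(traits: TraitTable) -> pd.DataFrame:
    """Analysis-scale trait values: log where skewed (seed mass), raw otherwise."""
    tv = traits.analysis_traits().copy()
    for col in tv.columns:
        if col in LOG_TRAITS:
            tv[col] = np.log(tv[col])
    return tv


def run_effect_grid(
    community: CommunityData,
    traits: TraitTable,
    disturbance: DisturbanceTable,
    trait_names: list[str] | None = None,
    statistics: tuple[str, ...] = ("cwm", "p05", "p95"),
    scales: list[int] | None = None,
    exposures: tuple[str, ...] = EXPOSURES,
    spatial: bool = True,
    n_perm: int = 99,
    random_state: int = 0,
    min_species_level: float = 0.50,
    min_total: float = 0.80,
) -> pd.DataFrame:
    """One EffectEstimate per exposure x trait x statistic x region x scale.

    Per-cell failures are flagged rows (``error`` column), never aborts.
    """
    tv = _trait_values_for_analysis(traits)
    trait_names = trait_names or list(tv.columns)
    scales = scales or disturbance.scales
    coverage = filter_plots_by_trait_coverage(
        community, traits, min_species_level=min_species_level, min_total=min_total
    )
    profile = community_profile(community.abundance, tv[trait_names])
    profile = profile.set_index(["plot", "trait"])
    dag = default_dag()
    rows = []
    for trait, stat, scale, exposure in itertools.product(
        trait_names, statistics, scales, exposures
    ):
        keep = coverage.plots_for(trait)
        env_all = disturbance.at_scale(scale)
        for region, meta in community.plot_meta.groupby("region"):
            plots = meta.index.intersection(keep)
            est_kwargs = dict(trait=trait, statistic=stat)
            try:
                y_raw = profile.xs(trait, level="trait").loc[plots, stat]
                env = env_all.loc[plots]
                data = pd.concat([env, y_raw.rename("outcome")], axis=1).dropna()
                controls = backdoor_controls(dag, exposure)
                if len(data) < len(controls) + 3:
                    raise ValueError(f"too few plots ({len(data)}) for exposure {exposure}")
                std, dropped = transform_and_standardize(data, list(EXPOSURES) + ["outcome"])
                if exposure in dropped or "outcome" in dropped:
                    raise ValueError(f"zero-variance exposure or outcome (dropped={dropped})")
                coords = meta.loc[data.index, ["x", "y"]].to_numpy()
                est = BackdoorEffectEstimator(
                    exposure=exposure,
                    dag=dag,
                    spatial=spatial and len(data) >= 4,
                    n_perm=n_perm,
                    random_state=random_state,
                ).fit(std, std["outcome"], coords=coords)
                rec = est.estimate(outcome=f"{trait}:{stat}", region=str(region), scale=scale)
                rows.append({**rec.as_dict(), **est_kwargs})
            except Exception as exc:  # flagged row, grid continues
                rows.append(
                    dict(
                        exposure=exposure,
                        outcome=f"{trait}:{stat}",
                        region=str(region),
                        scale=scale,
                        error=str(exc),
                        **est_kwargs,
                    )
                )
    return pd.DataFrame(rows)


def fit_predictive_model(
    data: pd.DataFrame,
    outcome: str = "outcome",
    exposures: tuple[str, ...] = EXPOSURES,
) -> dict:
    """Best-subset OLS over the four disturbance variables by AICc.

    Approximates selection for out-of-sample predictive accuracy; returns the
    chosen subset, its adjusted R2, and the per-subset trail.
    """
    y = data[outcome].to_numpy(float)
    n = len(y)
    trail = []
    best = None
    for r in range(len(exposures) + 1):
        for subset in itertools.combinations(exposures, r):
            cols = [c for c in subset if c in data.columns]
            design = sm.add_constant(data[list(cols)].to_numpy(float)) if cols else np.ones((n, 1))
            fit = sm.OLS(y, design).fit()
            k = design.shape[1] + 1  # + error variance
            aicc = fit.aic + 2.0 * k * (k + 1) / max(n - k - 1, 1)
            trail.append(dict(subset=subset, aicc=float(aicc), r2_adj=float(fit.rsquared_adj)))
            if best is None or aicc < best["aicc"]:
                best = trail[-1]
    return {"chosen": best["subset"], "r2_adj": best["r2_adj"], "aicc": best["aicc"], "trail": trail}
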