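"""Double-constrained correspondence analysis (dc-CA) with the max permutation test.

dc-CA couples community-level CWM regression and species-level niche-trait
regression in one eigen-analysis: site scores are constrained to the span
of environmental predictors (row-weighted) and species scores to the span
of traits (column-weighted).  Each axis maximizes the weighted
fourth-corner correlation between a unit-variance composite environmental
gradient and a unit-variance composite trait, subject to orthogonality to
earlier axes; the eigenvalue of an axis is that squared correlation.

Implementation is the two-step weighted-regression form: project the
CA-scaled contingency residual matrix onto weighted-orthonormal bases of
the trait and predictor spans, then take an SVD of the projected core.
Significance uses the max test — the larger of the community-level
(plots permuted, within covariate strata) and species-level (trait rows
permuted) permutation p values — which guards against the type 1 error
inflation of plain CWM regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "prepare_relative_abundance",
    "DCCA",
    "DCCAResult",
    "max_test",
    "term_screen",
    "DegenerateTermError",
]


class DegenerateTermError(ValueError):
    """All predictor variation is absorbed by the covariates (zero conditional span)."""


def prepare_relative_abundance(abundance: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Divide abundances by plot totals; return (normalized, row weights, column weights).

    Row weights are equal after normalization (each plot counts once,
    removing plot-size effects); column weights are proportional to species'
    shares of the normalized table.
    """
    y = abundance.to_numpy(float)
    empty_rows = abundance.index[y.sum(axis=1) == 0].tolist()
    if empty_rows:
        raise ValueError(f"empty plots (no stems): {empty_rows[:5]}")
    empty_cols = abundance.columns[y.sum(axis=0) == 0].tolist()
    if empty_cols:
        raise ValueError(f"empty species columns: {empty_cols[:5]}")
    norm = y / y.sum(axis=1, keepdims=True)
    n = norm.shape[0]
    r = np.full(n, 1.0 / n)
    c = norm.sum(axis=0) / n
    return pd.DataFrame(norm, index=abundance.index, columns=abundance.columns), r, c


def _weighted_center(m: np.ndarray, w: np.ndarray) -> np.ndarray:
    return m - (w @ m)[None, :] / w.sum()


def _weighted_scale(m: np.ndarray, w: np.ndarray) -> np.ndarray:
    sd = np.sqrt((w[:, None] * m**2).sum(axis=0) / w.sum())
    sd[sd == 0] = 1.0
    return m / sd


def _partial_out(m: np.ndarray, z: np.ndarray | None, w: np.ndarray) -> np.ndarray:
    if z is None or z.size == 0:
        return m
    wz = w[:, None] * z
    beta = np.linalg.lstsq(z.T @ wz, wz.T @ m, rcond=None)[0]
    return m - z @ beta


def _orthobasis(m: np.ndarray, w: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Weighted-orthonormal basis of the span of m (columns), with back-map.

    Returns (X, A) with X = sqrt(w) m A orthonormal; raises on collinearity.
    """
    g = np.sqrt(w)[:, None] * m
    q, rr = np.linalg.qr(g)
    diag = np.abs(np.diag(rr))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        cond = np.linalg.cond(g)
        raise ValueError(f"collinear {label} matrix (condition number {cond:.3g})")
    return q, np.linalg.inv(rr)


@dataclass
class DCCAResult:
    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    trait_weights: pd.DataFrame
    predictor_weights: pd.DataFrame
    trait_correlations: pd.DataFrame
    predictor_correlations: pd.DataFrame
    p_community: float | None = None
    p_species: float | None = None
    p_max: float | None = None
    permutations: dict = field(default_factory=dict)


class DCCA(BaseEstimator):
    """Double-constrained correspondence analysis estimator.

    Parameters
    ----------
    n_axes : number of ordination axes to retain.
    standardize : weighted-standardize trait and predictor columns so the
        canonical weights are comparable standardized weights (does not
        change the eigenvalues).
    """

    def __init__(self, n_axes: int = 2, standardize: bool = True):
        self.n_axes = n_axes
        self.standardize = standardize

    def fit(
        self,
        abundance: pd.DataFrame,
        traits: pd.DataFrame,
        env: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
    ):
        traits = traits.reindex(abundance.columns)
        env = env.reindex(abundance.index)
        if traits.isna().any().any():
            raise ValueError("traits must be complete for dc-CA (filter or drop species first)")
        if env.isna().any().any():
            raise ValueError("predictors must be complete")
        ynorm, r, c = prepare_relative_abundance(abundance)
        p = ynorm.to_numpy() / ynorm.to_numpy().sum()
        q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))

        e = _weighted_center(env.to_numpy(float), r)
        pre_norm = np.sqrt((r[:, None] * e**2).sum(axis=0))
        z = None
        if covariates is not None:
            z = _weighted_center(covariates.reindex(abundance.index).to_numpy(float), r)
        e = _partial_out(e, z, r)
        post_norm = np.sqrt((r[:, None] * e**2).sum(axis=0))
        if np.all(post_norm <= 1e-10 * np.maximum(pre_norm, 1e-30)):
            raise DegenerateTermError(
                "predictors carry no variation beyond the covariates"
            )
        if self.standardize:
            e = _weighted_scale(e, r)
        t = _weighted_center(traits.to_numpy(float), c)
        if self.standardize:
            t = _weighted_scale(t, c)

        xr, ar = _orthobasis(e, r, "predictor")
        xk, ak = _orthobasis(t, c, "trait")
        m = xr.T @ q @ xk
        u, s, vt = np.linalg.svd(m, full_matrices=False)
        k = min(self.n_axes, s.size)
        self.eigenvalues_ = s[:k] ** 2
        b_env = ar @ u[:, :k]
        b_trait = ak @ vt.T[:, :k]
        axes = [f"axis{i + 1}" for i in range(k)]
        site = e @ b_env  # unit r-weighted variance composite gradients
        comp = t @ b_trait
        self.result_ = DCCAResult(
            eigenvalues=self.eigenvalues_,
            site_scores=pd.DataFrame(site, index=abundance.index, columns=axes),
            species_scores=pd.DataFrame(comp, index=abundance.columns, columns=axes),
            trait_weights=pd.DataFrame(b_trait, index=traits.columns, columns=axes),
            predictor_weights=pd.DataFrame(b_env, index=env.columns, columns=axes),
            trait_correlations=pd.DataFrame(
                _wcorr(t, comp, c), index=traits.columns, columns=axes
            ),
            predictor_correlations=pd.DataFrame(
                _wcorr(e, site, r), index=env.columns, columns=axes
            ),
        )
        # cache pieces for fast permutation tests
        self._cache = dict(q=q, r=r, c=c, z=z, env=env, traits=traits, xr=xr, xk=xk)
        return self

    def statistic(self, kind: str = "first") -> float:
        s2 = np.linalg.svd(self._cache["xr"].T @ self._cache["q"] @ self._cache["xk"], compute_uv=False) ** 2
        return float(s2[0]) if kind == "first" else float(s2.sum())


def _wcorr(cols: np.ndarray, comp: np.ndarray, w: np.ndarray) -> np.ndarray:
    wn = w / w.sum()
    cc = cols - (wn @ cols)[None, :]
    kk = comp - (wn @ comp)[None, :]
    num = cc.T @ (wn[:, None] * kk)
    sd1 = np.sqrt((wn[:, None] * cc**2).sum(axis=0))
    sd2 = np.sqrt((wn[:, None] * kk**2).sum(axis=0))
    sd1[sd1 == 0] = np.nan
    return num / np.outer(sd1, sd2)


def _stat_from(core: np.ndarray, kind: str) -> float:
    s2 = np.linalg.svd(core, compute_uv=False) ** 2
    return float(s2[0]) if kind == "first" else float(s2.sum())


def _perm_indices(rng, n: int, strata: np.ndarray | None) -> np.ndarray:
    idx = np.arange(n)
    if strata is None:
        return rng.permutation(n)
    out = idx.copy()
    for s in np.unique(strata):
        mask = strata == s
        out[mask] = idx[mask][rng.permutation(mask.sum())]
    return out


def max_test(
    abundance: pd.DataFrame,
    traits: pd.DataFrame,
    env: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    strata: pd.Series | None = None,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    statistic: str = "first",
) -> dict:
    """Community- and species-level permutation tests; p_max is their maximum.

    The community test permutes plots (rows of the predictor table), within
    ``strata`` when given (e.g. region, matching a region covariate); the
    species test permutes rows of the trait table.  The test statistic is
    the first dc-CA eigenvalue (or the trace with ``statistic='trace'``).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    rng = rng or np.random.default_rng()
    try:
        model = DCCA(n_axes=1).fit(abundance, traits, env, covariates)
    except DegenerateTermError:
        return dict(statistic=0.0, p_community=1.0, p_species=1.0, p_max=1.0, n_perm=n_perm)
    cache = model._cache
    q, r, c, z = cache["q"], cache["r"], cache["c"], cache["z"]
    xr, xk = cache["xr"], cache["xk"]
    obs = _stat_from(xr.T @ q @ xk, statistic)

    strata_arr = None
    if strata is not None:
        strata_arr = strata.reindex(abundance.index).to_numpy()

    qxk = q @ xk
    e_raw = cache["env"].to_numpy(float)
    n_comm = 0
    for _ in range(n_perm):
        idx = _perm_indices(rng, len(e_raw), strata_arr)
        e = _weighted_center(e_raw[idx], r)
        e = _partial_out(e, z, r)
        xr_p, _ = _orthobasis(e, r, "permuted predictor")
        if _stat_from(xr_p.T @ qxk, statistic) >= obs - 1e-12:
            n_comm += 1
    p_comm = (1 + n_comm) / (n_perm + 1)

    xrtq = xr.T @ q
    t_raw = cache["traits"].to_numpy(float)
    n_sp = 0
    for _ in range(n_perm):
        t = _weighted_center(t_raw[rng.permutation(len(t_raw))], c)
        xk_p, _ = _orthobasis(t, c, "permuted trait")
        if _stat_from(xrtq @ xk_p, statistic) >= obs - 1e-12:
            n_sp += 1
    p_sp = (1 + n_sp) / (n_perm + 1)
    return dict(
        statistic=obs,
        p_community=float(p_comm),
        p_species=float(p_sp),
        p_max=float(max(p_comm, p_sp)),
        n_perm=n_perm,
    )


_SEQUENTIAL_ORDER = ("forest_loss", "n_patches", "edge_density", "degradation")


def term_screen(
    abundance: pd.DataFrame,
    traits: pd.DataFrame,
    env_by_term: dict[str, pd.DataFrame],
    covariates: pd.DataFrame | None = None,
    strata: pd.Series | None = None,
    sequential: dict[str, list[str]] | None = None,
    n_perm: int = 999,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Marginal and sequential max tests over a set of single-variable terms.

    ``env_by_term`` maps term labels to one-column predictor tables (e.g.
    'forest_loss@2000').  ``sequential`` maps a term to the labels it is
    conditioned on (conditioning predictors are partialled out together with
    the covariates).  p values are Bonferroni-adjusted across all tested
    terms; terms are ranked by their marginal fourth-corner eigenvalue.
    """
    rng = rng or np.random.default_rng()
    rows = []
    for label, env in env_by_term.items():
        cond = (sequential or {}).get(label, [])
        cov = covariates
        if cond:
            extra = pd.concat([env_by_term[c] for c in cond], axis=1)
            cov = extra if cov is None else pd.concat([cov, extra], axis=1)
        res = max_test(
            abundance, traits, env, covariates=cov, strata=strata, n_perm=n_perm, rng=rng
        )
        rows.append(
            dict(
                term=label,
                conditioning="+".join(cond),
                eigenvalue=res["statistic"],
                p_community=res["p_community"],
                p_species=res["p_species"],
                p_max=res["p_max"],
            )
        )
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_adj"] = np.minimum(1.0, out["p_max"] * m)
    out["significant"] = out["p_adj"] <= alpha
    return out.sort_values("eigenvalue", ascending=False).reset_index(drop=True)
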