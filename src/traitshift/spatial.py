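"""Moran's eigenvector maps (MEM) and residual spatial-autocorrelation control.

Candidate spatial weighting matrices combine two graph-based connectivity
structures (Gabriel graph, minimum spanning tree) with two edge weightings
(binary, linearly decreasing with distance).  For each candidate, MEMs are
the eigenvectors of the doubly centred weighting matrix; those with
positive eigenvalues describe positive spatial autocorrelation and are
ordered by their Moran's I.  Model residuals are screened with a global
Moran's I permutation test, Sidak-corrected across the four candidates;
within significant candidates eigenvectors are added greedily until the
residual autocorrelation is gone, and the candidate needing the fewest
eigenvectors wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator

__all__ = [
    "gabriel_graph",
    "mst_graph",
    "SpatialBasis",
    "build_spatial_candidates",
    "morans_i",
    "moran_permutation_test",
    "MoranSpatialFilter",
    "FilterDecision",
]


def _distances(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    d = squareform(pdist(coords))
    off = d[~np.eye(len(d), dtype=bool)]
    if len(off) and off.min() == 0:
        raise ValueError(
            "duplicate plot coordinates; jitter is refused — provide distinct locations"
        )
    return d


def gabriel_graph(coords: np.ndarray) -> np.ndarray:
    """Boolean adjacency: (i, j) connected iff the circle with diameter ij is empty."""
    d2 = _distances(coords) ** 2
    n = len(d2)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            # empty-circumcircle test against every third point
            if np.all(np.delete(d2[i] + d2[j], [i, j]) >= d2[i, j] - 1e-12):
                adj[i, j] = adj[j, i] = True
    return adj


def mst_graph(coords: np.ndarray) -> np.ndarray:
    d = _distances(coords)
    t = minimum_spanning_tree(d).toarray()
    adj = (t > 0) | (t.T > 0)
    return adj


def _weighting(adj: np.ndarray, d: np.ndarray, kind: str) -> np.ndarray:
    if kind == "binary":
        return adj.astype(float)
    if kind == "linear":
        return adj * (1.0 - d / d.max())
    raise ValueError(f"unknown weighting {kind!r}")


def morans_i(x: np.ndarray, w: np.ndarray) -> float:
    """Global Moran's I of x under symmetric weight matrix w."""
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    s0 = w.sum()
    denom = (z**2).sum()
    if denom == 0 or s0 == 0:
        return float("nan")
    return float(len(x) / s0 * (z @ w @ z) / denom)


@dataclass
class SpatialBasis:
    """One candidate spatial weighting matrix and its MEM eigenvectors."""

    graph: str  # 'gabriel' | 'mst'
    weighting: str  # 'binary' | 'linear'
    w: np.ndarray = field(repr=False)
    eigenvectors: np.ndarray = field(repr=False)  # plots x k, Moran-ordered
    moran: np.ndarray = field(repr=False)

    @property
    def name(self) -> str:
        return f"{self.graph}-{self.weighting}"

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]


def _mem(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(w)
    c = np.eye(n) - np.ones((n, n)) / n
    b = c @ ((w + w.T) / 2.0) @ c
    vals, vecs = np.linalg.eigh(b)
    keep = vals > 1e-9 * max(1.0, abs(vals).max())
    vecs = vecs[:, keep]
    mor = np.array([morans_i(v, w) for v in vecs.T])
    order = np.argsort(-mor)
    return vecs[:, order], mor[order]


def build_spatial_candidates(coords: np.ndarray) -> list[SpatialBasis]:
    """The four connectivity x weighting MEM bases for a set of plot coordinates."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 4:
        raise ValueError("need at least 4 plots to build spatial candidates")
    d = _distances(coords)
    graphs = {"gabriel": gabriel_graph(coords), "mst": mst_graph(coords)}
    out = []
    for gname, adj in graphs.items():
        for kind in ("binary", "linear"):
            w = _weighting(adj, d, kind)
            vecs, mor = _mem(w)
            out.append(SpatialBasis(gname, kind, w, vecs, mor))
    return out


def moran_permutation_test(
    x: np.ndarray,
    w: np.ndarray,
    n_perm: int = 199,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Permutation test of global Moran's I; returns (I, p)."""
    rng = rng or np.random.default_rng()
    obs = morans_i(x, w)
    if np.isnan(obs):
        return obs, 1.0
    x = np.asarray(x, dtype=float)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    z = perms - perms.mean(axis=1, keepdims=True)
    num = np.einsum("pi,ij,pj->p", z, w, z)
    null = len(x) / w.sum() * num / (z**2).sum(axis=1)
    if alternative == "greater":
        p = (1 + np.sum(null >= obs)) / (n_perm + 1)
    elif alternative == "two-sided":
        p = (1 + np.sum(np.abs(null - null.mean()) >= abs(obs - null.mean()))) / (n_perm + 1)
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return obs, float(p)


@dataclass
class FilterDecision:
    """Outcome of spatial-filter selection, with the full test trail."""

    chosen: str | None
    eigenvectors: np.ndarray | None
    n_selected: int
    trail: list[dict]

    @property
    def selected(self) -> bool:
        return self.chosen is not None


class MoranSpatialFilter(BaseEstimator):
    """Select the smallest MEM subset removing residual spatial autocorrelation.

    Parameters
    ----------
    alpha : family-wise significance level for the candidate screen.
    n_perm : permutations per Moran test.
    max_vectors : cap on selected eigenvectors (default n // 2).
    random_state : seed for the permutation streams.
    """

    def __init__(self, alpha: float = 0.05, n_perm: int = 199, max_vectors: int | None = None, random_state: int | None = 0):
        self.alpha = alpha
        self.n_perm = n_perm
        self.max_vectors = max_vectors
        self.random_state = random_state

    def fit(self, coords: np.ndarray, residuals: np.ndarray | None = None):
        """Build the four candidate bases; if residuals are given, select."""
        self.candidates_ = build_spatial_candidates(coords)
        if residuals is not None:
            self.decision_ = self.select(residuals)
        return self

    def select(self, residuals: np.ndarray) -> FilterDecision:
        residuals = np.asarray(residuals, dtype=float)
        rng = np.random.default_rng(self.random_state)
        # Sidak-corrected per-candidate level for the global screen
        alpha_c = 1.0 - (1.0 - self.alpha) ** (1.0 / len(self.candidates_))
        trail = []
        screened = []
        for cand in self.candidates_:
            i_obs, p = moran_permutation_test(residuals, cand.w, self.n_perm, rng)
            trail.append(dict(step="screen", candidate=cand.name, moran_i=i_obs, p=p, alpha=alpha_c))
            if p <= alpha_c:
                screened.append(cand)
        if not screened:
            self.decision_ = FilterDecision(None, None, 0, trail)
            return self.decision_

        best: tuple[int, str, np.ndarray] | None = None
        cap = self.max_vectors or max(1, len(residuals) // 2)
        for cand in screened:
            r = residuals.copy()
            used: list[int] = []
            avail = list(range(cand.k))
            ok = False
            while avail and len(used) < cap:
                # greedy: take the eigenvector whose removal most reduces Moran's I
                vecs = cand.eigenvectors[:, avail]
                proj = vecs * (r @ vecs)  # eigenvectors are orthonormal
                cand_resid = r[:, None] - proj
                scores = [morans_i(cand_resid[:, j], cand.w) for j in range(len(avail))]
                j = int(np.argmin(scores))
                used.append(avail.pop(j))
                r = cand_resid[:, j]
                i_obs, p = moran_permutation_test(r, cand.w, self.n_perm, rng)
                trail.append(dict(step="forward", candidate=cand.name, k=len(used), moran_i=i_obs, p=p))
                if p > self.alpha:
                    ok = True
                    break
            if ok and (best is None or len(used) < best[0]):
                best = (len(used), cand.name, cand.eigenvectors[:, used])
        if best is None:
            self.decision_ = FilterDecision(None, None, 0, trail)
        else:
            self.decision_ = FilterDecision(best[1], best[2], best[0], trail)
        return self.decision_
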