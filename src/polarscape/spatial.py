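"""Environment-independent spatial variables.

PCNM eigenvector basis from truncated site distances, residualization of the
basis against environmental predictors, regression-based prediction of
richness from the residual basis, and PCA summarization of the predicted
values into the two leading spatial components s1 and s2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SpatialBasis",
    "SpatialComponents",
    "pcnm_basis",
    "residualize",
    "spatial_components",
    "select_pcnm",
]


@dataclass
class SpatialBasis:
    """Positive-eigenvalue PCNM eigenfunctions of the truncated distances."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray      # sites x m, orthonormal columns
    truncation_distance: float

    @property
    def scores(self) -> np.ndarray:
        """Eigenvectors scaled by sqrt(eigenvalue) (classical PCNM scaling)."""
        return self.eigenvectors * np.sqrt(self.eigenvalues)

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class SpatialComponents:
    s1: np.ndarray
    s2: np.ndarray
    variance_explained: np.ndarray   # fraction per retained component
    loadings: np.ndarray             # richness-variables x 2
    r_squared: np.ndarray            # per richness regression


def pcnm_basis(coords: np.ndarray, truncation: float | None = None) -> SpatialBasis:
    """PCNM basis of a set of site coordinates.

    Pairwise Euclidean distances above the truncation threshold are replaced
    by four times the threshold; the matrix is Gower double-centered and
    eigendecomposed; eigenvectors with positive eigenvalues are returned.
    The default truncation is the longest edge of the minimum spanning tree
    of the complete distance graph (the smallest threshold keeping all sites
    connected).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need at least 3 sites with coordinate pairs")
    dvec = pdist(coords)
    if np.all(dvec == 0):
        raise ValueError("all sites are coincident; distances degenerate")
    d = squareform(dvec)
    if truncation is None:
        mst = minimum_spanning_tree(d)
        truncation = float(mst.data.max())
    if truncation <= 0:
        raise ValueError("truncation distance must be positive")
    dt = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(dt, 0.0)
    n = dt.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (dt**2) @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-10
    keep = evals > tol
    return SpatialBasis(evals[keep], evecs[:, keep], truncation)


def residualize(basis: SpatialBasis | np.ndarray, env: np.ndarray) -> np.ndarray:
    """Residuals of each spatial eigenfunction on [1, env] by least squares.

    Rank-deficient predictor columns are dropped with a warning. The result
    has the same shape as the basis scores and is orthogonal to every
    retained environmental column and to the intercept.
    """
    v = basis.scores if isinstance(basis, SpatialBasis) else np.asarray(basis, dtype=float)
    env = np.asarray(env, dtype=float)
    if env.ndim == 1:
        env = env[:, None]
    if env.shape[0] != v.shape[0]:
        raise ValueError("basis and env row counts differ")
    if env.shape[1] >= env.shape[0]:
        raise ValueError("more environmental predictors than sites")
    x = np.column_stack([np.ones(env.shape[0]), env])
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    ok = diag > diag.max() * 1e-10
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} collinear environmental column(s)")
        x = x[:, ok]
        q, _ = np.linalg.qr(x)
    return v - q @ (q.T @ v)


def spatial_components(residual_basis: np.ndarray, richness: np.ndarray) -> SpatialComponents:
    """Spatially predicted richness summarized by PCA into s1 and s2.

    Each richness variable is regressed on the residual basis (with
    intercept); a covariance-based PCA of the fitted-value columns yields
    the component scores. ``variance_explained`` is reported over all
    retained components, so it sums to ~1.
    """
    z = np.asarray(residual_basis, dtype=float)
    y = np.asarray(richness, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if z.shape[0] != y.shape[0]:
        raise ValueError("row mismatch between residual basis and richness")
    if z.shape[1] < 2:
        raise ValueError("need at least 2 residual spatial eigenfunctions")
    x = np.column_stack([np.ones(z.shape[0]), z])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ coef
    ss_res = ((y - fitted) ** 2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    r2 = 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, np.nan)

    fc = fitted - fitted.mean(axis=0)
    if np.allclose(fc, 0.0):
        raise ValueError("fitted richness values are constant; no spatial signal")
    cov = fc.T @ fc / (fc.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for k in range(evecs.shape[1]):
        lead = evecs[np.argmax(np.abs(evecs[:, k])), k]
        if lead < 0:
            evecs[:, k] = -evecs[:, k]
    scores = fc @ evecs
    frac = evals / evals.sum()
    if scores.shape[1] < 2:
        raise ValueError("need at least two richness variables for s1/s2")
    return SpatialComponents(
        s1=scores[:, 0],
        s2=scores[:, 1],
        variance_explained=frac,
        loadings=evecs[:, :2],
        r_squared=r2,
    )


def moran_i(values: np.ndarray, coords: np.ndarray, threshold: float) -> float:
    """Moran's I with binary connectivity at the given distance threshold."""
    values = np.asarray(values, dtype=float)
    d = squareform(pdist(np.asarray(coords, dtype=float)))
    w = ((d > 0) & (d <= threshold)).astype(float)
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("no neighbor pairs within the threshold")
    zc = values - values.mean()
    num = float(zc @ w @ zc)
    den = float((zc**2).sum())
    return len(values) / s0 * num / den


def select_pcnm(
    basis: SpatialBasis | np.ndarray,
    response: np.ndarray,
    method: str = "all",
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> np.ndarray:
    """Column indices of the spatial eigenfunctions to keep.

    ``all`` retains every positive-eigenvalue eigenfunction. ``forward``
    adds eigenfunctions greedily by incremental fit to the (multivariate)
    response, stopping when the best candidate's permutation p-value exceeds
    `alpha` or the adjusted R-squared stops improving.
    """
    v = basis.scores if isinstance(basis, SpatialBasis) else np.asarray(basis, dtype=float)
    m = v.shape[1]
    if method == "all":
        return np.arange(m)
    if method != "forward":
        raise ValueError(f"unknown selection method {method!r}")
    y = np.asarray(response, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    yc = y - y.mean(axis=0)
    ss_tot = (yc**2).sum()
    rng = np.random.default_rng(seed)
    n = v.shape[0]
    chosen: list[int] = []
    best_adj = -np.inf

    def rss(cols: list[int]) -> float:
        x = np.column_stack([np.ones(n), v[:, cols]])
        coef, *_ = np.linalg.lstsq(x, yc, rcond=None)
        return float(((yc - x @ coef) ** 2).sum())

    while len(chosen) < m:
        cands = [c for c in range(m) if c not in chosen]
        scores = [(rss(chosen + [c]), c) for c in cands]
        best_rss, best_c = min(scores)
        k = len(chosen) + 1
        r2 = 1 - best_rss / ss_tot
        adj = 1 - (1 - r2) * (n - 1) / (n - k - 1)
        if adj <= best_adj:
            break
        # permutation test of the incremental improvement
        base_rss = rss(chosen) if chosen else ss_tot
        obs_gain = base_rss - best_rss
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            x = np.column_stack([np.ones(n), v[:, chosen + [best_c]][perm]]) \
                if not chosen else np.column_stack(
                    [np.ones(n), v[:, chosen], v[perm][:, [best_c]]])
            coef, *_ = np.linalg.lstsq(x, yc, rcond=None)
            gain = base_rss - float(((yc - x @ coef) ** 2).sum())
            if gain >= obs_gain:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        if p > alpha:
            break
        chosen.append(best_c)
        best_adj = adj
    return np.array(sorted(chosen), dtype=int)
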