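"""Community-structure statistics.

Bray-Curtis dissimilarity, non-metric multidimensional scaling (Kruskal
stress-1 minimized by alternating isotonic regression and Guttman updates),
the smooth-isocline nestedness matrix temperature with permutation nulls,
and richness-vs-ordination-axis correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, isotonic_regression
from scipy.special import gammaln
from scipy.stats import rankdata

__all__ = [
    "Ordination",
    "NestednessResult",
    "bray_curtis",
    "nmds",
    "orient_axes",
    "nestedness_temperature",
    "nestedness_test",
    "null_matrix",
    "richness_axis_correlation",
]


# ---------------------------------------------------------------------------
# helpers

def _as_matrix(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), [str(i) for i in m.index]
    arr = np.asarray(m, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


# ---------------------------------------------------------------------------
# Bray-Curtis

def bray_curtis(m) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity, d(i,j) = sum|xi-xj| / sum(xi+xj)."""
    x, sites = _as_matrix(m)
    if np.any(x < 0):
        raise ValueError("community matrix has negative entries")
    rowsum = x.sum(axis=1)
    if np.any(rowsum == 0):
        bad = [sites[i] for i in np.flatnonzero(rowsum == 0)]
        raise ValueError(f"all-zero site rows not allowed: {bad}")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = rowsum[:, None] + rowsum[None, :]
    return num / den


# ---------------------------------------------------------------------------
# NMDS

@dataclass
class Ordination:
    """Site scores from non-metric multidimensional scaling."""

    scores: np.ndarray          # sites x k, centered, principal-axis rotated
    stress: float               # Kruskal stress-1
    converged: bool
    n_starts: int
    seed: int
    stress_history: list[float] = field(default_factory=list)


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float((dist**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


def _nmds_single(
    d: np.ndarray, init: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list[float]]:
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    dvec = d[iu]
    order = np.argsort(dvec, kind="stable")
    x = init.copy()
    x_best = x.copy()
    history: list[float] = []
    stress_prev = np.inf
    converged = False
    for _ in range(max_iter):
        dist = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=2)
        dist_vec = dist[iu]
        disp_vec = np.empty_like(dist_vec)
        disp_vec[order] = isotonic_regression(dist_vec[order], increasing=True).x
        stress = _stress1(dist_vec, disp_vec)
        if stress > stress_prev:  # safeguarded: never accept a worse configuration
            break
        x_best = x.copy()
        history.append(stress)
        if stress_prev - stress < tol:
            converged = True
            stress_prev = stress
            break
        stress_prev = stress
        # Guttman transform toward the current disparities.
        disp = np.zeros_like(dist)
        disp[iu] = disp_vec
        disp += disp.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x_new = b @ x / n
        x = x_new - x_new.mean(axis=0)
    return x_best, history[-1] if history else np.inf, converged, history


def nmds(
    d,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Ordination:
    """Best-of-`n_starts` NMDS of a dissimilarity matrix.

    One start is seeded from classical (metric) scaling, the rest from
    random configurations. Non-convergence is reported through the
    ``converged`` flag, never raised. Axes are centered and rotated to
    principal axes.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    n = d.shape[0]
    rng = np.random.default_rng(seed)

    # classical-scaling start
    j = np.eye(n) - 1.0 / n
    g = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(g)
    idx = np.argsort(evals)[::-1][:k]
    pcoa = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 0.0))

    best: tuple[np.ndarray, float, bool, list[float]] | None = None
    inits = [pcoa] + [rng.normal(size=(n, k)) for _ in range(max(n_starts - 1, 0))]
    for init in inits:
        res = _nmds_single(d, init, max_iter, tol)
        if best is None or res[1] < best[1]:
            best = res
    x, stress, converged, history = best
    # principal-axis rotation, deterministic sign
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for a in range(x.shape[1]):
        lead = x[np.argmax(np.abs(x[:, a])), a]
        if lead < 0:
            x[:, a] = -x[:, a]
    return Ordination(x, stress, converged, n_starts, seed, history)


def orient_axes(scores: np.ndarray, richness: np.ndarray) -> np.ndarray:
    """Flip each axis so its correlation with richness is non-positive."""
    scores = scores.copy()
    richness = np.asarray(richness, dtype=float)
    for a in range(scores.shape[1]):
        if np.corrcoef(richness, scores[:, a])[0, 1] > 0:
            scores[:, a] = -scores[:, a]
    return scores


# ---------------------------------------------------------------------------
# nestedness temperature (smooth-isocline estimator)

def _pack_matrix(comm: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Iteratively reorder rows/columns into maximally nested packing.

    Packing scores are integers, so rank ties are common; with `rng` given,
    ties break by a sub-unit random jitter (equivalent to random tie-break
    ranking), otherwise deterministically by position.
    """

    def _rank(v: np.ndarray) -> np.ndarray:
        if rng is not None:
            v = v + rng.uniform(0.0, 0.5, size=v.shape)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size, dtype=np.int64)
        ranks[order] = np.arange(1, v.size + 1)
        return ranks

    def colpack(x: np.ndarray, rr: np.ndarray) -> np.ndarray:
        ind = np.tile(rr[:, None], (1, x.shape[1]))
        s = -((x * ind) ** 2).sum(axis=0)
        t = -((x.shape[0] - (1 - x) * ind + 1) ** 2).sum(axis=0)
        return _rank(s + t)

    def rowpack(x: np.ndarray, cr: np.ndarray) -> np.ndarray:
        ind = np.tile(cr[None, :], (x.shape[0], 1))
        s = -((x * ind) ** 2).sum(axis=1)
        t = -((x.shape[1] - (1 - x) * ind + 1) ** 2).sum(axis=1)
        return _rank(s + t)

    if comm.shape[1] >= comm.shape[0]:
        i = rankdata(-comm.sum(axis=1), method="average")
    else:
        j = rankdata(-comm.sum(axis=0), method="average")
        i = rowpack(comm, j)
    for _ in range(8):
        j = colpack(comm, i)
        i = rowpack(comm, j)
    if comm.shape[1] < comm.shape[0]:
        j = colpack(comm, i)
    return comm[np.argsort(i), :][:, np.argsort(j)]


class _IsoclineEvaluator:
    """Surprise-distance temperature for matrices of one shape and fill.

    The fitted isocline depends only on (nrows, ncols, fill), so it is
    computed once and reused across permutations of the same matrix.
    """

    def __init__(self, nr: int, nc: int, fill: float, grid: int = 8001):
        self.nr, self.nc = nr, nc
        r = (np.arange(1, nr + 1) - 0.5) / nr
        c = (np.arange(1, nc + 1) - 0.5) / nc
        self.p = _fill_exponent(fill)
        xgrid = np.linspace(0.0, 1.0, grid)
        with np.errstate(invalid="ignore"):
            fgrid = 1.0 - (1.0 - (1.0 - xgrid) ** self.p) ** (1.0 / self.p)
        fgrid = np.nan_to_num(fgrid, nan=0.0)
        hgrid = fgrid - xgrid  # strictly decreasing from 1 to -1
        a = c[None, :] - r[:, None]
        self.crossing = np.interp(-a, -hgrid, xgrid)
        self.dis = np.tile(r[:, None], (1, nc))
        self.totdis = 1.0 - np.abs(r[:, None] - c[None, :])

    def temperature(self, packed: np.ndarray, return_surprise: bool = False):
        u = (self.dis - self.crossing) / self.totdis
        u[(u < 0) & (packed == 1)] = 0.0
        u[(u > 0) & (packed == 0)] = 0.0
        u = u**2
        temp = 100.0 * u.sum() / packed.size / 0.04145
        return (float(temp), u) if return_surprise else float(temp)


def _fill_exponent(fill: float) -> float:
    """Exponent p of the isocline family whose unit-square integral is `fill`.

    The family is f(x) = 1 - (1 - (1-x)^p)^(1/p); its integral over [0, 1]
    is 1 - Gamma(1+1/p)^2 / Gamma(1+2/p), solved for p in closed form.
    """

    def intfun(logp: float) -> float:
        p = np.exp(logp)
        return 1.0 - np.exp(2 * gammaln(1 + 1 / p) - gammaln(1 + 2 / p)) - fill

    return float(np.exp(brentq(intfun, -14.0, 14.0, xtol=1e-12)))


def nestedness_temperature(m, n_pack: int = 10, seed: int = 0, return_details: bool = False):
    """Matrix temperature of an incidence matrix on the 0-100 scale.

    The matrix is packed by iterative row/column ranking, a smooth isocline
    of perfect nestedness matching the matrix fill is fitted, and the
    temperature is the normalized sum of squared relative distances of
    unexpected presences and absences from that isocline. 0 is perfectly
    nested; the normalization constant 0.04145 scales the maximum toward 100.

    Packing-rank ties are frequent, so the packing is repeated `n_pack`
    times (one deterministic pass plus jittered tie-breaks seeded by `seed`)
    and the coolest packing is reported; the whole procedure is
    deterministic for fixed arguments.
    """
    comm, _ = _as_matrix(m)
    comm = (comm > 0).astype(float)
    if comm.shape[0] < 2 or comm.shape[1] < 2:
        raise ValueError("nestedness needs at least a 2x2 matrix")
    fill = comm.sum() / comm.size
    if fill in (0.0, 1.0):
        warnings.warn("degenerate (empty or full) matrix; temperature is 0")
        return (0.0, None) if return_details else 0.0

    ev = _IsoclineEvaluator(*comm.shape, fill)
    rng = np.random.default_rng(seed)
    best_temp = np.inf
    best_packed = None
    for k in range(max(n_pack, 1)):
        packed = _pack_matrix(comm, rng if k else None)
        temp = ev.temperature(packed)
        if temp < best_temp:
            best_temp, best_packed = temp, packed
    if return_details:
        _, u = ev.temperature(best_packed, return_surprise=True)
        return best_temp, {"packed": best_packed, "surprise": u, "p": ev.p, "fill": fill}
    return best_temp


# ---------------------------------------------------------------------------
# null models and the permutation test

def null_matrix(comm: np.ndarray, model: str, rng: np.random.Generator) -> np.ndarray:
    """One permuted incidence matrix under the named null model.

    ``r00``
        equiprobable fill: the observed number of presences is scattered
        uniformly over the cells.
    ``quasiswap``
        fixed row and column sums via the curveball algorithm.
    """
    comm = (np.asarray(comm) > 0).astype(int)
    if model == "r00":
        flat = np.zeros(comm.size, dtype=int)
        flat[rng.choice(comm.size, size=int(comm.sum()), replace=False)] = 1
        return flat.reshape(comm.shape)
    if model == "quasiswap":
        return _curveball(comm, rng)
    raise ValueError(f"unknown null model {model!r}")


def _curveball(comm: np.ndarray, rng: np.random.Generator, n_trades: int | None = None) -> np.ndarray:
    rows = [set(np.flatnonzero(comm[i])) for i in range(comm.shape[0])]
    nr = len(rows)
    if n_trades is None:
        n_trades = 5 * nr
    for _ in range(n_trades):
        i, j = rng.choice(nr, size=2, replace=False)
        a, b = rows[i], rows[j]
        only_a = list(a - b)
        only_b = list(b - a)
        k = min(len(only_a), len(only_b))
        if k == 0:
            continue
        pool = only_a + only_b
        perm = rng.permutation(len(pool))
        new_a = set(pool[p] for p in perm[: len(only_a)])
        new_b = set(pool[p] for p in perm[len(only_a):])
        rows[i] = (a & b) | new_a
        rows[j] = (a & b) | new_b
    out = np.zeros_like(comm)
    for i, s in enumerate(rows):
        out[i, list(s)] = 1
    return out


@dataclass
class NestednessResult:
    temperature: float
    null_temperatures: np.ndarray
    p_value: float
    null_model: str


def nestedness_test(
    m, null_model: str = "r00", n_perm: int = 999, seed: int = 0
) -> NestednessResult:
    """Permutation test of nestedness; low temperature = more nested.

    p = (1 + #{null temperatures <= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    comm, _ = _as_matrix(m)
    comm = (comm > 0).astype(int)
    rng = np.random.default_rng(seed)

    # r00 and quasiswap both preserve total fill, so one isocline serves the
    # observed matrix and every null.
    fill = comm.sum() / comm.size
    if fill in (0.0, 1.0):
        warnings.warn("degenerate (empty or full) matrix; temperature is 0")
        return NestednessResult(0.0, np.zeros(n_perm), 1.0, null_model)
    ev = _IsoclineEvaluator(*comm.shape, fill)

    def _temp(x: np.ndarray, n_pack: int = 10) -> float:
        best = np.inf
        for k in range(n_pack):
            best = min(best, ev.temperature(_pack_matrix(x.astype(float), rng if k else None)))
        return best

    observed = _temp(comm)
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        nulls[b] = _temp(null_matrix(comm, null_model, rng))
    p = (1 + int((nulls <= observed).sum())) / (1 + n_perm)
    return NestednessResult(observed, nulls, p, null_model)


# ---------------------------------------------------------------------------
# richness vs ordination axes

def richness_axis_correlation(
    richness, ordination: Ordination | np.ndarray, n_perm: int = 999, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of richness against each ordination axis, permutation p.

    The p-value is two-sided: the fraction of label permutations whose |r|
    meets or exceeds the observed |r|, with the +1 correction.
    """
    scores = ordination.scores if isinstance(ordination, Ordination) else np.asarray(ordination)
    richness = np.asarray(richness, dtype=float)
    if richness.shape[0] != scores.shape[0]:
        raise ValueError("richness length does not match ordination scores")
    if np.std(richness) == 0:
        raise ValueError("richness has zero variance")
    rng = np.random.default_rng(seed)
    k = scores.shape[1]
    r_obs = np.array([np.corrcoef(richness, scores[:, a])[0, 1] for a in range(k)])
    exceed = np.zeros(k, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(richness.shape[0])
        for a in range(k):
            r_b = np.corrcoef(richness[perm], scores[:, a])[0, 1]
            if abs(r_b) >= abs(r_obs[a]) - 1e-15:
                exceed[a] += 1
    p = (1 + exceed) / (1 + n_perm)
    return r_obs, p
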