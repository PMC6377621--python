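"""Independent reference implementations used only by tests.

Each oracle deliberately follows a different computational route from the
package code it checks (brute force, enumeration, closed forms, or
equation-wise closed-form estimation).
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# ARISA: rule-by-rule reference filter

def reference_peak_filter(sizes, rfu, window, rfu_floor=30.0, rel=0.003):
    """Apply the three acceptance predicates independently per peak."""
    sizes = np.asarray(sizes, dtype=float)
    rfu = np.asarray(rfu, dtype=float)
    total = sum(r for r in rfu if r > rfu_floor)
    keep = []
    for s, r in zip(sizes, rfu):
        in_window = window[0] <= s <= window[1]
        over_floor = r > rfu_floor
        over_rel = total > 0 and (r / total) > rel
        if in_window and over_floor and over_rel:
            keep.append((s, r))
    return keep


def reference_bins(sizes, threshold=1.0):
    """Transitive closure of the |a-b| <= threshold relation on sizes."""
    sizes = sorted(set(float(s) for s in sizes))
    if not sizes:
        return []
    groups = [[sizes[0]]]
    for s in sizes[1:]:
        if s - groups[-1][-1] <= threshold:
            groups[-1].append(s)
        else:
            groups.append([s])
    return groups


# ---------------------------------------------------------------------------
# terrain

def brute_force_coast_distance(dem, points):
    """Exhaustive scan over all zero-elevation cell centers."""
    out = []
    coast = []
    for r in range(dem.nrows):
        for c in range(dem.ncols):
            if dem.values[r, c] == 0.0:
                coast.append(dem.cell_center(r, c))
    for x, y in np.atleast_2d(points):
        out.append(min(np.hypot(x - cx, y - cy) for cx, cy in coast))
    return np.array(out)


def semivariogram(values: np.ndarray, cellsize: float, max_lag_cells: int):
    """Empirical semivariance along rows for integer cell lags."""
    gamma = []
    for lag in range(1, max_lag_cells + 1):
        diff = values[:, lag:] - values[:, :-lag]
        gamma.append(0.5 * np.mean(diff**2))
    return np.array(gamma)


# ---------------------------------------------------------------------------
# SEM: path enumeration and closed-form recursive ML

def path_enumeration_total_effects(b: np.ndarray) -> np.ndarray:
    """Total effects by explicit enumeration of all directed paths.

    ``b[e, c]`` is the coefficient of cause c in effect e's equation. Returns
    the matrix of summed path products for every (effect, cause) pair.
    """
    p = b.shape[0]
    edges = {(e, c): b[e, c] for e in range(p) for c in range(p) if b[e, c] != 0}
    total = np.zeros_like(b)

    def walk(current, target, product, visited):
        nonlocal acc
        if current == target:
            acc += product
            return
        for (e, c), w in edges.items():
            if c == current and e not in visited:
                walk(e, target, product * w, visited | {e})

    for cause in range(p):
        for effect in range(p):
            if cause == effect:
                continue
            acc = 0.0
            walk(cause, effect, 1.0, {cause})
            total[effect, cause] = acc
    return total


def random_recursive_model(rng, n_vars: int, edge_prob: float = 0.45):
    """Random DAG over v0..v{n-1}; returns (model text, edge list)."""
    edges = []
    for j in range(1, n_vars):
        for i in range(j):
            if rng.random() < edge_prob:
                edges.append((f"v{i}", f"v{j}"))
    if not edges:
        edges.append(("v0", f"v{n_vars - 1}"))
    lines = {}
    for cause, effect in edges:
        lines.setdefault(effect, []).append(cause)
    mentioned = {v for e in edges for v in e}
    text = "\n".join(f"{eff} <- {' + '.join(causes)}" for eff, causes in lines.items())
    # tie isolated variables in via a free covariance so they stay observed
    isolated = [f"v{i}" for i in range(n_vars) if f"v{i}" not in mentioned]
    for v in isolated:
        text += f"\n{v} ~~ {edges[0][0]}"
    return text, edges


def closed_form_recursive_ml(model, S: np.ndarray) -> tuple[float, np.ndarray]:
    """ML discrepancy of a recursive diagonal-disturbance model, closed form.

    For a recursive path model with a saturated exogenous block and no
    disturbance covariances, the ML solution is equation-wise OLS computed
    from the sample covariance; the implied covariance is assembled by
    forward propagation through the topological order (an independent route
    from the package's (I-B)^-1 Psi (I-B)^-T assembly).
    """
    names = model.observed
    pos = {v: i for i, v in enumerate(names)}
    p = len(names)
    parents = {v: model.parents(v) for v in model.endogenous}
    order = [model.names[i] for i in model.topological_order()
             if model.names[i] in pos]

    sigma = np.zeros((p, p))
    exog = [v for v in names if v not in parents]
    ix = [pos[v] for v in exog]
    sigma[np.ix_(ix, ix)] = S[np.ix_(ix, ix)]
    done = list(exog)
    for v in order:
        if v in done:
            continue
        pa = parents[v]
        pi = [pos[u] for u in pa]
        vi = pos[v]
        beta = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, vi])
        psi = S[vi, vi] - S[vi, pi] @ beta
        for u in done:
            ui = pos[u]
            sigma[vi, ui] = sigma[ui, vi] = beta @ sigma[pi, ui]
        sigma[vi, vi] = beta @ sigma[np.ix_(pi, pi)] @ beta + psi
        done.append(v)

    sign, logdet_sigma = np.linalg.slogdet(sigma)
    _, logdet_s = np.linalg.slogdet(S)
    f = logdet_sigma + float(np.trace(np.linalg.solve(sigma, S))) - logdet_s - p
    return f, sigma


# ---------------------------------------------------------------------------
# spatial: dense PCNM oracle

def dense_pcnm(coords: np.ndarray, truncation: float):
    """PCNM by explicit Gower centering and full eigendecomposition."""
    n = len(coords)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = np.hypot(*(np.asarray(coords[i]) - np.asarray(coords[j])))
    d = np.where(d > truncation, 4 * truncation, d)
    np.fill_diagonal(d, 0.0)
    ones = np.ones((n, n)) / n
    a = -0.5 * d**2
    g = a - ones @ a - a @ ones + ones @ a @ ones
    w, v = np.linalg.eigh(g)
    idx = np.argsort(w)[::-1]
    w, v = w[idx], v[:, idx]
    keep = w > max(abs(w).max(), 1.0) * 1e-10
    return w[keep], v[:, keep]
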