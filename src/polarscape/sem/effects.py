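"""Effect decompositions, composite net effects, diagnostics, prediction."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import SEMFit

__all__ = ["collapsed_paths", "total_effects", "net_effects", "residual_covariance",
           "predict_richness"]

_BIOTIC_OUTCOMES = ["cyano_s", "fungal_s", "multi_s"]


def collapsed_paths(fit: SEMFit, standardized: bool = False) -> pd.DataFrame:
    """Path matrix over observed variables with composites expanded.

    Entry (effect, cause) is the coefficient of `cause` in the structural
    equation of `effect`; a path routed through a composite contributes
    ``path * weight``.
    """
    model = fit.model
    theta = fit.estimates.to_numpy()
    obs = {v: i for i, v in enumerate(model.observed)}
    p = len(obs)
    B = np.zeros((p, p))

    def value(k, fixed):
        return theta[k] if k is not None else fixed

    comp_weights: dict[str, list[tuple[str, float]]] = {c: [] for c in model.composites}
    direct: list[tuple[str, str, float]] = []
    for e, c, k, fixed in model.path_items:
        ename, cname = model.names[e], model.names[c]
        if ename in comp_weights:
            comp_weights[ename].append((cname, value(k, fixed)))
        else:
            direct.append((ename, cname, value(k, fixed)))
    for ename, cname, coef in direct:
        if cname in comp_weights:
            for leaf, w in comp_weights[cname]:
                B[obs[ename], obs[leaf]] += coef * w
        else:
            B[obs[ename], obs[cname]] += coef
    if standardized:
        sd = np.sqrt(np.diag(fit.sigma))
        B = B * sd[None, :] / sd[:, None]
    return pd.DataFrame(B, index=model.observed, columns=model.observed)


def total_effects(fit: SEMFit, standardized: bool = True) -> pd.DataFrame:
    """Direct, indirect, and total effects for every (source, outcome) pair.

    Total effects are ``(I - B)^-1 - I`` on the collapsed path matrix, which
    equals the sum over all directed paths of the product of coefficients
    along each path; indirect = total - direct.
    """
    B = collapsed_paths(fit, standardized=standardized).to_numpy()
    names = fit.model.observed
    p = len(names)
    total = np.linalg.inv(np.eye(p) - B) - np.eye(p)
    indirect = total - B
    rows = []
    endo = set(fit.model.endogenous)
    for ei, effect in enumerate(names):
        if effect not in endo:
            continue
        for ci, cause in enumerate(names):
            if cause == effect:
                continue
            if total[ei, ci] == 0 and B[ei, ci] == 0:
                continue
            rows.append(
                {
                    "source": cause,
                    "outcome": effect,
                    "direct": B[ei, ci],
                    "indirect": indirect[ei, ci],
                    "total": total[ei, ci],
                }
            )
    return pd.DataFrame(rows)


def _default_groups(fit: SEMFit) -> dict[str, dict[str, list[str]]]:
    """Construct membership per outcome: spatial / biotic / abiotic causes."""
    model = fit.model
    outcomes = [v for v in _BIOTIC_OUTCOMES if v in model.observed]
    if not outcomes:
        raise ValueError("no richness outcomes found; pass `groups` explicitly")
    spatial_vars = {"s1", "s2"} & set(model.observed)
    B = collapsed_paths(fit)
    groups = {}
    for out in outcomes:
        parents = [c for c in model.observed if B.loc[out, c] != 0]
        groups[out] = {
            "abiotic": [c for c in parents if c not in spatial_vars and c not in _BIOTIC_OUTCOMES],
            "spatial": [c for c in parents if c in spatial_vars],
            "biotic": [c for c in parents if c in _BIOTIC_OUTCOMES],
        }
    return groups


def net_effects(fit: SEMFit, groups: dict[str, dict[str, list[str]]] | None = None) -> pd.DataFrame:
    """Absolute standardized composite-path coefficient per construct.

    For each outcome, each construct's causes are bundled into an emergent
    composite ``C = sum_i c_i x_i`` using the outcome's unstandardized
    collapsed coefficients; the net effect is ``sd(C) / sd(outcome)`` under
    the implied covariance, identical to the absolute standardized path from
    the composite. Constructs with no paths into an outcome report 0.
    """
    if groups is None:
        groups = _default_groups(fit)
    model = fit.model
    obs = {v: i for i, v in enumerate(model.observed)}
    B = collapsed_paths(fit).to_numpy()
    sd = np.sqrt(np.diag(fit.sigma))
    constructs = sorted({c for g in groups.values() for c in g},
                        key=lambda c: ["abiotic", "spatial", "biotic"].index(c)
                        if c in ("abiotic", "spatial", "biotic") else 99)
    table = pd.DataFrame(0.0, index=list(groups), columns=constructs)
    for out, gr in groups.items():
        ei = obs[out]
        for construct, causes in gr.items():
            if not causes:
                continue
            ci = [obs[c] for c in causes]
            coefs = B[ei, ci]
            cov = fit.sigma[np.ix_(ci, ci)]
            table.loc[out, construct] = float(np.sqrt(coefs @ cov @ coefs)) / sd[ei]
    return table


def residual_covariance(fit: SEMFit, top: int = 10) -> dict:
    """Raw and standardized residual covariance S - Sigma(theta_hat).

    Standardized residuals divide by sqrt(S_ii * S_jj); the `top` largest
    off-diagonal magnitudes are listed for respecification.
    """
    resid = fit.S - fit.sigma
    d = np.sqrt(np.diag(fit.S))
    std = resid / np.outer(d, d)
    names = fit.model.observed
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append((names[i], names[j], std[i, j]))
    pairs.sort(key=lambda t: -abs(t[2]))
    return {
        "residual": pd.DataFrame(resid, index=names, columns=names),
        "standardized": pd.DataFrame(std, index=names, columns=names),
        "largest": pairs[:top],
    }


def predict_richness(
    fit: SEMFit, newdata: pd.DataFrame, outcomes: list[str] | None = None
) -> pd.DataFrame:
    """Reduced-form expected values of the endogenous variables.

    `newdata` must contain every exogenous predictor of the fitted model;
    endogenous mediators are propagated through the structural equations.
    Values are centered with the fitting-sample means and the outcome means
    are added back.
    """
    model = fit.model
    exog = model.exogenous
    missing = [v for v in exog if v not in newdata.columns]
    if missing:
        raise ValueError(f"newdata lacks exogenous predictors: {missing}")
    theta = fit.estimates.to_numpy()
    n = len(newdata)
    values: dict[str, np.ndarray] = {
        v: newdata[v].to_numpy(dtype=float) - fit.means[v] for v in exog
    }
    by_effect: dict[int, list[tuple[int, float]]] = {}
    for e, c, k, fixed in model.path_items:
        by_effect.setdefault(e, []).append((c, theta[k] if k is not None else fixed))
    for vi in model.topological_order():
        name = model.names[vi]
        if name in values or vi not in by_effect:
            continue
        acc = np.zeros(n)
        for c, coef in by_effect[vi]:
            acc += coef * values[model.names[c]]
        values[name] = acc
    endo = model.endogenous
    out = outcomes or endo
    bad = [v for v in out if v not in endo]
    if bad:
        raise ValueError(f"not endogenous in this model: {bad}")
    return pd.DataFrame({v: values[v] + fit.means[v] for v in out}, index=newdata.index)
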