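"""Maximum-likelihood covariance-structure estimation.

The implied covariance follows the reduced form of the recursive system:
with path matrix B and exogenous/disturbance covariance Psi over the full
variable set (composites included, with zero disturbance),
``Sigma = (I - B)^-1 Psi (I - B)^-T`` restricted to the observed variables.
``F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p`` is minimized by
quasi-Newton iteration with an analytic gradient; ``chi2 = (n - 1) F_ML``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import PathModel

__all__ = ["SEMFit", "fit_ml", "fit_indices", "standardize", "implied_covariance", "simulate"]

_PENALTY = 1e10


@dataclass
class SEMFit:
    """Fitted model: estimates, implied moments, fit statistics."""

    model: PathModel
    estimates: pd.Series          # free parameters, by name
    se: pd.Series
    sigma: np.ndarray             # implied covariance of observed variables
    sigma_full: np.ndarray        # implied covariance incl. composites
    S: np.ndarray                 # sample covariance
    means: pd.Series              # sample means of observed variables
    n: int
    F_ML: float
    chi2: float
    df: int
    p_value: float
    chi2_baseline: float
    df_baseline: int
    cfi: float
    converged: bool
    grad_norm: float
    std_estimates: pd.Series = field(default=None)

    @property
    def columns(self) -> list[str]:
        return list(self.model.observed)

    def param(self, name: str, standardized: bool = False) -> float:
        src = self.std_estimates if standardized else self.estimates
        return float(src[name])

    def report(self) -> dict:
        """JSON-ready summary."""
        return {
            "n": self.n,
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "cfi": self.cfi,
            "converged": self.converged,
            "estimates": self.estimates.to_dict(),
            "se": self.se.to_dict(),
            "standardized": self.std_estimates.to_dict(),
        }


def implied_covariance(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """Implied covariance over the full variable set (composites included)."""
    B, Psi = model.matrices(np.asarray(theta, dtype=float))
    a = np.linalg.inv(np.eye(model.n_vars) - B)
    return a @ Psi @ a.T


def _prepare_data(data, columns) -> tuple[np.ndarray, pd.Series, int]:
    if isinstance(data, pd.DataFrame):
        df = data[columns].dropna()
        x = df.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
        x = x[~np.isnan(x).any(axis=1)]
    n = x.shape[0]
    if n <= x.shape[1]:
        raise ValueError(f"need more rows ({n}) than variables ({x.shape[1]})")
    S = np.cov(x, rowvar=False, ddof=1)
    means = pd.Series(x.mean(axis=0), index=columns)
    return S, means, n


def _start_values(model: PathModel, S: np.ndarray) -> np.ndarray:
    """OLS-informed starting values.

    Observed-variable paths start at per-equation OLS slopes computed from
    the sample covariance; composite weights at their fixed-scale value;
    composite paths at a small positive value. Variances/covariances start
    at their sample moments, disturbances at half the outcome variance.
    """
    obs_pos = {name: i for i, name in enumerate(model.observed)}
    theta = np.zeros(model.n_free)
    # per-effect OLS on observed parents
    by_effect: dict[int, list[tuple[int, int | None]]] = {}
    for e, c, k, _ in model.path_items:
        by_effect.setdefault(e, []).append((c, k))
    for e, entries in by_effect.items():
        ename = model.names[e]
        if ename in model.composites:
            for c, k in entries:
                if k is not None:
                    theta[k] = 1.0
            continue
        obs_parents = [(c, k) for c, k in entries
                       if model.names[c] in obs_pos and k is not None]
        if obs_parents and ename in obs_pos:
            ei = obs_pos[ename]
            ci = [obs_pos[model.names[c]] for c, _ in obs_parents]
            try:
                beta = np.linalg.solve(S[np.ix_(ci, ci)], S[ci, ei])
            except np.linalg.LinAlgError:
                beta = np.zeros(len(ci))
            for (c, k), b in zip(obs_parents, beta):
                theta[k] = b
        for c, k in entries:
            if k is not None and model.names[c] in model.composites:
                theta[k] = 0.1
    for i, j, k, _ in model.cov_items:
        if k is None:
            continue
        a, b = model.names[i], model.names[j]
        if a in model.composites or b in model.composites:
            continue
        si, sj = obs_pos[a], obs_pos[b]
        if i == j:
            kind = model.parameters[k].kind
            theta[k] = S[si, si] * (0.5 if kind == "psi" else 1.0)
        else:
            theta[k] = S[si, sj]
    return theta


def _objective_factory(model: PathModel, S: np.ndarray):
    n_all = model.n_vars
    obs = model.observed_index
    eye = np.eye(n_all)
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    p = len(obs)
    path_idx = [(e, c, k) for e, c, k, _ in model.path_items if k is not None]
    cov_idx = [(i, j, k) for i, j, k, _ in model.cov_items if k is not None]

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        B, Psi = model.matrices(theta)
        try:
            a = np.linalg.inv(eye - B)
        except np.linalg.LinAlgError:
            return _PENALTY, np.zeros_like(theta)
        sigma_full = a @ Psi @ a.T
        sigma = sigma_full[np.ix_(obs, obs)]
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            # not PD: push back with a smooth penalty on the violation
            w = np.linalg.eigvalsh(sigma)
            grad = _numeric_grad_penalty(model, theta, obs, eye)
            return _PENALTY * (1.0 + abs(float(w.min()))), grad
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        sigma_inv = np.linalg.inv(sigma)
        f = logdet + float((sigma_inv * S).sum()) - logdet_s - p
        # gradient: dF = tr(M dSigma), M = Sigma^-1 (Sigma - S) Sigma^-1
        m_obs = sigma_inv - sigma_inv @ S @ sigma_inv
        m_full = np.zeros((n_all, n_all))
        m_full[np.ix_(obs, obs)] = m_obs
        P = a.T @ m_full @ a                       # Psi derivatives
        Q = (sigma_full @ m_full @ a)              # path derivatives
        grad = np.zeros_like(theta)
        for e, c, k in path_idx:
            grad[k] += 2.0 * Q[c, e]
        for i, j, k in cov_idx:
            grad[k] += P[i, j] if i == j else 2.0 * P[i, j]
        return f, grad

    return objective


def _numeric_grad_penalty(model, theta, obs, eye):
    """Direction of increasing smallest eigenvalue, to escape non-PD regions."""
    grad = np.zeros_like(theta)
    h = 1e-6

    def minev(t):
        B, Psi = model.matrices(t)
        try:
            a = np.linalg.inv(eye - B)
        except np.linalg.LinAlgError:
            return -1e6
        sf = a @ Psi @ a.T
        return float(np.linalg.eigvalsh(sf[np.ix_(obs, obs)]).min())

    base = minev(theta)
    for k in range(theta.size):
        t = theta.copy()
        t[k] += h
        grad[k] = -_PENALTY * (minev(t) - base) / h
    return grad


def fit_ml(
    model: PathModel,
    data,
    columns: list[str] | None = None,
    *,
    n_restarts: int = 3,
    gtol: float = 1e-5,
    seed: int = 0,
    compute_se: bool = True,
) -> SEMFit:
    """Fit a path model by maximum likelihood on the sample covariance.

    `data` is a DataFrame (columns selected by the model's observed
    variables) or an array whose columns follow `columns`. Rows with missing
    values are dropped listwise. Non-convergence is reported through the
    ``converged`` flag and gradient norm, not raised.
    """
    cols = columns or model.observed
    missing = [c for c in model.observed if c not in (list(data.columns) if isinstance(data, pd.DataFrame) else cols)]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    S, means, n = _prepare_data(data, model.observed)

    objective = _objective_factory(model, S)
    theta0 = _start_values(model, S)
    rng = np.random.default_rng(seed)

    best = None
    start = theta0
    for attempt in range(1 + 2 * n_restarts):
        res = optimize.minimize(
            objective, start, jac=True, method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-15, "gtol": gtol / 10},
        )
        gnorm = float(np.max(np.abs(res.jac)))
        if (best is None or res.fun < best[0].fun
                or (res.fun < best[0].fun + 1e-12 and gnorm < best[1])):
            best = (res, gnorm)
        if best[1] < gtol and best[0].fun < _PENALTY / 2:
            break
        if attempt % 2 == 0:
            # polishing pass: restarting L-BFGS from the incumbent resets its
            # curvature memory and usually drops the gradient further
            start = best[0].x
        else:
            start = theta0 * (1 + 0.1 * rng.standard_normal(theta0.size)) \
                + 0.01 * rng.standard_normal(theta0.size)
    res, gnorm = best
    theta = res.x
    converged = bool(gnorm < gtol and res.fun < _PENALTY / 2)
    if not converged:
        warnings.warn(f"SEM fit did not fully converge (|grad|_inf = {gnorm:.2e})")

    f_min = float(res.fun)
    chi2 = (n - 1) * f_min
    df = model.df
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    # independence baseline: free variances, zero covariances
    corr = S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
    sign, logdet_r = np.linalg.slogdet(corr)
    f_base = -logdet_r
    p = model.n_observed
    chi2_base = (n - 1) * f_base
    df_base = p * (p - 1) // 2
    cfi = _cfi(chi2, df, chi2_base, df_base)

    sigma_full = implied_covariance(model, theta)
    obs = model.observed_index
    sigma = sigma_full[np.ix_(obs, obs)]

    names = [q.name for q in model.parameters]
    estimates = pd.Series(theta, index=names)
    se = pd.Series(np.full(len(names), np.nan), index=names)
    if compute_se:
        se[:] = _standard_errors(objective, theta, n)
    fit = SEMFit(
        model=model, estimates=estimates, se=se, sigma=sigma, sigma_full=sigma_full,
        S=S, means=means, n=n, F_ML=f_min, chi2=chi2, df=df, p_value=p_value,
        chi2_baseline=chi2_base, df_baseline=df_base, cfi=cfi,
        converged=converged, grad_norm=gnorm,
    )
    fit.std_estimates = standardize(fit)
    return fit


def _cfi(chi2_m: float, df_m: int, chi2_b: float, df_b: int) -> float:
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_m - df_m, chi2_b - df_b, 0.0)
    if den == 0.0:
        return 1.0
    cfi = 1.0 - num / den
    if not 0.0 <= cfi <= 1.0:  # pragma: no cover - clamped by construction
        warnings.warn("baseline fits better than the model; CFI clamped")
        cfi = min(max(cfi, 0.0), 1.0)
    return cfi


def _standard_errors(objective, theta: np.ndarray, n: int) -> np.ndarray:
    """Normal-theory SEs from the numerically differentiated gradient.

    acov(theta) = (2 / (n - 1)) H^-1 with H the Hessian of F_ML.
    """
    t = theta.size
    H = np.zeros((t, t))
    h = 1e-5
    for k in range(t):
        step = h * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += step
        tm[k] -= step
        H[:, k] = (objective(tp)[1] - objective(tm)[1]) / (2 * step)
    H = (H + H.T) / 2
    try:
        acov = 2.0 / (n - 1) * np.linalg.inv(H)
        d = np.diag(acov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(t, np.nan)


def fit_indices(fit: SEMFit) -> dict[str, float]:
    """(chi2, df, p, CFI) of a fitted model."""
    return {
        "chi2": fit.chi2,
        "df": fit.df,
        "p_value": fit.p_value,
        "cfi": fit.cfi,
        "chi2_baseline": fit.chi2_baseline,
        "df_baseline": fit.df_baseline,
    }


def standardize(fit: SEMFit) -> pd.Series:
    """Standardized solution: paths scaled by SD(cause)/SD(effect).

    Covariance parameters are returned as correlations, variances as 1, and
    disturbance variances as their share of the outcome variance.
    """
    model = fit.model
    sd = np.sqrt(np.maximum(np.diag(fit.sigma_full), 0.0))
    if np.any(sd == 0):
        bad = [model.names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero implied variance for {bad}; cannot standardize")
    theta = fit.estimates.to_numpy()
    out = pd.Series(np.zeros(model.n_free), index=fit.estimates.index)
    for e, c, k, _ in model.path_items:
        if k is not None:
            out.iloc[k] = theta[k] * sd[c] / sd[e]
    for i, j, k, _ in model.cov_items:
        if k is None:
            continue
        if i == j:
            kind = model.parameters[k].kind
            out.iloc[k] = theta[k] / sd[i] ** 2 if kind == "psi" else 1.0
        else:
            out.iloc[k] = theta[k] / (sd[i] * sd[j])
    return out


def simulate(
    model: PathModel,
    values: dict[str, float] | pd.Series,
    n: int,
    rng: np.random.Generator | int | None = None,
    means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw observed data from the model's structural equations.

    `values` assigns every free parameter by name; exogenous variables and
    disturbances are multivariate normal with covariance Psi, and endogenous
    variables follow the reduced form ``y = (I - B)^-1 e``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = pd.Series(values)
    missing = [q.name for q in model.parameters if q.name not in values.index]
    if missing:
        raise ValueError(f"simulate needs values for parameters: {missing}")
    theta = np.array([values[q.name] for q in model.parameters])
    B, Psi = model.matrices(theta)
    # Psi is PSD by construction of a valid parameterization; draw via eigh
    w, v = np.linalg.eigh((Psi + Psi.T) / 2)
    w = np.maximum(w, 0.0)
    e = rng.standard_normal((n, model.n_vars)) @ (v * np.sqrt(w)).T
    y = np.linalg.solve(np.eye(model.n_vars) - B, e.T).T
    df = pd.DataFrame(y[:, model.observed_index], columns=model.observed)
    if means:
        for k, m in means.items():
            df[k] += m
    return df
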