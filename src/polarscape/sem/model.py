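"""Path-model specification and parsing.

The model syntax, one statement per line (``#`` starts a comment):

.. code-block:: text

    y <- x1 + x2 + 0.5*x3      # directed paths; numeric prefix fixes a coefficient
    composite C <= 1*s1 + s2   # emergent variable: weighted sum, no disturbance
    a ~~ b                     # free covariance
    a ~~ b @0                  # covariance fixed at a value

Composites are identified by fixing one cause weight (the first, to 1, when
none is fixed explicitly). Exogenous observed variables get free variances
and pairwise covariances by default; endogenous variables get a free
disturbance variance. Fixing a default covariance requires an explicit
``@value`` statement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Parameter", "PathModel", "parse_model", "builtin_model", "BUILTIN_MODELS"]


@dataclass(frozen=True)
class Parameter:
    name: str
    kind: str  # "path" | "weight" | "cov" | "var" | "psi"
    index: int


class ModelSyntaxError(ValueError):
    pass


@dataclass
class PathModel:
    """Recursive structural model over observed variables and composites."""

    names: list[str]                      # all variables, composites last
    observed: list[str]
    composites: dict[str, list[str]]      # composite -> causes
    # matrix slot -> either ("free", param_index) or ("fixed", value)
    path_items: list[tuple[int, int, int | None, float]] = field(default_factory=list)
    cov_items: list[tuple[int, int, int | None, float]] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    source: str = ""

    # -- structure ---------------------------------------------------------

    @property
    def n_vars(self) -> int:
        return len(self.names)

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    @property
    def n_free(self) -> int:
        return len(self.parameters)

    @property
    def df(self) -> int:
        p = self.n_observed
        return p * (p + 1) // 2 - self.n_free

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def observed_index(self) -> np.ndarray:
        return np.array([self.names.index(v) for v in self.observed])

    def parents(self, name: str) -> list[str]:
        i = self.index(name)
        return [self.names[j] for e, j, *_ in self.path_items if e == i]

    @property
    def endogenous(self) -> list[str]:
        targets = {self.names[e] for e, *_ in self.path_items}
        return [v for v in self.observed if v in targets]

    @property
    def exogenous(self) -> list[str]:
        endo = set(self.endogenous)
        return [v for v in self.observed if v not in endo]

    # -- assembly ----------------------------------------------------------

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(B, Psi) over the full variable set for a free-parameter vector."""
        n = self.n_vars
        B = np.zeros((n, n))
        Psi = np.zeros((n, n))
        for e, c, k, fixed in self.path_items:
            B[e, c] = theta[k] if k is not None else fixed
        for i, j, k, fixed in self.cov_items:
            v = theta[k] if k is not None else fixed
            Psi[i, j] = v
            Psi[j, i] = v
        return B, Psi

    def validate(self) -> None:
        # acyclicity by Kahn's algorithm over cause -> effect edges
        n = self.n_vars
        adj = [[] for _ in range(n)]
        indeg = [0] * n
        for e, c, *_ in self.path_items:
            adj[c].append(e)
            indeg[e] += 1
        stack = [i for i in range(n) if indeg[i] == 0]
        seen = 0
        while stack:
            u = stack.pop()
            seen += 1
            for v in adj[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    stack.append(v)
        if seen != n:
            cyc = [self.names[i] for i in range(n) if indeg[i] > 0]
            raise ModelSyntaxError(f"path graph contains a cycle through {cyc}")
        p = self.n_observed
        if self.n_free > p * (p + 1) // 2:
            raise ModelSyntaxError(
                f"model not identified: {self.n_free} free parameters exceed "
                f"{p * (p + 1) // 2} observed moments"
            )

    def topological_order(self) -> list[int]:
        n = self.n_vars
        adj = [[] for _ in range(n)]
        indeg = [0] * n
        for e, c, *_ in self.path_items:
            adj[c].append(e)
            indeg[e] += 1
        order, stack = [], [i for i in range(n) if indeg[i] == 0]
        while stack:
            u = stack.pop()
            order.append(u)
            for v in adj[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    stack.append(v)
        return order

    def describe(self) -> str:
        lines = [f"PathModel: {self.n_observed} observed, {self.n_free} free parameters, df={self.df}"]
        for e, c, k, fixed in self.path_items:
            tag = self.parameters[k].name if k is not None else f"fixed {fixed:g}"
            lines.append(f"  {self.names[e]} <- {self.names[c]}   [{tag}]")
        return "\n".join(lines)


_TERM_RE = re.compile(r"^(?:(?P<coef>[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)\*)?(?P<var>[A-Za-z_]\w*)$")


def _parse_terms(rhs: str, lineno: int) -> list[tuple[float | None, str]]:
    out = []
    for raw in rhs.split("+"):
        term = raw.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ModelSyntaxError(f"line {lineno}: cannot parse term {term!r}")
        coef = m.group("coef")
        out.append((float(coef) if coef is not None else None, m.group("var")))
    return out


def parse_model(text: str) -> PathModel:
    """Parse model text into a validated :class:`PathModel`."""
    paths: list[tuple[str, str, float | None, int]] = []   # effect, cause, fixed, lineno
    composites: dict[str, list[tuple[float | None, str]]] = {}
    covs: list[tuple[str, str, float | None, int]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("composite"):
            body = line[len("composite"):].strip()
            if "<=" not in body:
                raise ModelSyntaxError(f"line {lineno}: composite statement needs '<='")
            name, rhs = (s.strip() for s in body.split("<=", 1))
            if name in composites:
                raise ModelSyntaxError(f"line {lineno}: composite {name!r} defined twice")
            composites[name] = _parse_terms(rhs, lineno)
        elif "~~" in line:
            lhs, rhs = (s.strip() for s in line.split("~~", 1))
            fixed = None
            if "@" in rhs:
                rhs, val = (s.strip() for s in rhs.split("@", 1))
                fixed = float(val)
            covs.append((lhs, rhs, fixed, lineno))
        elif "<-" in line:
            effect, rhs = (s.strip() for s in line.split("<-", 1))
            for coef, var in _parse_terms(rhs, lineno):
                paths.append((effect, var, coef, lineno))
        else:
            raise ModelSyntaxError(f"line {lineno}: unrecognized statement {line!r}")

    # variable universe: observed = everything mentioned in paths/composites
    # that is not itself a composite; composites go last.
    observed: list[str] = []

    def note(v: str) -> None:
        if v not in composites and v not in observed:
            observed.append(v)

    for effect, cause, _, lineno in paths:
        if effect in composites:
            raise ModelSyntaxError(
                f"line {lineno}: composite {effect!r} cannot receive '<-' paths"
            )
        note(effect)
        note(cause)
    for name, terms in composites.items():
        for _, v in terms:
            if v in composites:
                raise ModelSyntaxError(f"composite {name!r} may not be built from composites")
            note(v)
    # Covariance statements may introduce a new exogenous variable when its
    # partner is already known (or when the model is covariances-only); a
    # pair of entirely unknown names is rejected.
    pure_cov_model = not observed and not composites
    for a, b, _, lineno in covs:
        if a in composites or b in composites:
            raise ModelSyntaxError(f"line {lineno}: composites cannot appear in '~~'")
        known = set(observed)
        if not pure_cov_model and a not in known and b not in known:
            raise ModelSyntaxError(
                f"line {lineno}: unknown variables {a!r}, {b!r} in covariance"
            )
        note(a)
        note(b)

    names = observed + list(composites)
    model = PathModel(names=names, observed=observed,
                      composites={k: [v for _, v in t] for k, t in composites.items()},
                      source=text)
    idx = {v: i for i, v in enumerate(names)}
    params: list[Parameter] = []

    def new_param(name: str, kind: str) -> int:
        params.append(Parameter(name, kind, len(params)))
        return len(params) - 1

    seen_paths: set[tuple[int, int]] = set()

    def add_path(effect: str, cause: str, fixed: float | None, kind: str, lineno: int | None) -> None:
        key = (idx[effect], idx[cause])
        if key in seen_paths:
            where = f"line {lineno}: " if lineno else ""
            raise ModelSyntaxError(f"{where}duplicate path {effect} <- {cause}")
        seen_paths.add(key)
        if fixed is None:
            sep = "<=" if kind == "weight" else "~"
            k = new_param(f"{effect}{sep}{cause}", kind)
            model.path_items.append((idx[effect], idx[cause], k, 0.0))
        else:
            model.path_items.append((idx[effect], idx[cause], None, fixed))

    for effect, cause, fixed, lineno in paths:
        add_path(effect, cause, fixed, "path", lineno)
    for name, terms in composites.items():
        if all(coef is None for coef, _ in terms):
            terms = [(1.0, terms[0][1])] + list(terms[1:])  # identification
        for coef, v in terms:
            add_path(name, v, coef, "weight", None)

    # covariances: explicit statements first, then the defaults
    seen_covs: set[tuple[int, int]] = set()

    def add_cov(a: str, b: str, fixed: float | None, kind: str) -> None:
        i, j = sorted((idx[a], idx[b]))
        if (i, j) in seen_covs:
            raise ModelSyntaxError(f"duplicate covariance {a} ~~ {b}")
        seen_covs.add((i, j))
        if fixed is None:
            label = f"var({a})" if a == b else f"{names[i]}~~{names[j]}"
            if kind == "psi":
                label = f"psi({a})"
            k = new_param(label, kind)
            model.cov_items.append((i, j, k, 0.0))
        else:
            model.cov_items.append((i, j, None, fixed))

    for a, b, fixed, _ in covs:
        add_cov(a, b, fixed, "cov" if a != b else "var")

    endo = {names[e] for e, *_ in model.path_items if names[e] not in composites}
    for v in observed:
        if (idx[v], idx[v]) not in seen_covs:
            add_cov(v, v, None, "psi" if v in endo else "var")
    exog = [v for v in observed if v not in endo]
    for i, a in enumerate(exog):
        for b in exog[i + 1:]:
            key = tuple(sorted((idx[a], idx[b])))
            if key not in seen_covs:
                add_cov(a, b, None, "cov")
    for c in composites:  # composites carry no disturbance
        model.cov_items.append((idx[c], idx[c], None, 0.0))

    model.parameters = params
    model.validate()
    return model


# ---------------------------------------------------------------------------
# built-in models

_ENV_VARS = ["elevation", "slope", "aspect", "distance", "wetness",
             "temperature", "ph", "nitrogen"]

_FINAL_2019 = """
# Final landscape model: 14 observed variables, df = 35.
soil_water <- temperature + wetness + elevation + distance + slope + aspect
cyano_s    <- elevation + distance + wetness + aspect + slope + space_cyano
fungal_s   <- distance + soil_water + cyano_s + ph + temperature + space_fungal
multi_s    <- cyano_s + fungal_s + nitrogen + distance + elevation + aspect + space_multi
# environmentally independent spatial vectors act through per-outcome composites
composite space_cyano  <= 1*s1 + s2
composite space_fungal <= 1*s1 + s2
composite space_multi  <= 1*s1 + s2
# spatial vectors are residualized against the environment and mutually
# orthogonal by construction, so those covariances are fixed at zero
s1 ~~ s2 @0
""" + "\n".join(
    f"{s} ~~ {v} @0" for s in ("s1", "s2") for v in _ENV_VARS
)

_PREDICTIVE_2019 = """
# Remote-sensing-only variant: predictors observable from satellite/DEM data.
cyano_s  <- elevation + distance + wetness + aspect + slope
fungal_s <- distance + temperature + cyano_s
multi_s  <- cyano_s + fungal_s + distance + elevation + aspect
"""

BUILTIN_MODELS: dict[str, str] = {
    "final_2019": _FINAL_2019,
    "predictive_2019": _PREDICTIVE_2019,
}


def builtin_model(name: str) -> PathModel:
    """Parse one of the shipped named models."""
    try:
        text = BUILTIN_MODELS[name]
    except KeyError:
        raise ValueError(f"unknown built-in model {name!r}; have {sorted(BUILTIN_MODELS)}") from None
    return parse_model(text)
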