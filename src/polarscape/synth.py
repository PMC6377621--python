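"""Synthetic landscapes with a known ground-truth path model.

Everything needed to exercise the pipeline without field data: a smooth
random DEM with a zero-elevation coast edge, sample tables whose biotic
richness follows recursive structural equations plus a spatially
autocorrelated component, nested community incidence matrices, and ARISA
electropherograms that round-trip exactly through the peak-calling rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from . import terrain as terrain_mod
from .arisa import GROUP_WINDOWS, Electropherogram
from .gridio import DEMGrid
from .sem import builtin_model, implied_covariance, simulate
from .sem.model import PathModel

__all__ = [
    "GroundTruth",
    "SyntheticBundle",
    "default_truth",
    "generate_dem",
    "generate_sample_table",
    "generate_community_matrix",
    "generate_electropherogram",
    "generate_bundle",
    "MULTI_TAXA",
]

#: The nine supraspecific multicellular groups scored per site.
MULTI_TAXA = [
    "nematodes", "rotifers", "tardigrades", "springtails", "mites",
    "cyano_mats", "mosses", "lichens", "hypoliths",
]

ENV_VARS = ["elevation", "slope", "aspect", "distance", "wetness",
            "temperature", "ph", "nitrogen"]
SPATIAL_VARS = ["s1", "s2"]
RICHNESS_VARS = ["cyano_s", "fungal_s", "multi_s"]

#: Upper bound of the integer richness scales.
RICHNESS_MAX = {"cyano_s": 120, "fungal_s": 120, "multi_s": 9}


@dataclass
class GroundTruth:
    """Standardized structural coefficients plus noise/spatial settings.

    ``path_coefficients`` maps (cause, effect) to a standardized coefficient;
    the topology must match the built-in final model. ``disturbance_sds``
    default to the values that give every endogenous variable unit implied
    variance. ``spatial_sd`` scales the spatially autocorrelated richness
    component in landscape mode; ``spatial_range`` is the autocorrelation
    range of that Gaussian-process component in metres.
    """

    path_coefficients: dict[tuple[str, str], float]
    exog_corr: pd.DataFrame
    disturbance_sds: dict[str, float] = field(default_factory=dict)
    spatial_sd: float = 1.0
    spatial_range: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.model = builtin_model("final_2019")
        if not self.disturbance_sds:
            self.disturbance_sds = self._unit_variance_disturbances()
        for v, sd in self.disturbance_sds.items():
            if sd < 0:
                raise ValueError(f"disturbance SD for {v} must be >= 0, got {sd}")
        w = np.linalg.eigvalsh(self.implied_covariance().to_numpy())
        if w.min() <= -1e-10:
            raise ValueError("truth-implied covariance is not positive (semi)definite")

    # -- parameterization of the built-in model ----------------------------

    def param_values(self) -> pd.Series:
        """Value for every free parameter of the final model."""
        coefs = dict(self.path_coefficients)
        values: dict[str, float] = {}
        for out, comp in (("cyano_s", "space_cyano"), ("fungal_s", "space_fungal"),
                          ("multi_s", "space_multi")):
            c1 = coefs.pop(("s1", out))
            c2 = coefs.pop(("s2", out))
            if c1 == 0:
                raise ValueError("s1 coefficient fixes the composite scale; must be nonzero")
            values[f"{out}~{comp}"] = c1
            values[f"{comp}<=s2"] = c2 / c1
        for (cause, effect), c in coefs.items():
            values[f"{effect}~{cause}"] = c
        corr = self.exog_corr
        for q in self.model.parameters:
            if q.name in values:
                continue
            if q.kind == "var":
                values[q.name] = 1.0
            elif q.kind == "psi":
                v = q.name[4:-1]
                values[q.name] = self.disturbance_sds[v] ** 2
            elif q.kind == "cov":
                a, b = q.name.split("~~")
                values[q.name] = float(corr.loc[a, b])
        missing = [q.name for q in self.model.parameters if q.name not in values]
        if missing:
            raise ValueError(f"truth does not parameterize: {missing}")
        return pd.Series(values)

    def _unit_variance_disturbances(self) -> dict[str, float]:
        endo = self.model.endogenous
        # walk the causal order: each variable's explained variance depends on
        # the disturbances already fixed for its upstream mediators
        order = [self.model.names[i] for i in self.model.topological_order()
                 if self.model.names[i] in endo]
        out = {v: 0.0 for v in endo}
        for v in order:
            sigma = _implied(self.model, self._values_with(out))
            explained = sigma.loc[v, v]
            if explained >= 1.0:
                raise ValueError(
                    f"explained variance of {v} is {explained:.3f} >= 1; "
                    "shrink the path coefficients"
                )
            out[v] = float(np.sqrt(1.0 - explained))
        return out

    def _values_with(self, sds: dict[str, float]) -> pd.Series:
        saved = self.disturbance_sds
        self.disturbance_sds = sds
        try:
            return self.param_values()
        finally:
            self.disturbance_sds = saved

    def implied_covariance(self) -> pd.DataFrame:
        """Truth-implied covariance of the observed variables."""
        return _implied(self.model, self.param_values())

    def net_effects(self) -> pd.DataFrame:
        """True construct-level net effects (abiotic/spatial/biotic)."""
        sigma = self.implied_covariance()
        coefs = self.path_coefficients
        table = pd.DataFrame(0.0, index=RICHNESS_VARS,
                             columns=["abiotic", "spatial", "biotic"])
        for out in RICHNESS_VARS:
            parents = [c for (c, e) in coefs if e == out]
            groups = {
                "abiotic": [c for c in parents if c in ENV_VARS or c == "soil_water"],
                "spatial": [c for c in parents if c in SPATIAL_VARS],
                "biotic": [c for c in parents if c in RICHNESS_VARS],
            }
            for g, causes in groups.items():
                if not causes:
                    continue
                cvec = np.array([coefs[(c, out)] for c in causes])
                cov = sigma.loc[causes, causes].to_numpy()
                table.loc[out, g] = float(np.sqrt(cvec @ cov @ cvec))
        return table


def _implied(model: PathModel, values: pd.Series) -> pd.DataFrame:
    theta = np.array([values[q.name] for q in model.parameters])
    sigma = implied_covariance(model, theta)
    obs = model.observed_index
    return pd.DataFrame(sigma[np.ix_(obs, obs)], index=model.observed,
                        columns=model.observed)


_DEFAULT_EXOG_CORR = {
    ("elevation", "distance"): 0.45,
    ("elevation", "temperature"): -0.35,
    ("distance", "temperature"): -0.25,
    ("slope", "wetness"): -0.25,
    ("elevation", "wetness"): -0.10,
    ("nitrogen", "wetness"): 0.20,
    ("ph", "nitrogen"): -0.20,
}

_DEFAULT_COEFFS = {
    # soil moisture <- climate and terrain
    ("temperature", "soil_water"): -0.35,
    ("wetness", "soil_water"): 0.30,
    ("elevation", "soil_water"): -0.20,
    ("distance", "soil_water"): 0.20,
    ("slope", "soil_water"): -0.20,
    ("aspect", "soil_water"): -0.15,
    # cyanobacterial richness
    ("elevation", "cyano_s"): 0.21,
    ("distance", "cyano_s"): 0.21,
    ("wetness", "cyano_s"): 0.175,
    ("aspect", "cyano_s"): -0.14,
    ("slope", "cyano_s"): -0.14,
    ("s1", "cyano_s"): 0.27,
    ("s2", "cyano_s"): 0.225,
    # fungal richness
    ("distance", "fungal_s"): 0.175,
    ("soil_water", "fungal_s"): 0.21,
    ("cyano_s", "fungal_s"): 0.20,
    ("ph", "fungal_s"): -0.175,
    ("temperature", "fungal_s"): -0.175,
    ("s1", "fungal_s"): 0.225,
    ("s2", "fungal_s"): 0.20,
    # multicellular richness
    ("cyano_s", "multi_s"): 0.15,
    ("fungal_s", "multi_s"): 0.15,
    ("nitrogen", "multi_s"): 0.20,
    ("distance", "multi_s"): 0.16,
    ("elevation", "multi_s"): 0.16,
    ("aspect", "multi_s"): -0.15,
    ("s1", "multi_s"): 0.15,
    ("s2", "multi_s"): 0.14,
}


def default_exog_corr() -> pd.DataFrame:
    corr = pd.DataFrame(np.eye(len(ENV_VARS)), index=ENV_VARS, columns=ENV_VARS)
    for (a, b), r in _DEFAULT_EXOG_CORR.items():
        corr.loc[a, b] = corr.loc[b, a] = r
    return corr


def default_truth(seed: int = 0, **overrides) -> GroundTruth:
    """The shipped ground truth matching the final model's topology."""
    kw = dict(path_coefficients=dict(_DEFAULT_COEFFS), exog_corr=default_exog_corr(),
              seed=seed)
    kw.update(overrides)
    return GroundTruth(**kw)


# ---------------------------------------------------------------------------
# DEM

def generate_dem(
    nrows: int,
    ncols: int,
    cellsize: float,
    relief: float,
    smoothness: float = 3.0,
    seed: int = 0,
) -> DEMGrid:
    """Smooth random elevation surface with a zero-elevation eastern coast.

    A Gaussian-filtered white-noise field (sigma = `smoothness` cells) is
    superposed on a ramp rising away from the eastern edge; the coast edge is
    shifted to touch zero and negative cells are clipped to sea level.
    """
    if nrows < 8 or ncols < 8:
        raise ValueError("DEM needs at least 8 rows and columns")
    if relief <= 0 or cellsize <= 0:
        raise ValueError("relief and cellsize must be positive")
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=max(smoothness, 0.5),
                            mode="reflect")
    noise /= max(noise.std(), 1e-12)
    ramp = np.linspace(1.0, 0.0, ncols)[None, :] ** 1.2
    z = relief * (0.7 * ramp + 0.3 * 0.5 * (noise + 1.0) * ramp ** 0.5)
    z -= z[:, -1].min()
    z = np.maximum(z, 0.0)
    z[z[:, -1].argmin(), -1] = 0.0
    return DEMGrid(z, cellsize=cellsize)


# ---------------------------------------------------------------------------
# sample table

def _gp_field(coords: np.ndarray, rng: np.random.Generator, range_m: float) -> np.ndarray:
    """Unit-variance draw from a GP with exponential covariance."""
    d = cdist(coords, coords)
    cov = np.exp(-d / max(range_m, 1e-9))
    cov[np.diag_indices_from(cov)] += 1e-8
    return np.linalg.cholesky(cov) @ rng.standard_normal(len(coords))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _quantile_counts(latent: np.ndarray, max_count: int, rng=None) -> np.ndarray:
    """Rank-preserving discretization of latent scores to 0..max_count."""
    n = latent.size
    ranks = pd.Series(latent).rank(method="first").to_numpy()
    u = (ranks - 0.5) / n
    return np.minimum((u * (max_count + 1)).astype(int), max_count)


def generate_sample_table(
    dem: DEMGrid,
    n_sites: int,
    truth: GroundTruth,
    seed: int = 0,
    *,
    mode: str = "landscape",
    discretize: bool = True,
) -> pd.DataFrame:
    """Site table with terrain, soil chemistry, and richness from `truth`.

    ``mode="landscape"`` samples sites on the DEM, derives terrain covariates
    with the terrain module, draws the remaining exogenous variables
    conditionally on them, and adds a shared Gaussian-process spatial
    component (scaled by ``truth.spatial_sd``) to each richness equation.
    ``mode="mvn"`` draws every variable, including the spatial vectors
    ``s1``/``s2``, from the truth's exact multivariate-normal structural
    equations (sites still get DEM coordinates); use this for clean
    parameter-recovery experiments.

    With ``discretize=True`` integer richness columns are added by
    rank-preserving quantile binning of the latent scores (microbial 0-120,
    multicellular 0-9); latent scores stay available as ``*_latent``.
    """
    truth.model.validate()  # cyclic truth cannot be constructed, but be safe
    rng = np.random.default_rng(seed)
    n_cells = dem.nrows * dem.ncols
    if n_sites > n_cells:
        raise ValueError(f"n_sites={n_sites} exceeds {n_cells} DEM cells")
    land = np.flatnonzero(dem.values.ravel() > 0)
    pool = land if land.size >= n_sites else np.arange(n_cells)
    cells = rng.choice(pool, size=n_sites, replace=False)
    rows, cols = np.divmod(cells, dem.ncols)
    x = dem.xllcorner + (cols + 0.5) * dem.cellsize
    y = dem.yllcorner + (dem.nrows - rows - 0.5) * dem.cellsize
    coords = np.column_stack([x, y])

    if mode == "mvn":
        data = simulate(truth.model, truth.param_values(), n_sites, rng)
        table = pd.DataFrame({"x": x, "y": y})
        for c in data.columns:
            table[c] = data[c].to_numpy()
        for v in RICHNESS_VARS:
            table.rename(columns={v: f"{v}_latent"}, inplace=True)
    elif mode == "landscape":
        table = _landscape_table(dem, coords, rows, cols, truth, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # ATP: biomass proxy, independent of everything else by construction
    table["atp"] = np.exp(rng.normal(0.0, 0.8, size=n_sites))
    table["conductivity"] = np.exp(rng.normal(1.0, 0.6, size=n_sites))
    table["carbon"] = np.exp(rng.normal(-1.0, 0.5, size=n_sites))

    for v in RICHNESS_VARS:
        latent = table[f"{v}_latent"].to_numpy()
        table[v] = _quantile_counts(latent, RICHNESS_MAX[v]) if discretize else latent
    table.index.name = "site"
    return table


def _landscape_table(dem, coords, rows, cols, truth, rng) -> pd.DataFrame:
    slope_g, aspect_g = terrain_mod.slope_aspect(dem)
    wet_g = terrain_mod.cti(dem)
    n = len(coords)
    table = pd.DataFrame({
        "x": coords[:, 0],
        "y": coords[:, 1],
        "elevation": dem.values[rows, cols],
        "slope": slope_g.values[rows, cols],
        "aspect": aspect_g.values[rows, cols],
        "distance": terrain_mod.distance_to_coast(dem, coords),
        "wetness": wet_g.values[rows, cols],
    })

    # z-scores of terrain drive the structural equations; soil exogenous
    # variables are drawn conditionally on them so the exogenous correlation
    # structure approximates the truth's.
    terrain_vars = ["elevation", "slope", "aspect", "distance", "wetness"]
    z = {v: _zscore(table[v].to_numpy()) for v in terrain_vars}
    corr = truth.exog_corr
    soil_exog = ["temperature", "ph", "nitrogen"]
    s_tt = corr.loc[terrain_vars, terrain_vars].to_numpy()
    s_st = corr.loc[soil_exog, terrain_vars].to_numpy()
    s_ss = corr.loc[soil_exog, soil_exog].to_numpy()
    zt = np.column_stack([z[v] for v in terrain_vars])
    a = s_st @ np.linalg.inv(s_tt)
    cond_cov = s_ss - a @ s_st.T
    w, vv = np.linalg.eigh((cond_cov + cond_cov.T) / 2)
    half = vv * np.sqrt(np.maximum(w, 0.0))
    zs = zt @ a.T + rng.standard_normal((n, len(soil_exog))) @ half.T
    for i, v in enumerate(soil_exog):
        z[v] = zs[:, i]

    g = _gp_field(coords, rng, truth.spatial_range)
    coefs = truth.path_coefficients
    order = ["soil_water", "cyano_s", "fungal_s", "multi_s"]
    for out in order:
        parents = [c for (c, e) in coefs if e == out and c not in SPATIAL_VARS]
        acc = np.zeros(n)
        for c in parents:
            acc += coefs[(c, out)] * z[c]
        s_net = float(np.hypot(coefs.get(("s1", out), 0.0), coefs.get(("s2", out), 0.0)))
        acc += truth.spatial_sd * s_net * _zscore(g) if s_net else 0.0
        acc += truth.disturbance_sds[out] * rng.standard_normal(n)
        z[out] = acc

    # emit in interpretable units
    table["temperature"] = -5.0 + 3.0 * z["temperature"]       # deg C, summer surface
    table["ph"] = 7.8 + 0.7 * z["ph"]
    table["nitrogen"] = np.exp(-2.3 + 0.5 * z["nitrogen"])      # % total N, lognormal-ish
    table["soil_water"] = np.exp(0.8 + 0.6 * z["soil_water"])   # % moisture, lognormal-ish
    for v in RICHNESS_VARS:
        table[f"{v}_latent"] = z[v]
    return table


# ---------------------------------------------------------------------------
# communities

def generate_community_matrix(
    richness: np.ndarray,
    pool_size: int,
    nestedness_strength: float = 1.0,
    seed: int = 0,
    taxon_names: list[str] | None = None,
) -> pd.DataFrame:
    """Incidence matrix with exact row sums and tunable nestedness.

    At strength 1 every site holds exactly the `richness[i]` highest-ranked
    taxa (perfect nesting); at 0 taxa are sampled uniformly; between, taxa
    are drawn without replacement with geometrically decaying rank weights.
    """
    richness = np.asarray(richness, dtype=int)
    if richness.size and richness.max() > pool_size:
        raise ValueError(
            f"richness {richness.max()} exceeds taxon pool of {pool_size}"
        )
    if not 0.0 <= nestedness_strength <= 1.0:
        raise ValueError("nestedness_strength must lie in [0, 1]")
    if np.any(richness < 0):
        raise ValueError("richness must be non-negative")
    rng = np.random.default_rng(seed)
    names = taxon_names or [f"taxon_{j:03d}" for j in range(pool_size)]
    if len(names) != pool_size:
        raise ValueError("taxon_names length must equal pool_size")
    m = np.zeros((richness.size, pool_size), dtype=int)
    if nestedness_strength >= 1.0:
        for i, r in enumerate(richness):
            m[i, :r] = 1
    else:
        # geometric rank decay; strength 0 -> uniform
        decay = nestedness_strength / (1.0 - nestedness_strength)
        logw = -decay * np.arange(pool_size) * 10.0 / pool_size
        w = np.exp(logw - logw.max())
        p = w / w.sum()
        for i, r in enumerate(richness):
            if r:
                m[i, rng.choice(pool_size, size=r, replace=False, p=p)] = 1
    return pd.DataFrame(m, columns=names).rename_axis(index="site")


# ---------------------------------------------------------------------------
# electropherograms

def generate_electropherogram(
    true_richness: int,
    size_range: tuple[float, float] = GROUP_WINDOWS["cyanobacteria"],
    seed: int = 0,
    noise_peaks: int = 10,
    rfu_scale: float = 5000.0,
    sample_id: str = "sample",
) -> Electropherogram:
    """Profile with exactly `true_richness` peaks passing the acceptance rule.

    True peaks sit >= 2 bp apart inside `size_range` with fluorescence high
    enough to clear both the 30-RFU floor and the 0.3% relative criterion;
    each noise peak violates at least one criterion (out of window, or at or
    below the floor).
    """
    if true_richness < 0:
        raise ValueError("true_richness must be >= 0")
    lo, hi = size_range
    if lo < 50 or hi > 1500 or hi <= lo:
        raise ValueError("size_range must be an interval within [50, 1500]")
    capacity = int((hi - lo) // 2.0)
    if true_richness > capacity:
        raise ValueError(
            f"size_range too narrow: fits {capacity} separated peaks, "
            f"needs {true_richness}"
        )
    rng = np.random.default_rng(seed)
    peaks: list[tuple[float, float]] = []

    if true_richness:
        # sizes on a jittered >= 2bp lattice
        slots = lo + 2.0 * rng.choice(capacity, size=true_richness, replace=False)
        sizes = np.sort(slots + rng.uniform(0.05, 0.9, size=true_richness))
        rfu = rng.uniform(0.2 * rfu_scale, rfu_scale, size=true_richness)
        peaks += list(zip(sizes, rfu))

    n_out = noise_peaks // 2
    n_low = noise_peaks - n_out
    # out-of-window noise, kept small so true peaks stay above 0.3% of total
    for _ in range(n_out):
        side = rng.random() < 0.5
        size = rng.uniform(max(lo - 40, 1.0), lo - 1.0) if side else rng.uniform(hi + 1.0, hi + 80)
        peaks.append((size, rng.uniform(31.0, 80.0)))
    # in-window sub-floor noise (<= 30 RFU never passes)
    for _ in range(n_low):
        size = rng.uniform(lo, hi)
        peaks.append((size, rng.uniform(0.5, 30.0)))

    peaks.sort()
    sizes = np.array([p[0] for p in peaks])
    # enforce strictly increasing, >=2bp clearance around true peaks is by lattice
    for i in range(1, sizes.size):
        if sizes[i] <= sizes[i - 1]:
            sizes[i] = np.nextafter(sizes[i - 1], np.inf) + 1e-3
    rfu = np.array([p[1] for p in peaks])
    profile = Electropherogram(sample_id, sizes, rfu)

    # guarantee the design post-condition against rare ratio violations
    total = rfu[rfu > 30.0].sum()
    if true_richness and total > 0:
        floor_needed = 0.003 * total
        true_mask = rfu > 80.0
        bump = rfu < floor_needed * 1.05
        rfu[true_mask & bump] = floor_needed * 1.5
        profile = Electropherogram(sample_id, sizes, rfu)
    return profile


# ---------------------------------------------------------------------------
# full bundle

@dataclass
class SyntheticBundle:
    dem: DEMGrid
    samples: pd.DataFrame
    communities: dict[str, pd.DataFrame]
    electropherograms: dict[tuple[str, str], Electropherogram]
    truth: GroundTruth


def generate_bundle(
    n_sites: int = 100,
    seed: int = 0,
    truth: GroundTruth | None = None,
    dem_shape: tuple[int, int] = (48, 48),
    cellsize: float = 200.0,
    relief: float = 900.0,
    nestedness_strength: float = 0.9,
    noise_peaks: int = 10,
) -> SyntheticBundle:
    """DEM + sample table + communities + electropherograms, all consistent.

    Richness columns equal the row sums of the incidence matrices, and the
    per-site electropherograms yield exactly those richness values under the
    acceptance rules.
    """
    truth = truth or default_truth(seed=seed)
    rng = np.random.default_rng(seed)
    dem = generate_dem(dem_shape[0], dem_shape[1], cellsize, relief,
                       smoothness=4.0, seed=seed)
    samples = generate_sample_table(dem, n_sites, truth, seed=seed + 1)

    communities: dict[str, pd.DataFrame] = {}
    electropherograms: dict[tuple[str, str], Electropherogram] = {}
    pools = {"cyano_s": 150, "fungal_s": 150, "multi_s": 9}
    group_of = {"cyano_s": "cyanobacteria", "fungal_s": "fungi"}
    for var, pool in pools.items():
        names = MULTI_TAXA if var == "multi_s" else None
        communities[var] = generate_community_matrix(
            samples[var].to_numpy(), pool, nestedness_strength,
            seed=int(rng.integers(2**31)), taxon_names=names,
        )
        communities[var].index = samples.index
    for var, group in group_of.items():
        for site, r in samples[var].items():
            sid = f"site{site:04d}"
            electropherograms[(group, sid)] = generate_electropherogram(
                int(r), GROUP_WINDOWS[group], seed=int(rng.integers(2**31)),
                noise_peaks=noise_peaks, sample_id=sid,
            )
    return SyntheticBundle(dem, samples, communities, electropherograms, truth)
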