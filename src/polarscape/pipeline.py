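"""End-to-end orchestration: data -> arisa -> community -> spatial -> sem.

A run is driven by a :class:`RunConfig` (YAML on disk); every random stage
derives its seed from the config seed, so repeated runs are byte-identical.
Artifacts are plain text (CSV / ESRI ASCII / JSON / Markdown).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arisa as arisa_mod
from . import community as comm_mod
from . import spatial as spatial_mod
from . import synth as synth_mod
from . import terrain as terrain_mod
from .gridio import DEMGrid, read_ascii_grid, write_ascii_grid
from .sem import builtin_model, fit_ml, net_effects, parse_model, predict_richness, total_effects

log = logging.getLogger("polarscape")

__all__ = ["RunConfig", "run_all", "write_bundle", "ABIOTIC_COLUMNS"]

#: Environmental predictors used for residualizing the spatial basis:
#: terrain, soil physicochemistry and temperature; biotic columns and the
#: biomass proxy (ATP) are excluded.
ABIOTIC_COLUMNS = [
    "elevation", "slope", "aspect", "distance", "wetness",
    "temperature", "ph", "nitrogen", "soil_water", "conductivity", "carbon",
]

GROUP_VARS = {"cyanobacteria": "cyano_s", "fungi": "fungal_s"}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "polarscape_run"
    # synthetic-data parameters; ignored when `samples` points at a CSV
    synth: dict = dfield(default_factory=lambda: {"n_sites": 100})
    samples: str | None = None
    dem: str | None = None
    peaks: dict = dfield(default_factory=dict)   # group -> peak CSV path
    arisa: dict = dfield(default_factory=dict)   # thresholds / enabled flag
    community: dict = dfield(default_factory=dict)
    spatial: dict = dfield(default_factory=dict)
    sem: dict = dfield(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("samples", "dem"):
            p = getattr(cfg, key)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"config {key} points at missing file {p}")
        return cfg


def write_bundle(bundle: synth_mod.SyntheticBundle, out: str | Path) -> None:
    """Write a synthetic bundle as plain-text artifacts."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(bundle.dem, out / "dem.asc")
    bundle.samples.to_csv(out / "samples.csv")
    for var, m in bundle.communities.items():
        m.to_csv(out / f"community_{var}.csv")
    by_group: dict[str, list] = {}
    for (group, sid), prof in bundle.electropherograms.items():
        by_group.setdefault(group, []).append(prof)
    for group, profs in by_group.items():
        arisa_mod.write_peak_csv(profs, out / f"peaks_{group}.csv")
    truth = {
        "path_coefficients": {f"{a}->{b}": v for (a, b), v in
                              bundle.truth.path_coefficients.items()},
        "disturbance_sds": bundle.truth.disturbance_sds,
        "spatial_sd": bundle.truth.spatial_sd,
        "spatial_range": bundle.truth.spatial_range,
        "seed": bundle.truth.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _stage_arisa(cfg: RunConfig, table: pd.DataFrame, out: Path,
                 profiles: dict[str, list]) -> dict:
    report = {}
    for group, profs in profiles.items():
        tables = [arisa_mod.call_true_peaks(p, group, **cfg.arisa.get("options", {}))
                  for p in profs]
        rich = pd.Series({t.sample_id: arisa_mod.richness(t) for t in tables})
        _, matrix = arisa_mod.bin_peaks(tables)
        matrix.to_csv(out / f"binned_{group}.csv")
        var = GROUP_VARS.get(group)
        if var:
            order = [f"site{int(i):04d}" for i in table.index]
            table[var] = rich.reindex(order).to_numpy()
        report[group] = {"n_profiles": len(profs), "n_bins": matrix.shape[1],
                         "mean_richness": float(rich.mean())}
    return report


def _stage_community(cfg: RunConfig, communities: dict[str, pd.DataFrame],
                     table: pd.DataFrame, out: Path, seed: int) -> dict:
    opts = cfg.community
    n_perm = int(opts.get("n_perm", 199))
    null_model = opts.get("null_model", "r00")
    n_starts = int(opts.get("nmds_starts", 8))
    report = {}
    for var, m in communities.items():
        inc = (m.to_numpy() > 0).astype(int)
        nonzero = inc.sum(axis=1) > 0
        res = comm_mod.nestedness_test(inc, null_model, n_perm, seed=seed)
        entry = {"temperature": res.temperature, "p_value": res.p_value,
                 "null_model": null_model}
        if nonzero.sum() >= 4:
            d = comm_mod.bray_curtis(inc[nonzero])
            ordn = comm_mod.nmds(d, n_starts=n_starts, seed=seed)
            rich = table.loc[table.index[nonzero], var].to_numpy()
            scores = comm_mod.orient_axes(ordn.scores, rich)
            r, p = comm_mod.richness_axis_correlation(rich, scores, seed=seed)
            entry.update(stress=ordn.stress, converged=ordn.converged,
                         axis_r=list(np.round(r, 4)), axis_p=list(p))
            pd.DataFrame(scores, columns=["nms1", "nms2"]).to_csv(
                out / f"nmds_{var}.csv", index=False)
        report[var] = entry
    return report


def _stage_spatial(cfg: RunConfig, table: pd.DataFrame, out: Path) -> dict:
    coords = table[["x", "y"]].to_numpy()
    basis = spatial_mod.pcnm_basis(coords, cfg.spatial.get("truncation"))
    env_cols = [c for c in cfg.spatial.get("env_columns", ABIOTIC_COLUMNS)
                if c in table.columns]
    resid = spatial_mod.residualize(basis, table[env_cols].to_numpy())
    richness = table[["cyano_s", "fungal_s", "multi_s"]].to_numpy()
    method = cfg.spatial.get("selection", "all")
    keep = spatial_mod.select_pcnm(resid, richness, method=method,
                                   seed=cfg.seed)
    comp = spatial_mod.spatial_components(resid[:, keep], richness)
    table["s1"] = comp.s1
    table["s2"] = comp.s2
    pd.DataFrame({"s1": comp.s1, "s2": comp.s2}, index=table.index).to_csv(
        out / "spatial_components.csv")
    return {
        "n_pcnm": basis.n_components,
        "n_selected": int(len(keep)),
        "truncation_m": basis.truncation_distance,
        "variance_explained_s1_s2": float(comp.variance_explained[:2].sum()),
        "regression_r2": list(np.round(comp.r_squared, 4)),
    }


def _stage_sem(cfg: RunConfig, table: pd.DataFrame, dem: DEMGrid | None,
               out: Path) -> dict:
    name = cfg.sem.get("model", "final_2019")
    model_text = cfg.sem.get("model_text")
    model = parse_model(model_text) if model_text else builtin_model(name)
    fit = fit_ml(model, table, seed=cfg.seed)
    (out / "sem_fit.json").write_text(json.dumps(fit.report(), indent=2))
    total_effects(fit).to_csv(out / "total_effects.csv", index=False)
    net = net_effects(fit)
    net.to_csv(out / "net_effects.csv")

    rasters = []
    if dem is not None and cfg.sem.get("predict", True):
        pred_model = builtin_model("predictive_2019")
        pfit = fit_ml(pred_model, table, seed=cfg.seed, compute_se=False)
        stack = terrain_mod.terrain_stack(dem)
        grid_table = pd.DataFrame({
            "elevation": dem.values.ravel(),
            "slope": stack.slope.values.ravel(),
            "aspect": stack.aspect_dev.values.ravel(),
            "distance": stack.dist_coast.values.ravel(),
            "wetness": stack.cti.values.ravel(),
            "temperature": np.full(dem.values.size, fit.means.get("temperature", 0.0)),
        })
        pred = predict_richness(pfit, grid_table)
        for var in pred.columns:
            g = dem.like(pred[var].to_numpy().reshape(dem.shape))
            write_ascii_grid(g, out / f"predicted_{var}.asc")
            rasters.append(f"predicted_{var}.asc")
    return {
        "model": name,
        "chi2": fit.chi2,
        "df": fit.df,
        "p_value": fit.p_value,
        "cfi": fit.cfi,
        "converged": fit.converged,
        "net_effects": {k: dict(v) for k, v in net.round(4).iterrows()},
        "prediction_rasters": rasters,
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "data"
    try:
        dem = None
        communities: dict[str, pd.DataFrame] = {}
        profiles: dict[str, list] = {}
        if config.samples:
            table = pd.read_csv(config.samples, index_col=0)
            if config.dem:
                dem = read_ascii_grid(config.dem)
            for group, path in config.peaks.items():
                profiles[group] = arisa_mod.read_peak_csv(path)
        else:
            bundle = synth_mod.generate_bundle(seed=config.seed, **config.synth)
            write_bundle(bundle, out / "synth")
            table, dem = bundle.samples.copy(), bundle.dem
            communities = bundle.communities
            for (group, _), _p in bundle.electropherograms.items():
                profiles.setdefault(group, [])
            for (group, _sid), prof in bundle.electropherograms.items():
                profiles[group].append(prof)
        report["n_samples"] = int(len(table))

        if profiles and config.arisa.get("enabled", True):
            stage = "arisa"
            report["arisa"] = _stage_arisa(config, table, out, profiles)

        if communities:
            stage = "community"
            report["community"] = _stage_community(config, communities, table, out,
                                                   seed=config.seed + 1)

        stage = "spatial"
        report["spatial"] = _stage_spatial(config, table, out)

        stage = "sem"
        report["sem"] = _stage_sem(config, table, dem, out)

        table.to_csv(out / "samples_final.csv")
    except Exception as err:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (out / "report.md").write_text(_markdown_report(report))
    return report


def _markdown_report(report: dict) -> str:
    lines = ["# polarscape run report", "", f"seed: {report['seed']}",
             f"samples: {report.get('n_samples')}", ""]
    if "community" in report:
        lines += ["## Community structure", ""]
        for var, e in report["community"].items():
            lines.append(
                f"- **{var}**: temperature {e['temperature']:.2f} "
                f"(P = {e['p_value']:.4g}, null {e['null_model']})"
                + (f", NMS stress {e['stress']:.3f}" if "stress" in e else "")
            )
        lines.append("")
    if "spatial" in report:
        s = report["spatial"]
        lines += ["## Spatial filters", "",
                  f"- PCNMs: {s['n_pcnm']} (selected {s['n_selected']}), "
                  f"truncation {s['truncation_m']:.1f} m",
                  f"- s1+s2 variance share: {s['variance_explained_s1_s2']:.3f}", ""]
    if "sem" in report:
        m = report["sem"]
        lines += ["## Structural equation model", "",
                  f"- model `{m['model']}`: chi2 = {m['chi2']:.3f}, df = {m['df']}, "
                  f"P = {m['p_value']:.4f}, CFI = {m['cfi']:.3f}", "",
                  "| outcome | abiotic | spatial | biotic |", "|---|---|---|---|"]
        for outc, row in m["net_effects"].items():
            lines.append(f"| {outc} | {row.get('abiotic', 0):.3f} | "
                         f"{row.get('spatial', 0):.3f} | {row.get('biotic', 0):.3f} |")
        lines.append("")
    return "\n".join(lines)
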