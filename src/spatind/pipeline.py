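"""End-to-end orchestration: simulate -> indicators -> variography -> PCA.

A :class:`PipelineConfig` (usually loaded from YAML) either points at
survey CSV files or describes a synthetic multi-year, multi-area panel.
:func:`run_pipeline` executes every stage, skipping (species, sub-area,
year) slices that fail (e.g. empty slices) with a logged warning rather
than aborting, and writes a self-describing output tree::

    outdir/
      surveys/<area>_<year>.csv     (synthetic runs only)
      indicators.csv                one row per species x area x year
      vario/<slice>.json            c80, range, nugget per slice
      pca/<pooling>.json            loadings, scores, supplementary corr.
      models/<pooling>.json         stepwise regression summary
      manifest.json                 config echo, seed, row counts, warnings
      summary.md                    human-readable tables
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indicators import compute_indicator_table
from .multivariate import run_pooled_analyses
from .simulate import SimConfig, simulate_multiyear_panel
from .survey import SurveyDataset, project_coordinates, read_survey_csv, write_survey_csv
from .variogram import DegenerateVariogramError, indicator_variography

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config", "build_panel_configs"]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


@dataclasses.dataclass
class PipelineConfig:
    """Everything one pipeline run needs; YAML keys mirror the field names."""

    output: str
    seed: int = 0
    inputs: list[str] | None = None         # survey CSVs; None => simulate
    simulate: dict | None = None            # see build_panel_configs
    species: list[str] | None = None
    dlim: float = 20.0
    min_patch_fraction: float = 0.10
    cutoff_fraction: float = 0.80
    lag_width: float = 1.0
    max_lag: float | None = None
    alpha: float = 0.05
    variance_target_pct: float = 85.0
    max_axes: int = 5

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config must set exactly one of 'inputs' or 'simulate'")
        if not 0 < self.cutoff_fraction <= 1:
            raise ValueError("cutoff_fraction must be in (0, 1]")
        if self.dlim <= 0 or self.lag_width <= 0:
            raise ValueError("dlim and lag_width must be positive")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def build_panel_configs(sim: dict, seed: int) -> dict[str, list[SimConfig]]:
    """Expand the ``simulate`` config block into per-area SimConfig lists.

    Block layout::

        years: [2001, 2002, ...]
        base: {transect_spacing: 5, variogram_range: 10, ...}
        areas:
          S1:
            base overrides...
            total_biomass: [per-year list or scalar]
            occupied_fraction: [per-year list or scalar]

    Per-year lists let biomass and occupancy co-vary across years.  Each
    (area, year) gets a distinct deterministic seed derived from ``seed``.
    """
    years = list(sim["years"])
    base = dict(sim.get("base", {}))
    out: dict[str, list[SimConfig]] = {}
    for ai, (area, overrides) in enumerate(sorted(sim["areas"].items())):
        merged = {**base, **(overrides or {})}
        unknown = set(merged) - _SIM_FIELDS
        if unknown:
            raise ValueError(f"unknown simulate key(s) for area {area!r}: {sorted(unknown)}")
        configs = []
        for yi, year in enumerate(years):
            kw: dict[str, Any] = {}
            for k, v in merged.items():
                if k in ("total_biomass", "occupied_fraction", "log_mean", "log_sd") \
                        and isinstance(v, (list, tuple)):
                    if len(v) != len(years):
                        raise ValueError(f"{k} list for area {area!r} must have one "
                                         f"entry per year")
                    kw[k] = v[yi]
                elif k in ("extent", "cg_shift", "species", "origin"):
                    kw[k] = _coerce(k, v)
                else:
                    kw[k] = v
            kw["survey_year"] = int(year)
            kw["sub_area"] = str(area)
            kw["seed"] = int(seed) + 7919 * ai + 104729 * yi
            configs.append(SimConfig(**kw))
        out[str(area)] = configs
    return out


def _coerce(key: str, v):
    if key == "extent" or key == "origin":
        return tuple(v)
    if key == "species":
        return tuple(v)
    if key == "cg_shift" and isinstance(v, dict):
        return {sp: tuple(sh) for sp, sh in v.items()}
    return v


def _log(msg: str) -> None:
    print(f"[spatind] {msg}", file=sys.stderr)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return {c: obj[c].tolist() for c in obj.columns} | {"_index": [str(i) for i in obj.index]}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    # ---- stage 1: obtain surveys -------------------------------------
    datasets: list[SurveyDataset] = []
    if config.simulate is not None:
        (outdir / "surveys").mkdir(exist_ok=True)
        for area, cfgs in build_panel_configs(config.simulate, config.seed).items():
            for ds, truth in simulate_multiyear_panel(cfgs):
                datasets.append(ds)
                name = f"{area}_{truth.config.survey_year}"
                write_survey_csv(ds, outdir / "surveys" / f"{name}.csv")
                (outdir / "surveys" / f"{name}.truth.json").write_text(
                    json.dumps(truth.to_dict(), indent=1, default=_jsonable))
        _log(f"simulated {len(datasets)} surveys in {time.time() - t0:.1f}s")
    else:
        for path in config.inputs:
            ds = read_survey_csv(path, species=config.species)
            if not (ds.has_projection and ds.origin is not None):
                ds = project_coordinates(ds)
            datasets.append(ds)
        _log(f"read {len(datasets)} survey file(s)")

    species = list(config.species or datasets[0].species)

    # ---- stage 2+3: indicators and variography per slice -------------
    t1 = time.time()
    (outdir / "vario").mkdir(exist_ok=True)
    ind_rows, vario_records = [], {}
    for ds in datasets:
        table = compute_indicator_table(ds, species, dlim=config.dlim,
                                        min_fraction=config.min_patch_fraction)
        pds = ds if ds.has_projection else project_coordinates(ds)
        x, y = pds.xy()
        for _, row in table.iterrows():
            key = f"{row['species']}_{row['sub_area']}_{row['year']}"
            try:
                v = indicator_variography(x, y, pds.density(row["species"]),
                                          pds.area_influence,
                                          fraction=config.cutoff_fraction,
                                          lag_width=config.lag_width,
                                          max_lag=config.max_lag)
            except DegenerateVariogramError as exc:
                warnings_log.append(f"variography skipped for {key}: {exc}")
                _log(warnings_log[-1])
                continue
            rec = row.to_dict()
            rec["c80"] = v["cutoff"].c80
            rec["range_nmi"] = v["range_nmi"]
            rec["nugget_pct"] = v["nugget_pct"]
            ind_rows.append(rec)
            vario_records[key] = {
                "c80": v["cutoff"].c80,
                "captured_fraction": v["cutoff"].captured_fraction,
                "proportion_above": v["proportion"],
                "range_nmi": v["range_nmi"],
                "nugget_pct": v["nugget_pct"],
                "sill": v["fit"].sill,
                "lag_centres": v["empirical"].lag_centres,
                "semivariance": v["empirical"].semivariance,
                "pair_counts": v["empirical"].pair_counts,
            }
            (outdir / "vario" / f"{key}.json").write_text(
                json.dumps(vario_records[key], indent=1, default=_jsonable))
    panel = pd.DataFrame(ind_rows)
    panel.to_csv(outdir / "indicators.csv", index=False)
    _log(f"indicators + variography for {len(panel)} slices in {time.time() - t1:.1f}s")

    # ---- stage 4: pooled PCA + regression ----------------------------
    t2 = time.time()
    (outdir / "pca").mkdir(exist_ok=True)
    (outdir / "models").mkdir(exist_ok=True)
    import warnings as _w
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        pooled = run_pooled_analyses(panel, alpha=config.alpha,
                                     variance_target_pct=config.variance_target_pct,
                                     max_axes=config.max_axes)
    warnings_log += [str(c.message) for c in caught]
    for name, res in pooled.items():
        safe = name.replace(":", "_")
        pca = res["pca"]
        (outdir / "pca" / f"{safe}.json").write_text(json.dumps({
            "pooling": name,
            "n_rows": pca.n_rows,
            "eigenvalues": pca.eigenvalues,
            "variance_explained_pct": pca.variance_explained,
            "loadings": pca.loadings,
            "loading_pvalues": pca.loading_pvalues,
            "scores": pca.scores,
            "supplementary_correlations": pca.supplementary_correlations,
            "supplementary_pvalues": pca.supplementary_pvalues,
        }, indent=1, default=_jsonable))
        reg = res["regression"]
        (outdir / "models" / f"{safe}.json").write_text(json.dumps({
            "pooling": name,
            "candidate_axes": reg.candidate_axes,
            "selected": reg.selected,
            "coefficients": reg.coefficients,
            "r_squared": reg.r_squared,
            "entry_pvalues": reg.entry_pvalues,
            "residual_mean": float(np.mean(reg.residuals)),
        }, indent=1, default=_jsonable))
    _log(f"pooled analyses ({len(pooled)}) in {time.time() - t2:.1f}s")

    # ---- manifest + summary ------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_surveys": len(datasets),
        "n_indicator_rows": len(panel),
        "n_poolings": len(pooled),
        "warnings": warnings_log,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=_jsonable))
    _write_summary(outdir, panel, pooled)
    _log(f"done in {time.time() - t0:.1f}s -> {outdir}")
    return outdir


def _write_summary(outdir: Path, panel: pd.DataFrame, pooled: dict) -> None:
    lines = ["# Pipeline summary", "", "## Spatial indicators per slice", "", "```"]
    if len(panel):
        lines.append(panel.round(3).to_string(index=False))
    lines.append("```")
    for name, res in pooled.items():
        pca, reg = res["pca"], res["regression"]
        lines += ["", f"## Pooling {name}", "",
                  f"Variance explained (%): "
                  f"{np.round(pca.variance_explained[:res['n_axes']], 1).tolist()}",
                  "", "```", pca.loadings.round(2).to_string(), "```", "",
                  f"Supplementary correlations:", "",
                  "```", pca.supplementary_correlations.round(2).to_string(), "```", "",
                  f"Stepwise model: selected={reg.selected} "
                  f"R2={reg.r_squared:.3f} coefficients={ {k: round(v, 3) for k, v in reg.coefficients.items()} }"]
    (outdir / "summary.md").write_text("\n".join(lines) + "\n")
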