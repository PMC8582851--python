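"""End-to-end orchestration: simulate → value → change → importance → gradient.

:func:`run_pipeline` runs the five stages on a synthetic study area,
writes every artifact (GeoTIFF rasters, CSV tables, JSON metrics)
under an output directory and returns a manifest mapping each
artifact to a content hash. Hashes are computed over the logical
content (array bytes, CSV text) so reruns with the same configuration
and seed produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .change import change_rate, classify_change
from .errors import ConfigurationError
from .gradient import builtin_schemes, esv_by_gradient, factor_correlation
from .grids import GridSpec, write_raster
from .importance import RFConfig, importance, mlr_baseline
from .synth import Scenario, generate_bundle
from .valuation import (
    CoefficientTable,
    LAND_CLASSES,
    SERVICES,
    aggregate,
    compute_esv,
    load_coefficients,
)

logger = logging.getLogger("esvpipe")


@dataclass
class PipelineConfig:
    """Everything one full run needs."""

    outdir: Path
    grid: GridSpec = field(default_factory=lambda: GridSpec(60, 60))
    scenario: Scenario = field(default_factory=Scenario)
    coefficients_path: Path | None = None  # None -> packaged 2015 table
    k_classes: int = 7
    rf: RFConfig = field(default_factory=lambda: RFConfig(mtry=5, ntree=100))
    seed: int = 0
    subsample: int | None = None  # observations for the RF stage; None = all cells

    def load_coefficients(self) -> CoefficientTable:
        if self.coefficients_path is None:
            return load_coefficients()
        path = Path(self.coefficients_path)
        if not path.exists():
            raise ConfigurationError(f"coefficient table not found: {path}")
        return CoefficientTable.from_csv(path)


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _hash_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict, **kwargs) -> None:
    text = df.to_csv(**kwargs)
    path.write_text(text)
    manifest[str(path.name)] = _hash_text(text)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all five stages; return (and write) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "grid": [config.grid.n_rows, config.grid.n_cols],
        "artifacts": {},
        "metrics": {},
        "stages": {},
    }
    art = manifest["artifacts"]
    coeffs = config.load_coefficients()

    # --- stage 1: simulate -------------------------------------------------
    logger.info("simulating %sx%s landscape", config.grid.n_rows, config.grid.n_cols)
    bundle = generate_bundle(config.grid, config.scenario, seed=config.seed)
    for year, comp in bundle.compositions.items():
        p = out / f"landuse_{year}.tif"
        write_raster(p, comp.fractions, config.grid, band_names=LAND_CLASSES)
        art[p.name] = _hash_array(comp.fractions.astype(np.float32))
    write_raster(out / "elevation.tif", bundle.elevation, config.grid)
    art["elevation.tif"] = _hash_array(bundle.elevation.astype(np.float32))
    truth = pd.DataFrame({"rank": range(1, 16), "factor": bundle.truth_ranking})
    _write_csv(truth, out / "truth_ranking.csv", art, index=False)
    manifest["stages"]["simulate"] = "ok"

    # --- stage 2: value ----------------------------------------------------
    esv_by_year = {}
    summaries = []
    for year, comp in bundle.compositions.items():
        esv = compute_esv(comp, coeffs)
        esv_by_year[year] = esv
        p = out / f"esv_{year}.tif"
        write_raster(p, esv.values, config.grid, band_names=SERVICES)
        art[p.name] = _hash_array(esv.values.astype(np.float32))
        summaries.append(aggregate(esv, bundle.regions, level="second"))
    summary = pd.concat(summaries, ignore_index=True)
    _write_csv(summary, out / "esv_summary.csv", art, index=False)
    years = list(bundle.compositions)
    totals = {y: esv_by_year[y].total() for y in years}
    manifest["metrics"]["esv_total_by_year"] = totals
    manifest["metrics"]["esv_change_rates_pct"] = {
        f"{a}-{b}": change_rate(totals[a], totals[b])
        for a, b in zip(years[:-1], years[1:])
    }
    manifest["stages"]["value"] = "ok"

    # --- stage 3: change ---------------------------------------------------
    delta = (
        esv_by_year[years[-1]].per_cell_total() - esv_by_year[years[0]].per_cell_total()
    )
    cm = classify_change(delta, k=config.k_classes,
                         year_start=years[0], year_end=years[-1])
    p = out / "esv_change.tif"
    write_raster(p, np.stack([cm.delta, cm.labels.astype(float)]), config.grid,
                 band_names=["delta_yuan", "jenks_class"])
    art[p.name] = _hash_array(cm.delta.astype(np.float32))
    breaks = pd.DataFrame(
        {"interval": cm.intervals(), "n_cells": cm.class_counts()}
    )
    _write_csv(breaks, out / "change_classes.csv", art, index=False)
    manifest["stages"]["change"] = "ok"

    # --- stage 4: importance ------------------------------------------------
    rng = np.random.default_rng(config.seed + 100)
    imp_rows = []
    metrics_rows = {}
    for year_index, year in enumerate(years):
        X = bundle.stacks[year].as_matrix()
        y = esv_by_year[year].per_cell_total().ravel()
        if config.subsample is not None and config.subsample < len(y):
            sel = rng.choice(len(y), size=config.subsample, replace=False)
            X, y = X[sel], y[sel]
        cfg = RFConfig(
            mtry=config.rf.mtry, ntree=config.rf.ntree,
            mtry_grid=config.rf.mtry_grid, ntree_grid=config.rf.ntree_grid,
            ntree_tolerance=config.rf.ntree_tolerance,
            seed=config.seed + year_index,
        )
        res = importance(X, y, cfg)
        base = mlr_baseline(X, y, cfg)
        metrics_rows[year] = {
            "oob_r2": res.oob_r2, "mtry": res.mtry, "ntree": res.ntree,
            "mlr_r2": base.mlr_r2, "mlr_pct_rmse": base.mlr_pct_rmse,
            "rf_r2": base.rf_r2, "rf_pct_rmse": base.rf_pct_rmse,
        }
        for f, c in res.coefficients.items():
            imp_rows.append(
                {"year": year, "factor": f, "coefficient": c,
                 "grade": res.grades[f]}
            )
    imp = pd.DataFrame(imp_rows)
    _write_csv(imp, out / "importance.csv", art, index=False)
    (out / "baseline_metrics.json").write_text(json.dumps(metrics_rows, indent=2))
    art["baseline_metrics.json"] = _hash_text(json.dumps(metrics_rows, indent=2))
    manifest["metrics"]["importance_top_factor"] = {
        y: imp[imp.year == y].nlargest(1, "coefficient")["factor"].iloc[0]
        for y in years
    }
    manifest["stages"]["importance"] = "ok"

    # --- stage 5: gradient ---------------------------------------------------
    schemes = builtin_schemes()
    grad_rows = []
    corr_rows = []
    for year in years:
        stack = bundle.stacks[year]
        per_cell = esv_by_year[year].per_cell_total()
        for fname, scheme in schemes.items():
            grad_rows.append(
                esv_by_gradient(per_cell, stack.layers[fname], scheme, year=year)
            )
            corr_rows.append(
                {"year": year, "factor": fname,
                 "pearson_r": factor_correlation(stack.layers[fname], per_cell)}
            )
    _write_csv(pd.concat(grad_rows, ignore_index=True), out / "gradient.csv",
               art, index=False)
    _write_csv(pd.DataFrame(corr_rows), out / "correlations.csv", art, index=False)
    manifest["stages"]["gradient"] = "ok"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
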