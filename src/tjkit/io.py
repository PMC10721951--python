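"""Readers, writers and the pipeline runner.

TSV is the canonical on-disk dialect; CSV is accepted on read (delimiter
auto-detected from the header line).  Every pipeline run writes a
``manifest.json`` recording the exact parameters, seed, package version and
SHA-256 of each output, so identical config + seed reproduces identical
artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barrier import FluxAssay, FluxGeometry, ResistanceSet, compute_papp, compute_ter
from .electrophysiology import SolutionPair, summarize_runs
from .exceptions import ConfigurationError, DataError
from .gene_activity import (
    activity_threshold,
    build_density,
    classify_genes,
    fit_double_gaussian,
    log2_transform,
)
from .synthetic import (
    ExpressionSimConfig,
    PlateSimConfig,
    UssingSimConfig,
    simulate_expression_table,
    simulate_plate_assay,
    simulate_ussing_runs,
)

log = logging.getLogger("tjkit")

FLOAT_FORMAT = "%.10g"


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "," if header.count(",") > header.count("\t") else "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV table with a header row, auto-detecting the delimiter."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    return pd.read_csv(path, sep=_detect_sep(path))


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a gene expression table (gene_id, tpm, fpkm).

    Column names are matched case-insensitively.  Duplicate gene ids,
    missing columns and negative values are parse errors naming the
    offending row (1-based, counting the header as row 1).
    """
    df = read_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = {"gene_id", "tpm", "fpkm"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required column(s) {sorted(missing)}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise DataError(
            f"{path}: duplicate gene_id {df['gene_id'][dup].iloc[0]!r} at row {row}"
        )
    for col in ("tpm", "fpkm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
            raise DataError(f"{path}: non-numeric {col} at row {row}")
        if (vals < 0).any():
            row = int(np.flatnonzero((vals < 0).to_numpy())[0]) + 2
            raise DataError(f"{path}: negative {col} at row {row}")
        df[col] = vals.astype(float)
    return df[["gene_id", "tpm", "fpkm"] + [c for c in df.columns
                                            if c not in ("gene_id", "tpm", "fpkm")]]


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# pipeline stages

def run_activity_stage(table: pd.DataFrame, ratio: float, out_prefix: Path,
                       combine: str = "both") -> dict:
    """Fit both metrics, derive cutoffs, classify genes; write calls + fit JSON."""
    fits, thresholds = {}, {}
    for metric in ("tpm", "fpkm"):
        values, n_zero = log2_transform(table, metric)
        density = build_density(values, metric)
        fit = fit_double_gaussian(density)
        fits[metric] = {
            "n_excluded_zeros": n_zero,
            "active": {"amplitude": fit.active.amplitude, "mean": fit.active.mean,
                       "sd": fit.active.sd},
            "inactive": {"amplitude": fit.inactive.amplitude, "mean": fit.inactive.mean,
                         "sd": fit.inactive.sd},
            "residual_norm": fit.residual_norm,
        }
        thresholds[metric] = activity_threshold(fit, ratio=ratio)
        fits[metric]["cutoff_log2"] = thresholds[metric].cutoff_log2
        fits[metric]["ratio"] = ratio
    calls = classify_genes(table, thresholds["tpm"], thresholds["fpkm"], combine=combine)
    calls_path = write_table(calls, Path(f"{out_prefix}_calls.tsv"))
    fit_path = Path(f"{out_prefix}_fit.json")
    fit_path.write_text(json.dumps(fits, indent=2, sort_keys=True) + "\n")
    return {"calls": str(calls_path), "fit": str(fit_path)}


def run_ter_stage(plate: pd.DataFrame, area: float, out: Path) -> dict:
    rset = ResistanceSet(
        cell_resistances=plate.loc[plate["kind"] == "cell", "resistance_ohm"].to_numpy(),
        blank_resistances=plate.loc[plate["kind"] == "blank", "resistance_ohm"].to_numpy(),
        area=area,
    )
    res = compute_ter(rset)
    per_filter = plate.loc[plate["kind"] == "cell", ["filter_id"]].copy()
    per_filter["ter_ohm_cm2"] = res.ter
    per_filter["mean_ter_ohm_cm2"] = res.mean
    per_filter["sd_ter_ohm_cm2"] = res.sd
    return {"ter": str(write_table(per_filter, out))}


def run_flux_stage(flux: pd.DataFrame, geometry: FluxGeometry, calibration: float,
                   out: Path) -> dict:
    blank = float(flux.loc[flux["kind"] == "blank", "intensity_au"].mean())
    cells = flux[flux["kind"] == "cell"]
    assay = FluxAssay(
        sample_intensities=cells["intensity_au"].to_numpy(),
        blank_intensity=blank,
        calibration=calibration,
        geometry=geometry,
    )
    res = compute_papp(assay)
    per_filter = cells[["filter_id"]].copy()
    per_filter["papp_cm_s"] = res.papp
    per_filter["mean_papp_cm_s"] = res.mean
    per_filter["sd_papp_cm_s"] = res.sd
    return {"papp": str(write_table(per_filter, out))}


def run_ussing_stage(runs: pd.DataFrame, bath: SolutionPair, out: Path) -> dict:
    return {"ussing": str(write_table(summarize_runs(runs, bath), out))}


def _bath_from_config(cfg: dict) -> SolutionPair:
    return SolutionPair(
        na_apical=cfg.get("na_apical", 75.0),
        cl_apical=cfg.get("cl_apical", cfg.get("na_apical", 75.0)),
        na_basolateral=cfg.get("na_basolateral", 150.0),
        cl_basolateral=cfg.get("cl_basolateral", cfg.get("na_basolateral", 150.0)),
        temperature=cfg.get("temperature", 273.15 + cfg.get("temp_c", 37.0)),
    )


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages and write a run manifest.

    ``config`` maps stage names (``simulate``, ``activity``, ``ter``,
    ``flux``, ``ussing``) to their parameters; simulated tables feed the
    analysis stages when no input path is given.  All input paths are
    validated before any output is written, and every artifact lands in the
    manifest with its SHA-256.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    seed = int(config.get("seed", 0) if seed is None else seed)
    stages = {k: v for k, v in config.items() if k != "seed"}

    # validate all referenced inputs up front: abort before partial outputs
    for stage, cfg in stages.items():
        if isinstance(cfg, dict) and "input" in cfg and not Path(cfg["input"]).exists():
            raise DataError(f"stage {stage!r}: input file not found: {cfg['input']}")

    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    tables: dict[str, pd.DataFrame] = {}

    sim = stages.get("simulate", {}) or {}
    if "expression" in sim:
        cfg = ExpressionSimConfig(**{**sim["expression"], "seed": seed})
        tables["expression"] = simulate_expression_table(cfg)
        artifacts["sim_expression"] = str(write_table(tables["expression"],
                                                      outdir / "sim_expression.tsv"))
    if "ussing" in sim:
        ucfg = dict(sim["ussing"])
        if "bath" in ucfg:
            ucfg["bath"] = _bath_from_config(ucfg.pop("bath"))
        tables["ussing"] = simulate_ussing_runs(UssingSimConfig(**{**ucfg, "seed": seed}))
        artifacts["sim_ussing"] = str(write_table(tables["ussing"], outdir / "sim_ussing.tsv"))
    if "plate" in sim:
        pcfg = dict(sim["plate"])
        if "geometry" in pcfg:
            pcfg["geometry"] = FluxGeometry(**pcfg.pop("geometry"))
        resistance, flux = simulate_plate_assay(PlateSimConfig(**{**pcfg, "seed": seed}))
        tables["plate_resistance"], tables["plate_flux"] = resistance, flux
        artifacts["sim_resistance"] = str(write_table(resistance, outdir / "sim_resistance.tsv"))
        artifacts["sim_flux"] = str(write_table(flux, outdir / "sim_flux.tsv"))

    try:
        if "activity" in stages:
            cfg = stages["activity"] or {}
            log.info("stage activity: fitting double-Gaussian activity model")
            table = (read_expression_table(cfg["input"]) if "input" in cfg
                     else tables["expression"])
            artifacts.update(run_activity_stage(
                table, ratio=float(cfg.get("ratio", 5.0)), out_prefix=outdir / "activity",
                combine=cfg.get("combine", "both")))
        if "ter" in stages:
            cfg = stages["ter"] or {}
            log.info("stage ter: blank-corrected transepithelial resistance")
            plate = read_table(cfg["input"]) if "input" in cfg else tables["plate_resistance"]
            artifacts.update(run_ter_stage(plate, area=float(cfg.get("area", 1.12)),
                                           out=outdir / "ter.tsv"))
        if "flux" in stages:
            cfg = stages["flux"] or {}
            log.info("stage flux: apparent permeability")
            flux = read_table(cfg["input"]) if "input" in cfg else tables["plate_flux"]
            geometry = FluxGeometry(**cfg.get("geometry", {}))
            artifacts.update(run_flux_stage(flux, geometry,
                                            calibration=float(cfg.get("calibration", 1e10)),
                                            out=outdir / "papp.tsv"))
        if "ussing" in stages:
            cfg = stages["ussing"] or {}
            log.info("stage ussing: GHK inversion of dilution potentials")
            runs = read_table(cfg["input"]) if "input" in cfg else tables["ussing"]
            artifacts.update(run_ussing_stage(runs, _bath_from_config(cfg.get("bath", {})),
                                              out=outdir / "ussing.tsv"))
    except KeyError as exc:
        raise ConfigurationError(
            f"stage needs an 'input' path or a matching simulate entry ({exc})"
        ) from exc

    manifest = {
        "tjkit_version": __version__,
        "seed": seed,
        "config": config,
        "artifacts": {name: {"path": p, "sha256": sha256_file(p)}
                      for name, p in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
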