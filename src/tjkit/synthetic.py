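"""Seeded synthetic data with the statistical structure the analyses assume.

Three generators mirror the three measurement tracks:

* an expression table whose nonzero log2-TPM values are a two-Gaussian
  mixture of "active" (high-mean) and "inactive" (low-mean) genes plus an
  exactly-zero fraction, with an FPKM channel tied to TPM by a scale factor
  and small lognormal jitter;
* Ussing-chamber runs whose dilution potentials come from the GHK forward
  model at a known true P_Na/P_Cl, offset by a filter blank and Gaussian
  noise, with V/I pairs consistent with a set areal conductance;
* a Transwell plate with blank/cell resistances around a true TER and a
  fluorescein flux assay whose intensities follow a linear gain from the
  basal concentration implied by a true Papp.

With all noise terms at zero each generator is the exact inverse of its
analysis stage, so true parameters round-trip through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barrier import FluxGeometry
from .electrophysiology import DEFAULT_BATH, SolutionPair, ghk_dilution_potential
from .exceptions import ConfigurationError

__all__ = [
    "ExpressionSimConfig",
    "UssingSimConfig",
    "PlateSimConfig",
    "simulate_expression_table",
    "simulate_ussing_runs",
    "simulate_plate_assay",
]


def _require(cond: bool, field_name: str, msg: str):
    if not cond:
        raise ConfigurationError(f"{field_name}: {msg}")


@dataclass
class ExpressionSimConfig:
    """Two-component log2-expression mixture with an exact-zero fraction.

    Defaults emulate a bulk RNA-seq gene table: ~half of annotated genes
    transcriptionally active, active mode around log2-TPM 5, inactive mode
    near 0, unit spreads, and a fifth of genes with no reads at all.
    """

    n_genes: int = 20000
    active_fraction: float = 0.5
    mu_active: float = 5.0
    sd_active: float = 1.0
    mu_inactive: float = 0.0
    sd_inactive: float = 1.0
    zero_fraction: float = 0.2
    fpkm_scale: float = 1.5
    fpkm_jitter_sd: float = 0.02  # lognormal sigma tying FPKM to TPM
    seed: int = 0

    def __post_init__(self):
        _require(self.n_genes > 0, "n_genes", "must be a positive integer")
        _require(0 < self.active_fraction < 1, "active_fraction", "must be in (0, 1)")
        _require(self.sd_active > 0, "sd_active", "must be positive")
        _require(self.sd_inactive > 0, "sd_inactive", "must be positive")
        _require(self.mu_active > self.mu_inactive, "mu_active",
                 "must exceed mu_inactive (active = higher-mean component)")
        _require(0 <= self.zero_fraction < 1, "zero_fraction", "must be in [0, 1)")
        _require(self.fpkm_scale > 0, "fpkm_scale", "must be positive")
        _require(self.fpkm_jitter_sd >= 0, "fpkm_jitter_sd", "must be non-negative")


def simulate_expression_table(config: ExpressionSimConfig) -> pd.DataFrame:
    """Draw a gene table (gene_id, tpm, fpkm, truth_label) from the mixture.

    Each gene is independently zero with probability ``zero_fraction``;
    otherwise active with probability ``active_fraction`` and its log2-TPM
    drawn from the matching Gaussian.  FPKM = fpkm_scale * TPM * lognormal
    jitter, zero exactly where TPM is zero.  Identical seeds give identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    is_zero = rng.random(n) < config.zero_fraction
    is_active = rng.random(n) < config.active_fraction
    mu = np.where(is_active, config.mu_active, config.mu_inactive)
    sd = np.where(is_active, config.sd_active, config.sd_inactive)
    log2_tpm = rng.normal(mu, sd)
    tpm = np.where(is_zero, 0.0, 2.0**log2_tpm)
    jitter = np.exp(rng.normal(0.0, config.fpkm_jitter_sd, n)) if config.fpkm_jitter_sd else 1.0
    fpkm = np.where(is_zero, 0.0, config.fpkm_scale * tpm * jitter)
    label = np.where(is_zero, "zero", np.where(is_active, "active", "inactive"))
    width = len(str(n))
    return pd.DataFrame(
        {
            "gene_id": [f"gene{str(i).zfill(width)}" for i in range(n)],
            "tpm": tpm,
            "fpkm": fpkm,
            "truth_label": label,
        }
    )


@dataclass
class UssingSimConfig:
    """Dilution-potential replicates at a known true P_Na/P_Cl.

    The forward GHK model under ``bath`` gives the noise-free cell
    potential; a filter blank offset and additive Gaussian noise are
    applied, and each record carries a V/I pair consistent with
    ``conductance`` (mS/cm^2) over the chamber window ``area_cm2``.
    """

    true_ratio: float = 1.0
    conductance: float = 10.0
    potential_noise_sd: float = 0.2
    blank_potential: float = -0.3
    n_replicates: int = 4
    bath: SolutionPair = field(default_factory=lambda: DEFAULT_BATH)
    area_cm2: float = 0.0707  # 3-mm circular chamber window
    test_voltage_mV: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _require(self.true_ratio > 0, "true_ratio", "must be positive")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.conductance >= 0, "conductance", "must be non-negative")
        _require(self.potential_noise_sd >= 0, "potential_noise_sd", "must be non-negative")
        _require(self.area_cm2 > 0, "area_cm2", "must be positive")


def simulate_ussing_runs(config: UssingSimConfig) -> pd.DataFrame:
    """Simulate ``n_replicates`` cell records plus one blank record.

    Columns: record_id, kind ("cell"/"blank"), potential_mV, voltage_mV,
    current_uA, area_cm2.  Cell potential = GHK(true_ratio, bath) +
    blank_potential + N(0, potential_noise_sd); the blank record carries the
    blank potential alone (it is what the analysis subtracts).
    """
    rng = np.random.default_rng(config.seed)
    v_true = ghk_dilution_potential(config.true_ratio, config.bath)
    noise = rng.normal(0.0, config.potential_noise_sd, config.n_replicates) \
        if config.potential_noise_sd else np.zeros(config.n_replicates)
    current = config.conductance * config.area_cm2 * config.test_voltage_mV
    rows = [
        {
            "record_id": f"cell{i + 1}",
            "kind": "cell",
            "potential_mV": v_true + config.blank_potential + noise[i],
            "voltage_mV": config.test_voltage_mV,
            "current_uA": current,
            "area_cm2": config.area_cm2,
        }
        for i in range(config.n_replicates)
    ]
    rows.append(
        {
            "record_id": "blank",
            "kind": "blank",
            "potential_mV": config.blank_potential,
            "voltage_mV": config.test_voltage_mV,
            "current_uA": 0.0,
            "area_cm2": config.area_cm2,
        }
    )
    return pd.DataFrame(rows)


@dataclass
class PlateSimConfig:
    """A Transwell plate: resistance readings and a fluorescein flux assay.

    ``true_ter`` in Ohm cm^2 and ``true_papp`` in cm/s are the ground
    truths; ``fluorescence_gain`` converts basal concentration (mol/cm^3)
    to intensity units, with ``blank_intensity`` the tracer-free baseline.
    """

    true_ter: float = 300.0
    blank_resistance_mean: float = 110.0
    blank_resistance_sd: float = 2.0
    true_papp: float = 1e-6
    geometry: FluxGeometry = field(default_factory=FluxGeometry)
    fluorescence_gain: float = 1e10
    intensity_noise_sd: float = 1.0
    blank_intensity: float = 50.0
    n_filters: int = 3
    n_blanks: int = 3
    seed: int = 0

    def __post_init__(self):
        _require(self.true_ter >= 0, "true_ter", "must be non-negative")
        _require(self.true_papp >= 0, "true_papp", "must be non-negative")
        _require(self.blank_resistance_mean >= 0, "blank_resistance_mean", "must be non-negative")
        _require(self.blank_resistance_sd >= 0, "blank_resistance_sd", "must be non-negative")
        _require(self.fluorescence_gain > 0, "fluorescence_gain", "must be positive")
        _require(self.intensity_noise_sd >= 0, "intensity_noise_sd", "must be non-negative")
        _require(self.n_filters >= 1, "n_filters", "must be >= 1")
        _require(self.n_blanks >= 1, "n_blanks", "must be >= 1")


def simulate_plate_assay(config: PlateSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate resistance and flux tables for one plate.

    Resistance table: ``n_blanks`` blank rows ~ N(blank_mean, blank_sd) and
    ``n_filters`` cell rows at blank_mean + true_ter/area + same noise, so
    with zero noise blank subtraction recovers ``true_ter`` exactly.

    Flux table: transported amount dQ = true_papp * A * Co * dt per filter;
    intensity = blank + gain * dQ/basal_volume + noise, plus one blank row.
    """
    rng = np.random.default_rng(config.seed)
    geom = config.geometry

    def noise(n, sd):
        return rng.normal(0.0, sd, n) if sd else np.zeros(n)

    blanks = config.blank_resistance_mean + noise(config.n_blanks, config.blank_resistance_sd)
    cell_r = (
        config.blank_resistance_mean
        + config.true_ter / geom.area
        + noise(config.n_filters, config.blank_resistance_sd)
    )
    resistance = pd.DataFrame(
        {
            "filter_id": [f"blank{i + 1}" for i in range(config.n_blanks)]
            + [f"cell{i + 1}" for i in range(config.n_filters)],
            "kind": ["blank"] * config.n_blanks + ["cell"] * config.n_filters,
            "resistance_ohm": np.concatenate([blanks, cell_r]),
        }
    )

    dq = config.true_papp * geom.area * geom.initial_concentration * geom.duration
    basal_conc = dq / geom.basal_volume
    cell_int = (
        config.blank_intensity
        + config.fluorescence_gain * basal_conc
        + noise(config.n_filters, config.intensity_noise_sd)
    )
    flux = pd.DataFrame(
        {
            "filter_id": [f"cell{i + 1}" for i in range(config.n_filters)] + ["blank"],
            "kind": ["cell"] * config.n_filters + ["blank"],
            "intensity_au": np.concatenate([cell_int, [config.blank_intensity]]),
        }
    )
    return resistance, flux
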