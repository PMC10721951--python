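"""Transepithelial electrophysiology: conductance, dilution potentials and GHK inversion.

The central quantity is the Na+/Cl- permeability ratio of a monolayer's
paracellular pathway, estimated from the transepithelial potential that
develops when the apical NaCl bath is diluted to half the basolateral
concentration (150 -> 75 mM).  For a membrane permeable only to Na+ and Cl-
the Goldman-Hodgkin-Katz voltage equation gives

    V = (RT/F) * ln( (b * Na_ap + Cl_bl) / (b * Na_bl + Cl_ap) ),   b = P_Na / P_Cl

with the sign convention fixed operationally: upon apical dilution a
cation-selective epithelium (b > 1) shows a *negative* potential and an
anion-selective one (b < 1) a *positive* potential; b = 1 gives exactly 0 mV.
The expression is linear in ``b`` after exponentiating, so the inversion is
closed form.

A pore with no charge selectivity still passes Na+ and Cl- at their
free-solution mobility ratio (50.11 / 75.23 ~= 0.666), so selectivity is
classified against that neutral-pore baseline rather than against 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants as _const

from .exceptions import DataError, MeasurementError, OutOfRangeError

__all__ = [
    "SolutionPair",
    "PhysicalConstants",
    "IonMobilities",
    "PotentialRecord",
    "ConductanceRecord",
    "PermeabilityResult",
    "CODATA",
    "DEFAULT_BATH",
    "DEFAULT_MOBILITIES",
    "conductance_from_iv",
    "correct_blank",
    "ghk_dilution_potential",
    "pna_pcl_from_dilution",
    "nernst_limits_mv",
    "neutral_pore_ratio",
    "classify_selectivity",
    "summarize_runs",
]


@dataclass(frozen=True)
class SolutionPair:
    """NaCl bath composition on the two sides of the monolayer.

    Concentrations in mM; temperature in kelvin.  The default is the
    dilution-potential condition: 150 mM NaCl basolateral, 75 mM apical
    (osmotically balanced with mannitol, which carries no charge and is
    ignored), at 37 degrees C.
    """

    na_apical: float = 75.0
    cl_apical: float = 75.0
    na_basolateral: float = 150.0
    cl_basolateral: float = 150.0
    temperature: float = 310.15

    def __post_init__(self):
        for name in ("na_apical", "cl_apical", "na_basolateral", "cl_basolateral", "temperature"):
            if not getattr(self, name) > 0:
                raise DataError(f"SolutionPair.{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant R (J/mol/K) and Faraday constant F (C/mol), CODATA values."""

    gas_constant: float = _const.R
    faraday: float = _const.physical_constants["Faraday constant"][0]


CODATA = PhysicalConstants()
DEFAULT_BATH = SolutionPair()


@dataclass(frozen=True)
class IonMobilities:
    """Limiting molar ionic conductivities of Na+ and Cl- in water, S cm^2 eq^-1."""

    na_mobility: float = 50.11
    cl_mobility: float = 75.23

    def __post_init__(self):
        if self.na_mobility <= 0 or self.cl_mobility <= 0:
            raise DataError(
                f"ion mobilities must be positive, got na={self.na_mobility}, cl={self.cl_mobility}"
            )


DEFAULT_MOBILITIES = IonMobilities()


@dataclass(frozen=True)
class PotentialRecord:
    """A dilution-potential reading with its filter blank, both in mV."""

    raw_mV: float
    blank_mV: float
    corrected_mV: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "corrected_mV", self.raw_mV - self.blank_mV)


@dataclass(frozen=True)
class ConductanceRecord:
    voltage_mV: float
    current_uA: float
    area_cm2: float
    g_t: float  # mS/cm^2


@dataclass(frozen=True)
class PermeabilityResult:
    p_na_over_p_cl: float
    p_cl_over_p_na: float
    selectivity: str  # "cation" | "anion" | "neutral"
    corrected_potential_mV: float


def conductance_from_iv(voltage_mV: float, current_uA: float, area_cm2: float) -> ConductanceRecord:
    """Transepithelial conductance G_t from one open-circuit (V, I) pair via Ohm's law.

    With V in mV and I in uA, I/V is directly in mS; dividing by the exposed
    membrane area gives mS/cm^2.  Zero current means an open circuit
    (G_t = 0); nonzero current at zero voltage is a short and is rejected.
    """
    if area_cm2 <= 0:
        raise MeasurementError(f"area_cm2 must be positive, got {area_cm2}")
    if current_uA == 0:
        g = 0.0
    elif voltage_mV == 0:
        raise MeasurementError("nonzero current at zero voltage: short circuit")
    else:
        g = (current_uA / voltage_mV) / area_cm2
    return ConductanceRecord(voltage_mV, current_uA, area_cm2, g)


def correct_blank(raw_mV, blank_mV):
    """Subtract the cell-free filter potential from the measured potential.

    Scalars give a :class:`PotentialRecord`; array-likes are corrected
    element-wise and returned as an ndarray of the same length.
    """
    if np.isscalar(raw_mV) and np.isscalar(blank_mV):
        return PotentialRecord(float(raw_mV), float(blank_mV))
    raw = np.asarray(raw_mV, dtype=float)
    return raw - np.asarray(blank_mV, dtype=float)


def _thermal_voltage_mv(bath: SolutionPair, constants: PhysicalConstants) -> float:
    return 1000.0 * constants.gas_constant * bath.temperature / constants.faraday


def ghk_dilution_potential(
    p_ratio: float,
    bath: SolutionPair = DEFAULT_BATH,
    constants: PhysicalConstants = CODATA,
) -> float:
    """Forward GHK dilution potential (mV) for a given P_Na/P_Cl.

    Strictly decreasing in ``p_ratio`` when the apical side is the dilute
    one; 0 mV at p_ratio = 1 for a symmetric NaCl dilution, approaching the
    Na+ and Cl- Nernst potentials as p_ratio -> inf and -> 0.
    """
    if not p_ratio > 0:
        raise DataError(f"p_ratio must be positive, got {p_ratio}")
    vt = _thermal_voltage_mv(bath, constants)
    num = p_ratio * bath.na_apical + bath.cl_basolateral
    den = p_ratio * bath.na_basolateral + bath.cl_apical
    return vt * math.log(num / den)


def nernst_limits_mv(
    bath: SolutionPair = DEFAULT_BATH, constants: PhysicalConstants = CODATA
) -> tuple[float, float]:
    """Open interval (v_na, v_cl) of attainable dilution potentials in mV.

    v_na is the p_ratio -> inf limit (pure Na+ electrode) and v_cl the
    p_ratio -> 0 limit (pure Cl- electrode); every finite positive ratio
    maps strictly between them.
    """
    vt = _thermal_voltage_mv(bath, constants)
    v_na = vt * math.log(bath.na_apical / bath.na_basolateral)
    v_cl = vt * math.log(bath.cl_basolateral / bath.cl_apical)
    return v_na, v_cl


def neutral_pore_ratio(mobilities: IonMobilities = DEFAULT_MOBILITIES) -> float:
    """P_Na/P_Cl of a pore with no charge selectivity: the Na+/Cl- mobility ratio.

    With the tabulated free-solution mobilities (50.11 and 75.23 S cm^2/eq)
    this is ~0.666 — the baseline that separates cation- from
    anion-selective paracellular pores.
    """
    return mobilities.na_mobility / mobilities.cl_mobility


def pna_pcl_from_dilution(
    corrected_mV: float,
    bath: SolutionPair = DEFAULT_BATH,
    constants: PhysicalConstants = CODATA,
    mobilities: IonMobilities = DEFAULT_MOBILITIES,
    neutral_rtol: float = 1e-6,
) -> PermeabilityResult:
    """Invert the GHK dilution potential to P_Na/P_Cl (closed form).

    Exponentiating the forward expression makes it linear in the ratio:
    with u = exp(V F / R T),

        P_Na/P_Cl = (u * Cl_ap - Cl_bl) / (Na_ap - u * Na_bl)

    A potential at or beyond either Nernst limit has no positive solution
    and raises :class:`OutOfRangeError`.
    """
    v_na, v_cl = nernst_limits_mv(bath, constants)
    lo, hi = min(v_na, v_cl), max(v_na, v_cl)
    if not (lo < corrected_mV < hi):
        raise OutOfRangeError(
            f"corrected potential {corrected_mV:.4g} mV outside the attainable "
            f"open interval ({lo:.4g}, {hi:.4g}) mV; no positive P_Na/P_Cl exists"
        )
    vt = _thermal_voltage_mv(bath, constants)
    u = math.exp(corrected_mV / vt)
    ratio = (u * bath.cl_apical - bath.cl_basolateral) / (bath.na_apical - u * bath.na_basolateral)
    selectivity = classify_selectivity(ratio, mobilities, rtol=neutral_rtol)
    return PermeabilityResult(
        p_na_over_p_cl=ratio,
        p_cl_over_p_na=1.0 / ratio,
        selectivity=selectivity,
        corrected_potential_mV=float(corrected_mV),
    )


def classify_selectivity(
    result: "PermeabilityResult | float",
    mobilities: IonMobilities = DEFAULT_MOBILITIES,
    rtol: float = 1e-6,
) -> str:
    """Classify a P_Na/P_Cl ratio as cation-, anion- or non-selective.

    The boundary is the neutral-pore mobility ratio (~0.666), not 1:
    above it the pore favours Na+ beyond what free diffusion explains
    (cation-selective), below it Cl- (anion-selective).  Equality within
    ``rtol`` relative is "neutral".
    """
    ratio = result.p_na_over_p_cl if isinstance(result, PermeabilityResult) else float(result)
    baseline = neutral_pore_ratio(mobilities)
    if math.isclose(ratio, baseline, rel_tol=rtol):
        return "neutral"
    return "cation" if ratio > baseline else "anion"


def _group_stats(values: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD; SD is NaN (not 0) for n = 1 to avoid fake precision."""
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")
    return mean, sd


def summarize_runs(
    runs: pd.DataFrame,
    bath: SolutionPair = DEFAULT_BATH,
    constants: PhysicalConstants = CODATA,
    mobilities: IonMobilities = DEFAULT_MOBILITIES,
) -> pd.DataFrame:
    """Per-group mean +/- SD of corrected potential, P_Na/P_Cl and conductance.

    ``runs`` must hold columns ``kind`` ("cell"/"blank") and ``potential_mV``;
    optional ``group`` (defaults to a single group), ``voltage_mV`` /
    ``current_uA`` / ``area_cm2`` for conductance.  The mean blank potential
    (across all blank rows) is subtracted from every cell potential before
    the per-record GHK inversion; group selectivity is classified on the
    group's mean ratio.
    """
    df = runs.copy()
    if "group" not in df.columns:
        df["group"] = "all"
    blanks = df[df["kind"] == "blank"]["potential_mV"]
    blank_mean = float(blanks.mean()) if len(blanks) else 0.0
    cells = df[df["kind"] == "cell"]
    if cells.empty:
        raise DataError("no cell records to summarize")
    out = []
    for group, sub in cells.groupby("group", sort=True):
        if sub.empty:
            raise DataError(f"empty group {group!r}")
        corrected = sub["potential_mV"].to_numpy(dtype=float) - blank_mean
        ratios = np.array(
            [
                pna_pcl_from_dilution(v, bath, constants, mobilities).p_na_over_p_cl
                for v in corrected
            ]
        )
        mean_v, sd_v = _group_stats(corrected)
        mean_r, sd_r = _group_stats(ratios)
        row = {
            "group": group,
            "n": len(sub),
            "mean_corrected_mV": mean_v,
            "sd_corrected_mV": sd_v,
            "mean_pna_pcl": mean_r,
            "sd_pna_pcl": sd_r,
            "selectivity": classify_selectivity(mean_r, mobilities),
        }
        if {"voltage_mV", "current_uA", "area_cm2"}.issubset(sub.columns):
            gts = np.array(
                [
                    conductance_from_iv(v, i, a).g_t
                    for v, i, a in zip(sub["voltage_mV"], sub["current_uA"], sub["area_cm2"])
                ]
            )
            row["mean_gt_mS_cm2"], row["sd_gt_mS_cm2"] = _group_stats(gts)
        out.append(row)
    return pd.DataFrame(out)
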