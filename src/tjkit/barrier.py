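"""Transwell barrier assays: TER and apparent permeability (Papp).

TER (transepithelial electrical resistance, Ohm cm^2) is the cell-free
filter resistance subtracted from each cell-covered filter reading, times
the growth area.  Papp (cm/s) is the linear-regime apparent permeability of
a tracer dosed apically:

    Papp = (dQ/dt) / (A * Co)

where dQ is the amount of tracer (mol) reaching the basal chamber over the
incubation time dt (s), A the filter growth area (cm^2) and Co the initial
apical tracer concentration (mol/cm^3).  Fluorescence intensities are turned
into amounts through a single linear calibration gain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DataError

__all__ = [
    "ResistanceSet",
    "TERResult",
    "FluxGeometry",
    "FluxAssay",
    "PappResult",
    "compute_ter",
    "intensity_to_amount",
    "compute_papp",
]

#: Nominal growth area of a 12-mm Transwell insert, cm^2 (manufacturer value).
DEFAULT_GROWTH_AREA_CM2 = 1.12


@dataclass
class ResistanceSet:
    """Raw Millicell-type resistance readings (Ohm) plus the filter growth area."""

    cell_resistances: np.ndarray
    blank_resistances: np.ndarray
    area: float = DEFAULT_GROWTH_AREA_CM2

    def __post_init__(self):
        self.cell_resistances = np.atleast_1d(np.asarray(self.cell_resistances, dtype=float))
        self.blank_resistances = np.atleast_1d(np.asarray(self.blank_resistances, dtype=float))
        if self.area <= 0:
            raise ConfigurationError(f"area must be positive, got {self.area}")
        if self.blank_resistances.size < 1:
            raise DataError("at least one blank resistance reading is required")


@dataclass(frozen=True)
class TERResult:
    ter: np.ndarray  # per-filter, Ohm cm^2
    mean: float
    sd: float  # sample SD; NaN for a single filter
    negative_corrected: np.ndarray  # warning flags, per filter


@dataclass
class FluxGeometry:
    """Chamber geometry and dosing of the tracer-flux assay.

    Defaults mirror a standard 12-well Transwell fluorescein assay: 250 ul
    of 200 uM tracer apically, 1 ml basally, 2 h incubation.  Volumes are in
    ml (= cm^3); ``initial_concentration`` is Co in mol/cm^3 (200 uM ->
    2e-7 mol/cm^3); ``duration`` in seconds.
    """

    area: float = DEFAULT_GROWTH_AREA_CM2
    apical_volume: float = 0.25
    basal_volume: float = 1.0
    initial_concentration: float = 2e-7
    duration: float = 7200.0

    def __post_init__(self):
        for name in ("area", "apical_volume", "basal_volume", "initial_concentration", "duration"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(
                    f"FluxGeometry.{name} must be positive, got {getattr(self, name)}"
                )


@dataclass
class FluxAssay:
    """Per-filter fluorescence readings with blank and linear calibration.

    ``calibration`` converts basal-chamber concentration to intensity
    (intensity units per mol/cm^3); intensities below the blank clamp to
    zero transported amount with a warning.
    """

    sample_intensities: np.ndarray
    blank_intensity: float
    calibration: float
    geometry: FluxGeometry = field(default_factory=FluxGeometry)

    def __post_init__(self):
        self.sample_intensities = np.atleast_1d(np.asarray(self.sample_intensities, dtype=float))
        if self.calibration <= 0:
            raise ConfigurationError(f"calibration must be positive, got {self.calibration}")


@dataclass(frozen=True)
class PappResult:
    papp: np.ndarray  # per-filter, cm/s
    mean: float
    sd: float


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


def compute_ter(rset: ResistanceSet) -> TERResult:
    """Blank-corrected TER per filter: (R_cell - mean(R_blank)) * area.

    A reading below the mean blank yields a negative TER; it is kept (not
    clamped) but flagged and warned about, since it usually signals a leaky
    mount or an unstable electrode rather than a real epithelium.
    """
    if rset.cell_resistances.size == 0:
        raise DataError("no cell-filter resistance readings")
    blank_mean = float(np.mean(rset.blank_resistances))
    ter = (rset.cell_resistances - blank_mean) * rset.area
    negative = ter < 0
    if negative.any():
        warnings.warn(
            f"{int(negative.sum())} filter(s) have resistance below the mean blank "
            f"({blank_mean:.1f} Ohm); TER reported negative",
            stacklevel=2,
        )
    mean, sd = _mean_sd(ter)
    return TERResult(ter=ter, mean=mean, sd=sd, negative_corrected=negative)


def intensity_to_amount(assay: FluxAssay, intensity) -> np.ndarray | float:
    """Transported tracer amount dQ (mol) from a fluorescence reading.

    dQ = max(0, intensity - blank) / calibration * basal_volume: the
    blank-corrected intensity gives the basal concentration through the
    linear gain, and the basal volume converts it to an amount.
    """
    scalar = np.isscalar(intensity)
    inten = np.atleast_1d(np.asarray(intensity, dtype=float))
    corrected = inten - assay.blank_intensity
    if (corrected < 0).any():
        warnings.warn(
            "intensity below blank; clamping transported amount to zero", stacklevel=2
        )
        corrected = np.clip(corrected, 0.0, None)
    dq = corrected / assay.calibration * assay.geometry.basal_volume
    return float(dq[0]) if scalar else dq


def compute_papp(assay: FluxAssay) -> PappResult:
    """Apparent permeability per filter: Papp = (dQ/dt) / (A * Co), cm/s."""
    geom = assay.geometry
    dq = np.atleast_1d(intensity_to_amount(assay, assay.sample_intensities))
    papp = (dq / geom.duration) / (geom.area * geom.initial_concentration)
    mean, sd = _mean_sd(papp)
    return PappResult(papp=papp, mean=mean, sd=sd)
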