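"""Transcriptional activity calling from bulk RNA-seq expression tables.

The log2-transformed TPM (or FPKM) values of all nonzero genes form a
bimodal density: a low-expression mode of transcriptionally inactive genes
(spurious reads, background) and a high-expression mode of active genes.
Both modes are well approximated by Gaussians, so the binned density
(0.1-log2 bins) is fitted with a sum of two Gaussian curves

    f(x) = A_a exp(-(x - mu_a)^2 / 2 sigma_a^2) + A_i exp(-(x - mu_i)^2 / 2 sigma_i^2)

where the component with the larger mean is the *active* one.  A gene is
called active when its log2 expression exceeds the point x* where the active
curve is ``ratio`` times (default 5x) the inactive curve and stays above
that ratio for all higher expression; genes with exactly zero expression are
excluded from the fit and called "zero".

Amplitudes here are curve heights in gene-count units (the density's
y-axis), not normalized mixture weights: the ratio cutoff is defined on the
relative *rates* of active vs inactive genes at a given expression level,
which is exactly the ratio of the two fitted curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import DataError, FitError, ThresholdError

__all__ = [
    "LogDensity",
    "GaussianComponent",
    "DoubleGaussianFit",
    "ActivityThreshold",
    "log2_transform",
    "round_half_away",
    "build_density",
    "double_gaussian",
    "fit_double_gaussian",
    "activity_threshold",
    "classify_genes",
]

BIN_WIDTH = 0.1


@dataclass(frozen=True)
class LogDensity:
    """Binned density of log2 expression values at 0.1-log2 resolution.

    ``counts`` are integer tallies for observed data but may be real-valued
    for synthetic noise-free densities (exact curve evaluations on bins).
    """

    metric: str
    bin_centers: np.ndarray
    counts: np.ndarray
    n_excluded_zeros: int


@dataclass(frozen=True)
class GaussianComponent:
    amplitude: float  # curve height, gene-count units
    mean: float  # log2 expression
    sd: float  # log2 expression

    def __call__(self, x):
        return self.amplitude * np.exp(-((x - self.mean) ** 2) / (2.0 * self.sd**2))


@dataclass(frozen=True)
class DoubleGaussianFit:
    metric: str
    active: GaussianComponent
    inactive: GaussianComponent
    residual_norm: float
    converged: bool


@dataclass(frozen=True)
class ActivityThreshold:
    metric: str
    cutoff_log2: float
    ratio: float = 5.0


def _metric_column(metric: str) -> str:
    m = metric.lower()
    if m not in ("tpm", "fpkm"):
        raise DataError(f"metric must be 'tpm' or 'fpkm', got {metric!r}")
    return m


def log2_transform(table: pd.DataFrame, metric: str) -> tuple[np.ndarray, int]:
    """log2 of one expression column, excluding exact zeros (no pseudocount).

    Returns the log2 values of the nonzero genes and the number of excluded
    zeros; a negative expression value is a data error naming the gene.
    """
    col = _metric_column(metric)
    values = table[col].to_numpy(dtype=float)
    if (values < 0).any():
        bad = table.loc[values < 0, "gene_id"].iloc[0]
        raise DataError(f"negative {col.upper()} value for gene {bad!r}")
    nonzero = values[values > 0]
    return np.log2(nonzero), int((values == 0).sum())


def round_half_away(values, decimals: int = 1):
    """Round half away from zero (spreadsheet-style), not banker's rounding."""
    arr = np.asarray(values, dtype=float)
    scale = 10.0**decimals
    return np.sign(arr) * np.floor(np.abs(arr) * scale + 0.5) / scale


def build_density(values, metric: str = "tpm") -> LogDensity:
    """Tally log2 values rounded to one decimal into contiguous 0.1-wide bins.

    Bins span the rounded range with zero-count gaps filled; the counts sum
    to the number of input values.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise DataError("cannot build a density from an empty value list")
    # integer deci-units avoid float drift in bin identity
    deci = np.rint(np.sign(vals) * np.floor(np.abs(vals) * 10.0 + 0.5)).astype(np.int64)
    lo, hi = int(deci.min()), int(deci.max())
    grid = np.arange(lo, hi + 1)
    counts = np.bincount(deci - lo, minlength=grid.size)
    return LogDensity(
        metric=_metric_column(metric),
        bin_centers=grid / 10.0,
        counts=counts,
        n_excluded_zeros=0,
    )


def double_gaussian(x, a_a, mu_a, sd_a, a_i, mu_i, sd_i):
    """Sum of two unnormalized Gaussian curves."""
    x = np.asarray(x, dtype=float)
    return a_a * np.exp(-((x - mu_a) ** 2) / (2.0 * sd_a**2)) + a_i * np.exp(
        -((x - mu_i) ** 2) / (2.0 * sd_i**2)
    )


def _seed_means(centers: np.ndarray, counts: np.ndarray, min_separation: float = 1.0):
    """Deterministic initialization: two highest local maxima >= min_separation apart."""
    n = counts.size
    is_peak = np.zeros(n, dtype=bool)
    for i in range(n):
        left = counts[i - 1] if i > 0 else -np.inf
        right = counts[i + 1] if i < n - 1 else -np.inf
        if counts[i] > 0 and counts[i] >= left and counts[i] >= right and (
            counts[i] > left or counts[i] > right
        ):
            is_peak[i] = True
    peaks = np.flatnonzero(is_peak)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(counts))])
    order = peaks[np.argsort(counts[peaks], kind="stable")[::-1]]
    first = int(order[0])
    second = None
    for idx in order[1:]:
        if abs(centers[idx] - centers[first]) >= min_separation:
            second = int(idx)
            break
    if second is None:
        # no distinct second peak: seed at the highest bin far enough away,
        # falling back to the farthest bin for very narrow densities
        far = np.flatnonzero(np.abs(centers - centers[first]) >= min_separation)
        if far.size == 0:
            far = np.array([int(np.argmax(np.abs(centers - centers[first])))])
        second = int(far[np.argmax(counts[far])])
    return first, second


def fit_double_gaussian(density: LogDensity, min_sd: float = 1e-3) -> DoubleGaussianFit:
    """Unweighted nonlinear least squares of the double-Gaussian curve to bin counts.

    Initialization is deterministic (no random restarts): the two
    highest-count local maxima at least 1.0 log2 units apart seed the means,
    the bin counts there seed the amplitudes, and both sigmas start at 1.0.
    The fitted component with the larger mean is labeled *active*.

    Raises :class:`FitError` on non-convergence or a degenerate solution
    (a sigma collapsed to the bound or an amplitude indistinguishable from
    zero), carrying the fitted parameters as diagnostics.
    """
    centers = np.asarray(density.bin_centers, dtype=float)
    counts = np.asarray(density.counts, dtype=float)
    if np.count_nonzero(counts) < 6:
        raise DataError("density must have at least 6 non-empty bins for a 6-parameter fit")
    i_first, i_second = _seed_means(centers, counts)
    p0 = [
        max(counts[i_first], 1.0),
        centers[i_first],
        1.0,
        max(counts[i_second], 1.0),
        centers[i_second],
        1.0,
    ]
    span = centers[-1] - centers[0]
    lower = [0.0, centers[0] - span, min_sd, 0.0, centers[0] - span, min_sd]
    upper = [np.inf, centers[-1] + span, np.inf, np.inf, centers[-1] + span, np.inf]
    try:
        popt, _ = curve_fit(
            double_gaussian, centers, counts, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"double-Gaussian fit did not converge: {exc}", {"p0": p0}) from exc
    a1, mu1, sd1, a2, mu2, sd2 = (float(v) for v in popt)
    comp1, comp2 = GaussianComponent(a1, mu1, sd1), GaussianComponent(a2, mu2, sd2)
    active, inactive = (comp1, comp2) if comp1.mean > comp2.mean else (comp2, comp1)
    residual = float(np.linalg.norm(double_gaussian(centers, *popt) - counts))
    diagnostics = {"active": active, "inactive": inactive, "residual_norm": residual}
    total = max(counts.max(), 1.0)
    if active.sd <= min_sd * 1.01 or inactive.sd <= min_sd * 1.01:
        raise FitError("degenerate fit: a component sigma collapsed", diagnostics)
    if active.amplitude < 1e-6 * total or inactive.amplitude < 1e-6 * total:
        raise FitError("degenerate fit: a component amplitude is ~0 (unimodal density?)",
                       diagnostics)
    if active.mean - inactive.mean < BIN_WIDTH:
        raise FitError(
            "degenerate fit: component means collapsed within one bin width "
            "(unimodal density?)", diagnostics
        )
    return DoubleGaussianFit(
        metric=density.metric,
        active=active,
        inactive=inactive,
        residual_norm=residual,
        converged=True,
    )


def activity_threshold(fit: DoubleGaussianFit, ratio: float = 5.0) -> ActivityThreshold:
    """Expression cutoff x* where the active curve is ``ratio`` x the inactive curve.

    Solves A_a phi_a(x) = ratio * A_i phi_i(x); the log of the curve ratio
    is a quadratic in x, so the roots are closed form.  The returned root is
    the one beyond which the curve ratio stays >= ``ratio`` for all larger x
    within the support of the fitted mixture (means + 6 sd — beyond it both
    curves are numerically zero and their ratio meaningless); if no such
    root exists — the ratio never reaches ``ratio`` on the right, or
    exceeds it everywhere — a :class:`ThresholdError` is raised.
    """
    if not fit.converged:
        raise ThresholdError("threshold requires a converged fit")
    if not ratio > 0:
        raise ThresholdError(f"ratio must be positive, got {ratio}")
    act, ina = fit.active, fit.inactive
    # log curve-ratio L(x) = alpha x^2 + beta x + gamma, threshold at L(x) = 0
    alpha = 1.0 / (2.0 * ina.sd**2) - 1.0 / (2.0 * act.sd**2)
    beta = act.mean / act.sd**2 - ina.mean / ina.sd**2
    gamma = (
        math.log(act.amplitude / (ratio * ina.amplitude))
        - act.mean**2 / (2.0 * act.sd**2)
        + ina.mean**2 / (2.0 * ina.sd**2)
    )
    support_hi = max(act.mean + 6.0 * act.sd, ina.mean + 6.0 * ina.sd)
    if alpha == 0.0:
        # equal widths: L is linear with slope beta > 0 since mu_a > mu_i
        if beta <= 0:
            raise ThresholdError("curve ratio is non-increasing; no lower cutoff exists")
        root = -gamma / beta
    else:
        disc = beta**2 - 4.0 * alpha * gamma
        if disc < 0 and alpha > 0:
            raise ThresholdError(
                "curve ratio exceeds the requested ratio at every expression level"
            )
        if disc < 0:  # alpha < 0: ratio never reaches the target
            raise ThresholdError("curve ratio never reaches the requested ratio")
        sq = math.sqrt(disc)
        r_lo, r_hi = sorted(((-beta - sq) / (2.0 * alpha), (-beta + sq) / (2.0 * alpha)))
        if alpha > 0:
            # ratio >= target outside (r_lo, r_hi): the largest root is the cutoff
            root = r_hi
        else:
            # sigma_a < sigma_i: ratio >= target only on [r_lo, r_hi]; accept
            # r_lo if the drop back below the target lies beyond the support
            if r_hi < support_hi:
                raise ThresholdError(
                    "active component narrower than inactive: the curve ratio falls "
                    f"back below {ratio:g} at {r_hi:.3g}, inside the fitted support"
                )
            root = r_lo
    return ActivityThreshold(metric=fit.metric, cutoff_log2=float(root), ratio=float(ratio))


def classify_genes(
    table: pd.DataFrame,
    thr_tpm: ActivityThreshold,
    thr_fpkm: ActivityThreshold,
    combine: str = "both",
) -> pd.DataFrame:
    """Call every gene active/inactive/zero under the TPM and FPKM cutoffs.

    Per metric a gene is *active* iff its log2 value strictly exceeds the
    cutoff; exact zeros are called "zero".  The combined call is "active"
    when both metrics agree on active (``combine="both"``, the conservative
    default) or when either does (``combine="either"``); a zero in any
    metric makes the combined call "zero".
    """
    if thr_tpm.metric != "tpm" or thr_fpkm.metric != "fpkm":
        raise DataError(
            f"threshold metrics mismatched: got ({thr_tpm.metric!r}, {thr_fpkm.metric!r}), "
            "expected ('tpm', 'fpkm')"
        )
    if combine not in ("both", "either"):
        raise DataError(f"combine must be 'both' or 'either', got {combine!r}")

    out = pd.DataFrame({"gene_id": table["gene_id"].to_numpy()})
    calls = {}
    for metric, thr in (("tpm", thr_tpm), ("fpkm", thr_fpkm)):
        vals = table[metric].to_numpy(dtype=float)
        if (vals < 0).any():
            bad = table.loc[vals < 0, "gene_id"].iloc[0]
            raise DataError(f"negative {metric.upper()} value for gene {bad!r}")
        zero = vals == 0
        log2v = np.where(zero, np.nan, np.log2(np.where(zero, 1.0, vals)))
        call = np.where(zero, "zero", np.where(log2v > thr.cutoff_log2, "active", "inactive"))
        out[f"log2_{metric}"] = log2v
        out[f"call_{metric}"] = call
        calls[metric] = call
    any_zero = (calls["tpm"] == "zero") | (calls["fpkm"] == "zero")
    both_active = (calls["tpm"] == "active") & (calls["fpkm"] == "active")
    either_active = (calls["tpm"] == "active") | (calls["fpkm"] == "active")
    active = both_active if combine == "both" else either_active & ~any_zero
    out["call_combined"] = np.where(any_zero, "zero", np.where(active, "active", "inactive"))
    return out
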