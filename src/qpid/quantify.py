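"""Quantitative analysis: spectral deconvolution, dose/uptake ratios,
linearity fitting, decay correction and histogram width estimation.

A multi-isotope energy spectrum is modelled as a linear mixture
``S_i = sum_j A_j phi_ij`` of unit-normalized basis spectra phi_j with
activities A_j; the activities minimize the unweighted sum of squares
``chi^2 = sum_i (S_i - sum_j A_j phi_ij)^2`` subject to A_j >= 0, with
parabolic uncertainties from the quadratic form at the minimum.

Uptake comparisons use percent injected activity (%IA): bioequivalence
``B`` is the ratio of the therapeutic compound's %IA to the imaging
surrogate's, and the cross-instrument ratio ``R`` compares %IA between
two assay devices (the injected-activity factor cancels, so R is
identical computed from %IA or raw activities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from qpid.core_model import EnergySpectrum, ValidationError


# ---------------------------------------------------------------------------
# spectral deconvolution


def normalize_basis(spectrum: EnergySpectrum) -> EnergySpectrum:
    """Normalize a basis spectrum to unit sum (idempotent)."""
    total = spectrum.counts.sum()
    if total <= 0:
        raise ValidationError("cannot normalize an empty spectrum")
    return EnergySpectrum(
        bin_edges=spectrum.bin_edges.copy(),
        counts=spectrum.counts / total,
        normalized=True,
    )


@dataclass
class DeconvolutionProblem:
    """Data spectrum plus per-isotope basis spectra on shared binning."""

    data: EnergySpectrum
    bases: dict[str, EnergySpectrum]

    def __post_init__(self) -> None:
        for name, basis in list(self.bases.items()):
            if not np.array_equal(basis.bin_edges, self.data.bin_edges):
                raise ValidationError(
                    f"basis {name!r} binning differs from the data spectrum"
                )
            if not basis.normalized:
                self.bases[name] = normalize_basis(basis)


@dataclass
class DeconvolutionResult:
    activities: dict[str, float]
    uncertainties: dict[str, float]
    chi2: float
    condition_number: float


def deconvolve_activities(
    problem: DeconvolutionProblem,
    nonnegative: bool = True,
    max_condition: float = 1e8,
) -> DeconvolutionResult:
    """Fit isotope activities to a mixed spectrum by least squares.

    Minimizes the unweighted chi-square of the linear mixture model,
    constrained to A_j >= 0 by default (activities cannot be negative);
    ``nonnegative=False`` gives the plain normal-equations solution, which
    the constrained fit matches whenever that solution is non-negative.
    Parabolic 1-sigma uncertainties come from the quadratic form at the
    minimum with per-bin Poisson variances taken from the fitted model
    (the heteroscedasticity-consistent covariance of the unweighted
    least-squares estimator on counting data).
    """
    names = list(problem.bases)
    phi = np.column_stack([problem.bases[n].counts for n in names])
    s = problem.data.counts.astype(float)
    cond = float(np.linalg.cond(phi))
    if cond > max_condition:
        raise ValidationError(
            f"basis spectra are (near-)collinear: condition number {cond:.3g}"
        )
    if nonnegative:
        a, _ = optimize.nnls(phi, s)
    else:
        a, *_ = np.linalg.lstsq(phi, s, rcond=None)
    resid = s - phi @ a
    rss = float(resid @ resid)
    # sandwich covariance: bin variances = fitted Poisson means
    lam_hat = np.maximum(phi @ a, 0.0)
    gram_inv = np.linalg.inv(phi.T @ phi)
    cov = gram_inv @ (phi.T * lam_hat) @ phi @ gram_inv
    sigma = np.sqrt(np.diag(cov))
    return DeconvolutionResult(
        activities={n_: float(v) for n_, v in zip(names, a)},
        uncertainties={n_: float(u) for n_, u in zip(names, sigma)},
        chi2=rss,
        condition_number=cond,
    )


# ---------------------------------------------------------------------------
# uptake ratios


def percent_injected_activity(measured_bq: float, injected_bq: float) -> float:
    """%IA = 100 x measured / injected (both decay-corrected to the same
    reference time)."""
    if injected_bq <= 0:
        raise ValidationError("injected activity must be positive")
    return 100.0 * measured_bq / injected_bq


def bioequivalence(therapeutic_pct_ia: float, surrogate_pct_ia: float) -> float:
    """B = therapeutic %IA / imaging-surrogate %IA (dimensionless)."""
    if surrogate_pct_ia == 0:
        raise ValidationError("surrogate %IA must be non-zero")
    return therapeutic_pct_ia / surrogate_pct_ia


def qpid_microdose_ratio(qpid_value: float, microdose_value: float) -> float:
    """R = imager %IA / dose-calibrator %IA.

    The injected-activity factor cancels, so passing raw activities gives
    the identical ratio.
    """
    if microdose_value == 0:
        raise ValidationError("denominator measurement must be non-zero")
    return qpid_value / microdose_value


def decay_correct(activity_bq: float, elapsed_s: float, half_life_s: float) -> float:
    """Correct a measured activity back to the reference time:
    activity x 2^(elapsed / half-life)."""
    if half_life_s <= 0:
        raise ValidationError("half-life must be positive")
    return activity_bq * 2.0 ** (elapsed_s / half_life_s)


# ---------------------------------------------------------------------------
# linearity / efficiency fitting


@dataclass
class LinearityFit:
    """OLS fit of observed event rate against known activity."""

    slope: float
    intercept: float
    slope_err: float
    intercept_err: float
    residuals_pct: np.ndarray
    nonlinear: bool = field(default=False)  # any |residual| > 10%


def fit_linearity(
    pairs: Sequence[tuple[float, float]],
    linearity_criterion_pct: float = 10.0,
) -> LinearityFit:
    """Efficiency fit: rate = slope x activity + intercept.

    The slope is the detection efficiency (events/s per Bq).  Per-point
    residuals are reported as 100 x (observed - fit)/fit, with a flag when
    any |residual| exceeds the 10% linearity criterion.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise ValidationError("need at least two (activity, rate) points")
    activity, rate = pairs[:, 0], pairs[:, 1]
    if np.unique(activity).size < 2:
        raise ValidationError("need at least two distinct activity levels")
    design = np.column_stack([activity, np.ones_like(activity)])
    coef, rss_arr, *_ = np.linalg.lstsq(design, rate, rcond=None)
    slope, intercept = coef
    fitted = design @ coef
    resid = rate - fitted
    dof = max(len(rate) - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    with np.errstate(divide="ignore", invalid="ignore"):
        residuals_pct = 100.0 * resid / fitted
    return LinearityFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_err=float(np.sqrt(cov[0, 0])),
        intercept_err=float(np.sqrt(cov[1, 1])),
        residuals_pct=residuals_pct,
        nonlinear=bool(np.any(np.abs(residuals_pct) > linearity_criterion_pct)),
    )


# ---------------------------------------------------------------------------
# histogram widths


def hist_width(histogram: EnergySpectrum) -> tuple[float, float]:
    """(FWHM, FWTM) of a peaked histogram by linear interpolation.

    Widths are measured between the outermost crossings of half / tenth
    of the peak count over bin centers, so asymmetric and flat-topped
    shapes are handled (the plateau counts toward the width).
    """
    counts = histogram.counts
    if counts.max() <= 0:
        raise ValidationError("all-zero histogram: width undefined")
    centers = histogram.bin_centers
    return (
        _level_width(centers, counts, counts.max() / 2.0, histogram),
        _level_width(centers, counts, counts.max() / 10.0, histogram),
    )


def _level_width(
    centers: np.ndarray, counts: np.ndarray, level: float, hist: EnergySpectrum
) -> float:
    above = counts >= level
    idx = np.nonzero(above)[0]
    left_i, right_i = idx[0], idx[-1]
    if left_i == 0:
        left = hist.bin_edges[0]
    else:
        y0, y1 = counts[left_i - 1], counts[left_i]
        x0, x1 = centers[left_i - 1], centers[left_i]
        left = x0 + (level - y0) / (y1 - y0) * (x1 - x0)
    if right_i == len(counts) - 1:
        right = hist.bin_edges[-1]
    else:
        y0, y1 = counts[right_i], counts[right_i + 1]
        x0, x1 = centers[right_i], centers[right_i + 1]
        right = x0 + (level - y0) / (y1 - y0) * (x1 - x0)
    width = float(right - left)
    # single occupied bin: resolution floor is one bin width
    return max(width, 0.0)
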