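"""Energy calibration: ToT->keV, gamma pulse area->keV, and the secondary
alpha energy transformation.

The pixel detector's factory calibration maps the per-pixel
time-over-threshold measurement to deposited energy in keV; here a
surrogate affine map stands in (global, or per-pixel tables).  That
calibration under-reports alpha energies: the high linear energy transfer
saturates the sensor response, and the protective mylar film absorbs
1.5--2 MeV before the particle reaches the silicon.  A secondary,
monotone piecewise-linear transform -- fitted from peak positions
measured on the pixel detector against reference alpha-spectrometer line
energies -- corrects alpha-identified tracks back onto the reference
energy scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from qpid.core_model import EnergySpectrum, PixelHit, Track, ValidationError


@dataclass
class PixelCalibration:
    """Affine ToT->keV map: global ``(slope, intercept)`` or per-pixel arrays.

    ``slope`` / ``intercept`` may be scalars or 256x256 arrays indexed
    ``[row, col]``.  Slopes must be positive (monotone map).
    """

    slope: Union[float, np.ndarray] = 1.0
    intercept: Union[float, np.ndarray] = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.slope) <= 0):
            raise ValidationError("calibration slope must be positive")

    def energy_kev(self, col: int, row: int, tot: float) -> float:
        slope = self.slope if np.isscalar(self.slope) else self.slope[row, col]
        icpt = self.intercept if np.isscalar(self.intercept) else self.intercept[row, col]
        return float(slope * tot + icpt)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PixelCalibration":
        """Read 'col,row,slope,intercept' rows; a single 'global' row (col=row=-1)
        yields a global map."""
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if rows.shape[0] == 1 and rows[0, 0] < 0:
            return cls(slope=float(rows[0, 2]), intercept=float(rows[0, 3]))
        slope = np.full((256, 256), np.nan)
        icpt = np.full((256, 256), np.nan)
        for c, r, s, b in rows:
            slope[int(r), int(c)] = s
            icpt[int(r), int(c)] = b
        return cls(slope=slope, intercept=icpt)


def apply_pixel_energy_calibration(
    hits: Sequence[PixelHit],
    cal: PixelCalibration,
    allow_global_fallback: bool = True,
) -> list[PixelHit]:
    """Convert raw ToT hits to calibrated keV hits.

    Already-calibrated streams pass through unchanged (idempotence guard).
    With per-pixel tables, a pixel missing from the table is an error
    unless ``allow_global_fallback``, which substitutes the table median.
    """
    if all(h.calibrated for h in hits):
        import warnings

        warnings.warn("stream already calibrated; returning unchanged", stacklevel=2)
        return list(hits)
    per_pixel = not np.isscalar(cal.slope)
    if per_pixel:
        med_slope = float(np.nanmedian(cal.slope))
        med_icpt = float(np.nanmedian(np.asarray(cal.intercept, dtype=float)))
    out: list[PixelHit] = []
    for h in hits:
        if h.calibrated:
            out.append(h)
            continue
        if per_pixel and np.isnan(cal.slope[h.row, h.col]):
            if not allow_global_fallback:
                raise ValidationError(
                    f"pixel (col={h.col}, row={h.row}) missing from calibration table"
                )
            energy = med_slope * h.energy + med_icpt
        else:
            energy = cal.energy_kev(h.col, h.row, h.energy)
        out.append(PixelHit(col=h.col, row=h.row, toa=h.toa, energy=energy))
    return out


@dataclass
class AlphaTransform:
    """Monotone piecewise-linear map from measured to reference alpha energy.

    Interpolates linearly through the matched (measured, reference) peak
    pairs and extrapolates linearly with the end-segment slopes, so the
    transform is strictly increasing and invertible everywhere.
    """

    measured_kev: np.ndarray
    reference_kev: np.ndarray

    def __post_init__(self) -> None:
        self.measured_kev = np.asarray(self.measured_kev, dtype=float)
        self.reference_kev = np.asarray(self.reference_kev, dtype=float)
        if self.measured_kev.size != self.reference_kev.size:
            raise ValidationError("peak lists must have equal length")
        if self.measured_kev.size < 2:
            raise ValidationError("need at least 2 calibration peak pairs")
        if np.any(np.diff(self.measured_kev) <= 0) or np.any(
            np.diff(self.reference_kev) <= 0
        ):
            raise ValidationError(
                "peak pairs must be strictly increasing (transform must be invertible)"
            )

    def __call__(self, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        m, r = self.measured_kev, self.reference_kev
        out = np.interp(e, m, r)
        lo_slope = (r[1] - r[0]) / (m[1] - m[0])
        hi_slope = (r[-1] - r[-2]) / (m[-1] - m[-2])
        out = np.where(e < m[0], r[0] + lo_slope * (e - m[0]), out)
        out = np.where(e > m[-1], r[-1] + hi_slope * (e - m[-1]), out)
        return float(out) if np.isscalar(energy_kev) else out

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        lines = ["measured_kev,reference_kev"] + [
            f"{float(m)!r},{float(r)!r}"
            for m, r in zip(self.measured_kev, self.reference_kev)
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "AlphaTransform":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(measured_kev=rows[:, 0], reference_kev=rows[:, 1])


def fit_alpha_transform(
    measured_peaks_kev: Sequence[float],
    reference_peaks_kev: Sequence[float],
) -> AlphaTransform:
    """Build the alpha energy transform from matched peak pairs."""
    return AlphaTransform(
        measured_kev=np.asarray(measured_peaks_kev, dtype=float),
        reference_kev=np.asarray(reference_peaks_kev, dtype=float),
    )


def apply_alpha_transform(track: Track, transform: AlphaTransform) -> Track:
    """Correct an alpha-identified track's energy onto the reference scale.

    The transform is defined for alpha tracks only (identification runs on
    factory-calibrated energies first); applying it to a beta-labeled
    track is a contract violation.
    """
    if track.pid_label == "beta":
        raise ValidationError(
            "alpha energy transform must not be applied to beta tracks"
        )
    track.energy = float(transform(track.energy))
    return track


def find_spectrum_peaks(
    spectrum: EnergySpectrum,
    n_peaks: int,
    min_separation_kev: float = 200.0,
    centroid_halfwidth_kev: float = 300.0,
) -> np.ndarray:
    """Locate the ``n_peaks`` tallest well-separated peaks of a spectrum.

    Returns count-weighted centroid positions (keV), ascending.  Used to
    extract measured alpha line positions from simulated or acquired
    spectra when fitting the energy transform.
    """
    centers = spectrum.bin_centers
    counts = spectrum.counts.copy()
    found: list[float] = []
    for _ in range(n_peaks):
        if counts.max() <= 0:
            raise ValidationError("fewer peaks found than requested")
        i = int(np.argmax(counts))
        sel = np.abs(centers - centers[i]) <= centroid_halfwidth_kev
        found.append(float((centers[sel] * spectrum.counts[sel]).sum()
                           / spectrum.counts[sel].sum()))
        counts[np.abs(centers - centers[i]) <= min_separation_kev] = 0.0
    return np.sort(np.array(found))


def gamma_energy_from_pulse_area(pulse_area, constant: float):
    """Gamma energy (keV) = calibration constant x digitizer pulse area."""
    if constant <= 0:
        raise ValidationError("gamma calibration constant must be positive")
    area = np.asarray(pulse_area, dtype=float)
    out = constant * area
    return float(out) if np.isscalar(pulse_area) else out
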