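"""Image reconstruction, physical-unit conversion and measurement.

Four image flavours from the same track list (mode x scale):

* event map + activity: every member pixel += 1/N (N = track pixel count),
  so each track contributes exactly one count to the grid total;
* centroid + activity: the pixel containing the energy-weighted centroid
  += 1;
* event map + spectroscopic: every member pixel += its own hit energy;
* centroid + spectroscopic: the centroid pixel += the track energy.

Unnormalized grids conserve track count (activity) or total deposited
energy (spectroscopic) exactly.  Time normalization divides by the
acquisition time; spectroscopic images are additionally divided by the
pixel area and converted to MeV to give MeV/s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.measure import profile_line

from qpid.core_model import (
    GRID_SIZE,
    PIXEL_AREA_MM2,
    PIXEL_PITCH_UM,
    SpectralImage,
    Track,
    ValidationError,
)


@dataclass
class ROI:
    """A region of interest: a boolean pixel mask on the 256x256 grid."""

    mask: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (GRID_SIZE, GRID_SIZE):
            raise ValidationError("ROI mask must be 256x256")
        if not self.mask.any():
            raise ValidationError("ROI must be non-empty")

    @classmethod
    def from_polygon(
        cls, vertices: Sequence[tuple[float, float]], label: str = "custom"
    ) -> "ROI":
        """Build an ROI from (col, row) polygon vertices."""
        cols = np.array([v[0] for v in vertices])
        rows = np.array([v[1] for v in vertices])
        rr, cc = draw_polygon(rows, cols, shape=(GRID_SIZE, GRID_SIZE))
        mask = np.zeros((GRID_SIZE, GRID_SIZE), dtype=bool)
        mask[rr, cc] = True
        return cls(mask=mask, label=label)


def _centroid_pixel(track: Track) -> tuple[int, int]:
    # floor of the fractional coordinates; clip for centroids on the far edge
    col = min(int(np.floor(track.centroid[0])), GRID_SIZE - 1)
    row = min(int(np.floor(track.centroid[1])), GRID_SIZE - 1)
    return col, row


def reconstruct_image(
    tracks: Sequence[Track],
    mode: str,
    scale: str,
    acquisition_time: float,
    normalize: bool = True,
    dead_pixel_mask: Optional[np.ndarray] = None,
) -> SpectralImage:
    """Accumulate tracks into a 256x256 image (see module increment rules).

    With ``normalize`` the grid is divided by ``acquisition_time``
    (events/s/pixel) and, for spectroscopic scale, by the pixel area with
    keV -> MeV conversion (MeV/s/mm^2); otherwise raw counts / keV are
    returned.  Centroids landing on a dead pixel are moved to the nearest
    unmasked pixel.
    """
    if mode not in ("event_map", "centroid"):
        raise ValidationError(f"unknown mode {mode!r}")
    if scale not in ("activity", "spectroscopic"):
        raise ValidationError(f"unknown scale {scale!r}")
    if acquisition_time <= 0:
        raise ValidationError("acquisition time must be positive")

    grid = np.zeros((GRID_SIZE, GRID_SIZE))
    for track in tracks:
        if mode == "event_map":
            inv_n = 1.0 / track.n_pixels
            for h in track.hits:
                if dead_pixel_mask is not None and dead_pixel_mask[h.row, h.col]:
                    continue
                grid[h.row, h.col] += inv_n if scale == "activity" else h.energy
        else:
            col, row = _centroid_pixel(track)
            if dead_pixel_mask is not None and dead_pixel_mask[row, col]:
                col, row = _nearest_unmasked(col, row, dead_pixel_mask)
            grid[row, col] += 1.0 if scale == "activity" else track.energy

    if normalize:
        grid = grid / acquisition_time
        if scale == "spectroscopic":
            grid = grid / 1000.0 / PIXEL_AREA_MM2  # keV -> MeV, per mm^2
        units = "events/s/pixel" if scale == "activity" else "MeV/s/mm^2"
    else:
        units = "counts" if scale == "activity" else "keV"
    return SpectralImage(
        grid=grid,
        mode=mode,
        scale=scale,
        units=units,
        acquisition_time=acquisition_time,
    )


def _nearest_unmasked(col: int, row: int, mask: np.ndarray) -> tuple[int, int]:
    free_rows, free_cols = np.nonzero(~mask)
    if free_rows.size == 0:
        raise ValidationError("dead-pixel mask covers the whole grid")
    d2 = (free_cols - col) ** 2 + (free_rows - row) ** 2
    i = int(np.argmin(d2))
    return int(free_cols[i]), int(free_rows[i])


def to_activity_units(image: SpectralImage, calibration_factor: float) -> SpectralImage:
    """Scale a time-normalized activity image to Bq/pixel."""
    if image.scale != "activity":
        raise ValidationError("activity calibration applies to activity-scale images")
    return SpectralImage(
        grid=image.grid * calibration_factor,
        mode=image.mode,
        scale=image.scale,
        units="Bq/pixel",
        acquisition_time=image.acquisition_time,
        pixel_pitch=image.pixel_pitch,
    )


def to_cell_density(
    image: SpectralImage,
    specific_activity_bq_per_cell: float,
    thickness_um: float,
    pixel_pitch_um: float = PIXEL_PITCH_UM,
) -> np.ndarray:
    """Convert a Bq/pixel image to cells/uL.

    cells per pixel = activity / specific activity; density divides by the
    pixel volume (pitch^2 x section thickness).  E.g. a labeling specific
    activity of 17.6 kBq per 10^6 cells is 0.0176 Bq/cell.
    """
    if specific_activity_bq_per_cell <= 0:
        raise ValidationError("specific activity must be positive")
    if thickness_um <= 0:
        raise ValidationError("sample thickness must be positive")
    cells_per_pixel = image.grid / specific_activity_bq_per_cell
    pixel_volume_ul = (pixel_pitch_um * 1e-3) ** 2 * (thickness_um * 1e-3)  # mm^3 = uL
    return cells_per_pixel / pixel_volume_ul


def line_profile_fwhm(
    image: SpectralImage,
    start: tuple[float, float],
    end: tuple[float, float],
    width: int = 1,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Profile along a segment plus its FWHM in um.

    ``start`` / ``end`` are (col, row) pixel coordinates; ``width`` pixels
    are averaged perpendicular to the segment.  Returns (positions_um,
    profile, fwhm_um); the FWHM uses linear interpolation at half maximum
    (outermost crossings).  A flat profile has no defined width.
    """
    for col, row in (start, end):
        if not (0 <= col < GRID_SIZE and 0 <= row < GRID_SIZE):
            raise ValidationError("profile endpoints must lie inside the grid")
    prof = profile_line(
        image.grid,
        (start[1], start[0]),
        (end[1], end[0]),
        linewidth=width,
        mode="constant",
        cval=0.0,
    )
    positions_um = np.arange(prof.size) * image.pixel_pitch
    fwhm_px = _curve_width(np.arange(prof.size, dtype=float), prof, 0.5)
    return positions_um, prof, fwhm_px * image.pixel_pitch


def _curve_width(x: np.ndarray, y: np.ndarray, level_frac: float) -> float:
    """Width of a sampled curve at level_frac * max (outermost crossings)."""
    peak = y.max()
    if peak <= y.min():
        raise ValidationError("flat profile: width undefined")
    level = level_frac * peak
    above = y >= level
    idx = np.nonzero(above)[0]
    left_i, right_i = idx[0], idx[-1]
    if left_i == 0:
        left = x[0]
    else:
        x0, x1, y0, y1 = x[left_i - 1], x[left_i], y[left_i - 1], y[left_i]
        left = x0 + (level - y0) / (y1 - y0) * (x1 - x0)
    if right_i == len(y) - 1:
        right = x[-1]
    else:
        x0, x1, y0, y1 = x[right_i], x[right_i + 1], y[right_i], y[right_i + 1]
        right = x0 + (level - y0) / (y1 - y0) * (x1 - x0)
    return float(right - left)


def roi_statistics(
    image: SpectralImage,
    rois: Sequence[ROI],
    background_label: Optional[str] = "background",
) -> dict[str, dict[str, float]]:
    """Per-ROI pixel mean and standard error, optionally background-subtracted.

    When an ROI labelled ``background_label`` is present, its mean is
    subtracted from every other ROI's mean (reported as ``mean_bgsub``).
    Overlap between the background ROI and a target ROI triggers a warning.
    """
    import warnings

    stats: dict[str, dict[str, float]] = {}
    background_mean = None
    bg_roi = next((r for r in rois if r.label == background_label), None)
    for roi in rois:
        values = image.grid[roi.mask]
        mean = float(values.mean())
        sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
        stats[roi.label] = {"mean": mean, "sem": sem, "n_pixels": int(values.size)}
        if roi.label == background_label:
            background_mean = mean
        elif bg_roi is not None and np.any(roi.mask & bg_roi.mask):
            warnings.warn(
                f"ROI {roi.label!r} overlaps the background ROI", stacklevel=2
            )
    if background_mean is not None:
        for label, s in stats.items():
            if label != background_label:
                s["mean_bgsub"] = s["mean"] - background_mean
    return stats
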