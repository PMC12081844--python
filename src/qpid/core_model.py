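"""Domain types and list-mode / image I/O.

The detector produces two list-mode streams: per-pixel ionization hits
(pixel column/row, time of arrival, deposited energy) from the 256 x 256
silicon sensor, and gamma pulses (time, pulse area, energy) from the
scintillation detector.  The vendor binary formats are proprietary, so
this package defines a transparent tab-separated dialect (``#qpid-listmode
v1``) that every stage reads and writes.  Quantitative images are stored
as 32-bit float TIFF rasters with a JSON metadata sidecar; any log scaling
is display-only and never touches the quantitative file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import tifffile

GRID_SIZE = 256
PIXEL_PITCH_UM = 55.0
TIME_QUANTUM_NS = 1.5625
#: pixel area in mm^2: (55 um)^2
PIXEL_AREA_MM2 = (PIXEL_PITCH_UM * 1e-3) ** 2

LISTMODE_MAGIC = "#qpid-listmode v1"

PIXEL_COLUMNS = ("col", "row", "toa_ns", "energy_keV")
GAMMA_COLUMNS = ("time_ns", "pulse_area", "energy_keV")


class FormatError(ValueError):
    """Raised when a list-mode file does not conform to the v1 dialect."""


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


@dataclass(frozen=True)
class PixelHit:
    """One ionized-pixel record from the pixel-detector stream.

    Parameters
    ----------
    col, row:
        0-based pixel indices on the 256 x 256 grid.
    toa:
        Time of arrival in ns; the hardware quantizes to 1.5625 ns.
    energy:
        Deposited energy in keV once calibrated; raw time-over-threshold
        units are allowed pre-calibration with ``calibrated=False``.
    """

    col: int
    row: int
    toa: float
    energy: float
    calibrated: bool = True

    def validate(self) -> None:
        if not (0 <= self.col < GRID_SIZE and 0 <= self.row < GRID_SIZE):
            raise ValidationError(
                f"pixel index out of range: col={self.col}, row={self.row}"
            )
        if self.toa < 0:
            raise ValidationError(f"negative time of arrival: {self.toa}")
        if self.calibrated and not self.energy > 0:
            raise ValidationError(
                f"calibrated hit must have positive energy, got {self.energy}"
            )


@dataclass(frozen=True)
class GammaEvent:
    """One scintillator detection: time (ns), raw pulse area, energy (keV)."""

    time: float
    pulse_area: float
    energy: float = 0.0

    def validate(self) -> None:
        if self.time < 0:
            raise ValidationError(f"negative gamma time: {self.time}")
        if self.energy < 0:
            raise ValidationError(f"negative gamma energy: {self.energy}")


@dataclass
class Track:
    """An aggregated ionization cluster.

    ``energy`` is the sum of member-hit energies (keV), ``time`` the
    unweighted mean of member-hit times (ns) and ``centroid`` the
    energy-weighted centroid in fractional (col, row) pixel coordinates.
    ``coincident_gamma`` holds ``(gamma_energy_keV, delta_t_ns)`` once
    coincidence matching has tagged the track.
    """

    hits: tuple[PixelHit, ...]
    energy: float
    time: float
    centroid: tuple[float, float]
    n_pixels: int
    shape: Optional[tuple[float, float]] = None  # (elongation, fill_fraction)
    coincident_gamma: Optional[tuple[float, float]] = None
    pid_label: Literal["alpha", "beta", "unknown"] = "unknown"

    def positions(self) -> np.ndarray:
        """(n, 2) array of (col, row) member pixel indices."""
        return np.array([(h.col, h.row) for h in self.hits], dtype=float)

    def hit_energies(self) -> np.ndarray:
        return np.array([h.energy for h in self.hits], dtype=float)

    def hit_times(self) -> np.ndarray:
        return np.array([h.toa for h in self.hits], dtype=float)


@dataclass
class SpectralImage:
    """A 256 x 256 reconstructed image in one mode x scale combination.

    ``mode`` selects how a track deposits into the grid (every member pixel
    for ``event_map``, the single centroid pixel for ``centroid``);
    ``scale`` selects the deposited quantity (unit counts for ``activity``,
    energy for ``spectroscopic``).
    """

    grid: np.ndarray
    mode: Literal["event_map", "centroid"]
    scale: Literal["activity", "spectroscopic"]
    units: str
    acquisition_time: float
    pixel_pitch: float = PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_SIZE, GRID_SIZE):
            raise ValidationError(
                f"image grid must be {GRID_SIZE}x{GRID_SIZE}, got {self.grid.shape}"
            )
        if np.any(self.grid < 0):
            raise ValidationError("image grid values must be non-negative")


@dataclass
class EnergySpectrum:
    """A binned histogram: monotone bin edges plus non-negative counts.

    Used both for energy spectra (keV bins; deconvolution bases and data)
    and for timing histograms (ns bins) fed to width estimation.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValidationError(
                "counts length must be len(bin_edges) - 1 "
                f"({len(self.counts)} vs {len(self.bin_edges)})"
            )
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.normalized and abs(self.counts.sum() - 1.0) > 1e-9:
            raise ValidationError("normalized spectrum must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


Record = Union[PixelHit, GammaEvent]


# ---------------------------------------------------------------------------
# list-mode dialect


def _format_float(x: float) -> str:
    # repr round-trips doubles exactly, keeping write->read->write idempotent
    return repr(float(x))


def write_listmode(
    records: Sequence[Record],
    path: Union[str, Path],
    kind: Optional[Literal["pixel", "gamma"]] = None,
) -> Path:
    """Write records to a v1 list-mode file, validating each record.

    Byte output is deterministic for a given record sequence. ``kind`` is
    inferred from the first record when omitted; an empty sequence needs an
    explicit ``kind`` and produces a header-only file.
    """
    path = Path(path)
    if kind is None:
        if not records:
            raise ValueError("kind must be given for an empty record list")
        kind = "pixel" if isinstance(records[0], PixelHit) else "gamma"
    if kind not in ("pixel", "gamma"):
        raise ValueError(f"unknown stream kind: {kind!r}")

    lines = [LISTMODE_MAGIC, f"#kind {kind}"]
    if kind == "pixel":
        calibrated = all(r.calibrated for r in records)
        lines.append(f"#calibrated {'true' if calibrated else 'false'}")
        lines.append("\t".join(PIXEL_COLUMNS))
        for r in records:
            if not isinstance(r, PixelHit):
                raise ValidationError(f"expected PixelHit, got {type(r).__name__}")
            r.validate()
            lines.append(
                f"{r.col}\t{r.row}\t{_format_float(r.toa)}\t{_format_float(r.energy)}"
            )
    else:
        lines.append("\t".join(GAMMA_COLUMNS))
        for r in records:
            if not isinstance(r, GammaEvent):
                raise ValidationError(f"expected GammaEvent, got {type(r).__name__}")
            r.validate()
            lines.append(
                f"{_format_float(r.time)}\t{_format_float(r.pulse_area)}"
                f"\t{_format_float(r.energy)}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_listmode(
    path: Union[str, Path], kind: Literal["pixel", "gamma"]
) -> list[Record]:
    """Read a v1 list-mode file, returning records in file order.

    Raises :class:`FormatError` for a missing/unknown header or kind
    mismatch, and :class:`ValidationError` naming the offending line for
    malformed or out-of-range records.
    """
    path = Path(path)
    if kind not in ("pixel", "gamma"):
        raise ValueError(f"unknown stream kind: {kind!r}")
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first != LISTMODE_MAGIC:
            raise FormatError(
                f"{path}: missing or unknown list-mode header (got {first!r})"
            )
        kind_line = fh.readline().rstrip("\n")
        if not kind_line.startswith("#kind "):
            raise FormatError(f"{path}: missing '#kind' header line")
        file_kind = kind_line.split(" ", 1)[1].strip()
        if file_kind != kind:
            raise FormatError(
                f"{path}: file holds a {file_kind!r} stream, requested {kind!r}"
            )
        calibrated = True
        lineno = 2
        if kind == "pixel":
            cal_line = fh.readline().rstrip("\n")
            lineno += 1
            if not cal_line.startswith("#calibrated "):
                raise FormatError(f"{path}: missing '#calibrated' header line")
            calibrated = cal_line.split(" ", 1)[1].strip() == "true"
            expected_cols = "\t".join(PIXEL_COLUMNS)
        else:
            expected_cols = "\t".join(GAMMA_COLUMNS)
        header = fh.readline().rstrip("\n")
        lineno += 1
        if header != expected_cols:
            raise FormatError(f"{path}: unexpected column header {header!r}")

        records: list[Record] = []
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                if kind == "pixel":
                    if len(parts) != 4:
                        raise ValueError("expected 4 columns")
                    rec: Record = PixelHit(
                        col=int(parts[0]),
                        row=int(parts[1]),
                        toa=float(parts[2]),
                        energy=float(parts[3]),
                        calibrated=calibrated,
                    )
                else:
                    if len(parts) != 3:
                        raise ValueError("expected 3 columns")
                    rec = GammaEvent(
                        time=float(parts[0]),
                        pulse_area=float(parts[1]),
                        energy=float(parts[2]),
                    )
                rec.validate()
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc} (record {line!r})") from exc
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# images


def write_image(
    image: SpectralImage,
    path: Union[str, Path],
    display_log10: bool = False,
) -> Path:
    """Write a quantitative image as float32 TIFF plus a JSON sidecar.

    The quantitative raster is written losslessly (float32, no scaling).
    With ``display_log10`` an additional ``*_log10.tif`` rendering with
    ``log10(1 + value)`` scaling is emitted for visualization only.
    """
    path = Path(path)
    tifffile.imwrite(path, image.grid.astype(np.float32))
    sidecar = {
        "mode": image.mode,
        "scale": image.scale,
        "units": image.units,
        "acquisition_time_s": image.acquisition_time,
        "pixel_pitch_um": image.pixel_pitch,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    if display_log10:
        display = np.log10(1.0 + image.grid)
        tifffile.imwrite(
            path.with_name(path.stem + "_log10" + path.suffix),
            display.astype(np.float32),
        )
    return path


def read_image(path: Union[str, Path]) -> SpectralImage:
    path = Path(path)
    grid = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SpectralImage(
        grid=grid,
        mode=meta["mode"],
        scale=meta["scale"],
        units=meta["units"],
        acquisition_time=meta["acquisition_time_s"],
        pixel_pitch=meta.get("pixel_pitch_um", PIXEL_PITCH_UM),
    )


def log10_display(grid: np.ndarray) -> np.ndarray:
    """Display rendering: ``log10(1 + value)``; never used quantitatively."""
    return np.log10(1.0 + np.asarray(grid, dtype=float))


# ---------------------------------------------------------------------------
# spectra / profiles as CSV; dead-pixel masks


def write_spectrum(spectrum: EnergySpectrum, path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = ["bin_edge_lo,bin_edge_hi,count"]
    for lo, hi, c in zip(spectrum.bin_edges[:-1], spectrum.bin_edges[1:], spectrum.counts):
        lines.append(f"{_format_float(lo)},{_format_float(hi)},{_format_float(c)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_spectrum(path: Union[str, Path]) -> EnergySpectrum:
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    edges = np.concatenate([rows[:, 0], rows[-1:, 1]])
    counts = rows[:, 2]
    normalized = abs(counts.sum() - 1.0) <= 1e-9
    return EnergySpectrum(bin_edges=edges, counts=counts, normalized=normalized)


def load_dead_pixel_mask(path: Union[str, Path]) -> np.ndarray:
    """Read a dead-pixel list ('col,row' per line) into a 256x256 bool mask."""
    mask = np.zeros((GRID_SIZE, GRID_SIZE), dtype=bool)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        col_s, row_s = line.split(",")
        col, row = int(col_s), int(row_s)
        if not (0 <= col < GRID_SIZE and 0 <= row < GRID_SIZE):
            raise ValidationError(f"{path}:{lineno}: dead pixel out of range")
        mask[row, col] = True
    return mask
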