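"""Particle identification: classify tracks as alpha, beta or unknown.

Alphas deposit several MeV in compact circular blobs; betas deposit under
~1 MeV along linear, kinked random-walk chains.  Classification therefore
combines an energy rule (alpha >= 3 MeV, beta <= 1 MeV) with a
circle-versus-line topology test built from the energy-weighted
second-moment matrix (elongation) and the convex-hull fill fraction.
Positrons are indistinguishable from electrons by track shape alone; the
beta-plus filter instead requires a coincident annihilation gamma above
450 keV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from skimage.morphology import convex_hull_image

from qpid.core_model import Track, ValidationError


@dataclass
class PIDConfig:
    """Energy thresholds (keV) and circularity decision parameters."""

    beta_max_kev: float = 1000.0       # HET: betas have at most ~1 MeV
    alpha_min_kev: float = 3000.0      # alphas deposit at least ~3 MeV
    annihilation_gamma_min_kev: float = 450.0
    elongation_min: float = 0.6        # circular iff elongation AND fill pass
    fill_fraction_min: float = 0.6
    energy_window_kev: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (0 < self.beta_max_kev < self.alpha_min_kev):
            raise ValidationError(
                "need 0 < beta threshold < alpha threshold"
            )
        if self.annihilation_gamma_min_kev <= 0:
            raise ValidationError("gamma threshold must be positive")


def track_shape_metrics(track: Track) -> tuple[float, float]:
    """Topology metrics: (elongation in [0,1], fill fraction in (0,1]).

    Elongation is sqrt(lambda_minor / lambda_major) of the energy-weighted
    second-moment matrix of member pixel positions: 1 for circular blobs,
    near 0 for lines.  Fill fraction is n_pixels over the pixel count of
    the filled convex hull: jagged sparse chains score low, filled discs
    score ~1.  A single-pixel track is (1, 1) by convention.
    """
    if track.n_pixels == 1:
        track.shape = (1.0, 1.0)
        return track.shape
    pos = track.positions()
    w = track.hit_energies()
    w = w / w.sum()
    center = (w[:, None] * pos).sum(axis=0)
    d = pos - center
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
    eigvals = np.linalg.eigvalsh(cov)
    lam_minor, lam_major = max(eigvals[0], 0.0), max(eigvals[1], 0.0)
    elongation = float(np.sqrt(lam_minor / lam_major)) if lam_major > 0 else 1.0

    cols = pos[:, 0].astype(int)
    rows = pos[:, 1].astype(int)
    c0, r0 = cols.min(), rows.min()
    mask = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    mask[rows - r0, cols - c0] = True
    hull = convex_hull_image(mask)
    fill = float(mask.sum() / max(hull.sum(), mask.sum()))
    track.shape = (elongation, fill)
    return track.shape


def is_circular(track: Track, config: Optional[PIDConfig] = None) -> bool:
    config = config or PIDConfig()
    elongation, fill = track.shape if track.shape is not None else track_shape_metrics(track)
    return elongation >= config.elongation_min and fill >= config.fill_fraction_min


def classify_track(
    track: Track, config: Optional[PIDConfig] = None
) -> Literal["alpha", "beta", "unknown"]:
    """Label one track: alpha iff circular and >= 3 MeV; beta iff <= 1 MeV.

    The labels are mutually exclusive by construction (the thresholds do
    not overlap); anything in between, or energetic but non-circular, is
    unknown.  Runs on factory-calibrated energies, before the secondary
    alpha energy transform.
    """
    config = config or PIDConfig()
    if track.energy >= config.alpha_min_kev and is_circular(track, config):
        label = "alpha"
    elif track.energy <= config.beta_max_kev:
        label = "beta"
    else:
        label = "unknown"
    track.pid_label = label
    return label


def classify_tracks(
    tracks: Sequence[Track], config: Optional[PIDConfig] = None
) -> list[Track]:
    config = config or PIDConfig()
    for t in tracks:
        classify_track(t, config)
    return list(tracks)


def alpha_filter(
    tracks: Sequence[Track], config: Optional[PIDConfig] = None
) -> list[Track]:
    """Tracks passing the alpha PID rule (circular, energy >= 3 MeV)."""
    config = config or PIDConfig()
    return [t for t in tracks if classify_track(t, config) == "alpha"]


def beta_plus_filter(
    tracks: Sequence[Track], config: Optional[PIDConfig] = None
) -> list[Track]:
    """Positron selection: track energy <= 1 MeV AND a coincident gamma
    with energy >= 450 keV.

    Track shape is deliberately not consulted: electron and positron
    tracks are identical, only the annihilation gamma separates them.
    Coincidence matching must already have run.
    """
    config = config or PIDConfig()
    kept = []
    for t in tracks:
        if t.energy > config.beta_max_kev:
            continue
        if t.coincident_gamma is None:
            continue
        gamma_energy, _ = t.coincident_gamma
        if gamma_energy >= config.annihilation_gamma_min_kev:
            kept.append(t)
    return kept


def energy_window_filter(
    tracks: Sequence[Track], lo_kev: float, hi_kev: float
) -> list[Track]:
    """Tracks with lo <= energy <= hi (bounds inclusive).

    E.g. a 5--20 keV window selects the 12.7 keV Auger-electron tracks
    that give the sharpest images.
    """
    if lo_kev >= hi_kev:
        raise ValidationError("energy window needs lo < hi")
    return [t for t in tracks if lo_kev <= t.energy <= hi_kev]
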