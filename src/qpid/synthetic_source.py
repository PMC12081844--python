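"""Synthetic decay, detector-response and list-mode stream simulator.

Stands in for the hardware (pixelated silicon sensor + gamma scintillator)
so every downstream stage can be tested against known truth.  The
simulator emulates the statistical structure the pipeline assumes:

* Poisson decay times from planar point/lattice sources, with full decay
  chains walked promptly (daughters decay at the parent decay time);
* alpha tracks as compact filled discs (mean diameter > 400 um) with a
  radially decreasing energy profile, betas as self-avoiding random-walk
  pixel chains whose length grows with emission energy, Auger electrons
  as sub-pixel-range tracks;
* mylar-film absorption of 1.5--2 MeV per alpha and an optional
  saturation roll-off of measured alpha energy (the distortions the
  secondary alpha energy calibration must undo);
* per-hit arrival-time jitter from a right-skewed (Gaussian + exponential)
  distribution scaled to a target intra-track FWHM, quantized to the
  1.5625 ns sampling quantum;
* a gamma detector producing 511 keV annihilation events coincident with
  a configurable fraction of detected positrons, plus Poisson background
  singles.

This is a morphology/statistics surrogate, not particle transport; see
the package methods note for what it does and does not emulate.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import yaml
from scipy import optimize, stats

from qpid.core_model import (
    GRID_SIZE,
    PIXEL_PITCH_UM,
    TIME_QUANTUM_NS,
    GammaEvent,
    PixelHit,
    ValidationError,
    write_listmode,
)

DecayMode = Literal["alpha", "beta_minus", "beta_plus", "auger"]

_CHARGED_MODES = ("alpha", "beta_minus", "beta_plus", "auger")


# ---------------------------------------------------------------------------
# nuclide library


@functools.cache
def _nuclide_library() -> dict:
    text = resources.files("qpid.data").joinpath("nuclides.yaml").read_text()
    return yaml.safe_load(text)["nuclides"]


def half_life_s(nuclide: str) -> float:
    """Half-life in seconds from the bundled nuclide table."""
    entry = _nuclide_library().get(nuclide)
    if entry is None or "half_life_s" not in entry:
        raise KeyError(f"no half-life on record for {nuclide!r}")
    return float(entry["half_life_s"])


@dataclass(frozen=True)
class DecayBranch:
    """One decay branch: mode, branching fraction, emission energy model."""

    mode: DecayMode
    fraction: float
    daughter: str
    energy_kev: Optional[float] = None          # alpha / auger line
    beta_mean_kev: Optional[float] = None
    beta_endpoint_kev: Optional[float] = None


@dataclass
class NuclideChain:
    """A decay chain: mapping nuclide -> branches; empty branches = stable."""

    head: str
    nuclides: dict[str, tuple[DecayBranch, ...]]
    half_lives_s: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_library(cls, head: str) -> "NuclideChain":
        """Build the chain starting at ``head`` from the bundled table."""
        lib = _nuclide_library()
        if head not in lib:
            raise KeyError(f"unknown nuclide {head!r}")
        nuclides: dict[str, tuple[DecayBranch, ...]] = {}
        half_lives: dict[str, float] = {}
        frontier = [head]
        while frontier:
            name = frontier.pop()
            if name in nuclides:
                continue
            entry = lib.get(name)
            if entry is None:
                raise KeyError(f"chain references unknown nuclide {name!r}")
            if "half_life_s" in entry:
                half_lives[name] = float(entry["half_life_s"])
            if entry.get("stable"):
                nuclides[name] = ()
                continue
            branches = tuple(
                DecayBranch(
                    mode=b["mode"],
                    fraction=float(b["fraction"]),
                    daughter=b["daughter"],
                    energy_kev=b.get("energy_kev"),
                    beta_mean_kev=b.get("beta_mean_kev"),
                    beta_endpoint_kev=b.get("beta_endpoint_kev"),
                )
                for b in entry["branches"]
            )
            nuclides[name] = branches
            frontier.extend(b.daughter for b in branches)
        chain = cls(head=head, nuclides=nuclides, half_lives_s=half_lives)
        chain.validate()
        return chain

    def validate(self) -> None:
        for name, branches in self.nuclides.items():
            if branches and abs(sum(b.fraction for b in branches) - 1.0) > 1e-9:
                raise ValidationError(
                    f"branch fractions of {name!r} must sum to 1"
                )
        # cycle check / termination via DFS
        state: dict[str, int] = {}

        def visit(name: str) -> None:
            if state.get(name) == 1:
                raise ValidationError(f"decay chain has a cycle through {name!r}")
            if state.get(name) == 2:
                return
            state[name] = 1
            for b in self.nuclides.get(name, ()):
                if b.daughter not in self.nuclides:
                    raise ValidationError(f"missing daughter {b.daughter!r}")
                visit(b.daughter)
            state[name] = 2

        visit(self.head)


def chain_emission_counts(chain: NuclideChain) -> tuple[float, float, float]:
    """Expected charged emissions (alpha, beta-, beta+) per head decay.

    Walks the chain from head to stability, weighting by branch fraction;
    with all fractions 1 the counts are exact integers (4 alpha + 2 beta-
    for Ra-223, a single beta+ for F-18).
    """
    chain.validate()
    memo: dict[str, np.ndarray] = {}

    def counts(name: str) -> np.ndarray:
        if name in memo:
            return memo[name]
        total = np.zeros(3)
        for b in self_branches(name):
            own = np.zeros(3)
            if b.mode == "alpha":
                own[0] = 1.0
            elif b.mode in ("beta_minus", "auger"):
                # Auger K electrons are beta-like negative emissions
                own[1] = 1.0
            elif b.mode == "beta_plus":
                own[2] = 1.0
            total += b.fraction * (own + counts(b.daughter))
        memo[name] = total
        return total

    def self_branches(name: str) -> tuple[DecayBranch, ...]:
        return chain.nuclides.get(name, ())

    n_alpha, n_beta_minus, n_beta_plus = counts(chain.head)
    return float(n_alpha), float(n_beta_minus), float(n_beta_plus)


# ---------------------------------------------------------------------------
# scene and detector configuration


@dataclass(frozen=True)
class PointSource:
    """A planar point drop of one nuclide (activity in Bq at pixel x, y)."""

    nuclide: str
    activity_bq: float
    x: float
    y: float


@dataclass
class SourceScene:
    """The simulated sample: planar activity plus acquisition conditions."""

    sources: list[PointSource]
    duration_s: float
    thickness_um: float = 10.0
    #: alpha energy lost to the protective mylar film, uniform draw (keV)
    mylar_loss_kev: tuple[float, float] = (1500.0, 2000.0)
    #: prompt approximation: daughters decay at the parent decay time.
    #: False samples explicit exponential daughter lifetimes (ingrowth mode);
    #: emissions falling past the acquisition end are then dropped.
    prompt_chain: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("acquisition duration must be positive")
        if self.thickness_um <= 0:
            raise ValidationError("sample thickness must be positive")
        for s in self.sources:
            if s.activity_bq < 0:
                raise ValidationError("activities must be non-negative")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SourceScene":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            sources=[PointSource(**s) for s in cfg["sources"]],
            duration_s=float(cfg["duration_s"]),
            thickness_um=float(cfg.get("thickness_um", 10.0)),
            mylar_loss_kev=tuple(cfg.get("mylar_loss_kev", (1500.0, 2000.0))),
            seed=int(cfg.get("seed", 0)),
        )


@dataclass
class DetectorModel:
    """Detector-response parameters (defaults match the measured device).

    ``intra_track_fwhm_ns`` and ``ctr_fwhm_ns`` are targets: the per-hit
    jitter scale and the gamma coincidence-time jitter are derived from
    them analytically.  ``gamma_coincidence_prob`` is the probability that
    a detected positron track has its annihilation gamma recorded (the
    measured coincident-method efficiency, 2.3%).
    """

    pixel_pitch_um: float = PIXEL_PITCH_UM
    grid_size: int = GRID_SIZE
    time_quantum_ns: float = TIME_QUANTUM_NS
    intra_track_fwhm_ns: float = 7.7
    alpha_diameter_mean_um: float = 450.0
    alpha_diameter_sd_um: float = 40.0
    beta_range_k: float = 0.21
    beta_range_p: float = 0.77
    gamma_coincidence_prob: float = 0.023
    ctr_fwhm_ns: float = 24.2
    gamma_background_rate_bq: float = 0.0
    gamma_background_energy_kev: tuple[float, float] = (50.0, 1500.0)
    gamma_energy_resolution: float = 0.04      # fractional sigma at 511 keV
    gamma_threshold_kev: float = 0.0
    gamma_pulse_area_per_kev: float = 4.0      # digitizer units per keV
    #: measured alpha energy saturation: identity below the knee, slope < 1
    #: above it (continuous); the secondary alpha calibration must undo this
    alpha_sat_knee_kev: float = 3000.0
    alpha_sat_slope: float = 0.8
    alpha_saturation_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_coincidence_prob <= 1.0:
            raise ValidationError("coincidence probability must be in [0, 1]")
        for name in ("intra_track_fwhm_ns", "ctr_fwhm_ns",
                     "alpha_diameter_mean_um", "beta_range_k", "beta_range_p"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def saturate_alpha_energy(self, energy_kev: float) -> float:
        """Measured (saturated) energy for a true absorbed alpha energy."""
        if not self.alpha_saturation_enabled or energy_kev <= self.alpha_sat_knee_kev:
            return energy_kev
        a, knee = self.alpha_sat_slope, self.alpha_sat_knee_kev
        return a * energy_kev + (1.0 - a) * knee


@dataclass(frozen=True)
class Emission:
    """One charged emission reaching the detector plane."""

    nuclide: str
    mode: DecayMode
    energy_kev: float            # post-mylar for alphas
    emitted_kev: float           # line / sampled energy before absorption
    x: float
    y: float
    time_ns: float


# ---------------------------------------------------------------------------
# timing jitter: exponentially-modified Gaussian scaled to a target FWHM


@functools.cache
def _unit_emg_fwhm() -> float:
    """FWHM of N(0,1) + Exp(1) (exponnorm with K = 1), computed once."""
    dist = stats.exponnorm(K=1.0)
    mode = optimize.minimize_scalar(
        lambda x: -dist.pdf(x), bounds=(-3.0, 5.0), method="bounded"
    ).x
    half = dist.pdf(mode) / 2.0
    left = optimize.brentq(lambda x: dist.pdf(x) - half, mode - 20.0, mode)
    right = optimize.brentq(lambda x: dist.pdf(x) - half, mode, mode + 40.0)
    return right - left


def _sample_hit_jitter(rng: np.random.Generator, n: int, target_fwhm_ns: float) -> np.ndarray:
    """Right-skewed per-hit time jitter with the configured FWHM."""
    s = target_fwhm_ns / _unit_emg_fwhm()
    return s * (rng.normal(0.0, 1.0, n) + rng.exponential(1.0, n))


def quantize_time(t_ns: np.ndarray, quantum: float = TIME_QUANTUM_NS) -> np.ndarray:
    return np.round(np.asarray(t_ns) / quantum) * quantum


# ---------------------------------------------------------------------------
# decay sampling


def _sample_beta_energy(
    rng: np.random.Generator, mean_kev: float, endpoint_kev: float
) -> float:
    """Beta-spectrum surrogate: endpoint-scaled Beta(2, b) matching the mean."""
    m = mean_kev / endpoint_kev
    b = 2.0 * (1.0 - m) / m
    return endpoint_kev * rng.beta(2.0, b)


def sample_decays(
    scene: SourceScene,
    chain: NuclideChain,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[Emission]:
    """Sample decays from every scene source headed by this chain.

    Decay times are Poisson with the source activity (uniform over the
    acquisition); each decay walks the chain promptly, emitting the full
    charged cascade at the decay time.  Alpha energies are reduced by the
    mylar absorption draw before detection.
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed if seed is None else seed)
    chain.validate()
    emissions: list[Emission] = []
    lo, hi = scene.mylar_loss_kev
    for src in scene.sources:
        if src.nuclide != chain.head or src.activity_bq == 0:
            continue
        n_decays = rng.poisson(src.activity_bq * scene.duration_s)
        times_ns = np.sort(rng.uniform(0.0, scene.duration_s * 1e9, n_decays))
        end_ns = scene.duration_s * 1e9
        for t0 in times_ns:
            name = chain.head
            t = float(t0)
            while True:
                branches = chain.nuclides[name]
                if not branches:
                    break
                if not scene.prompt_chain and name != chain.head:
                    # daughter waits out its own exponential lifetime
                    t12 = chain.half_lives_s.get(name)
                    if t12 is not None:
                        t = t + rng.exponential(t12 / np.log(2.0)) * 1e9
                if t > end_ns:
                    break  # decays after the acquisition window are unseen
                fractions = [b.fraction for b in branches]
                branch = branches[rng.choice(len(branches), p=fractions)]
                if branch.mode == "alpha":
                    emitted = float(branch.energy_kev)
                    detected = max(emitted - rng.uniform(lo, hi), 0.0)
                elif branch.mode == "auger":
                    emitted = detected = float(branch.energy_kev)
                else:
                    emitted = detected = _sample_beta_energy(
                        rng, branch.beta_mean_kev, branch.beta_endpoint_kev
                    )
                emissions.append(
                    Emission(
                        nuclide=name,
                        mode=branch.mode,
                        energy_kev=detected,
                        emitted_kev=emitted,
                        x=src.x,
                        y=src.y,
                        time_ns=float(t),
                    )
                )
                name = branch.daughter
    emissions.sort(key=lambda e: e.time_ns)
    return emissions


def geometric_acceptance_fraction(
    n_samples: int,
    seed: Optional[int] = None,
    sensorward_only: bool = False,
) -> float:
    """Fraction of isotropic emission directions entering the sensor.

    For a source resting on the sensor plane, directions with a negative
    component along the outward surface normal enter the sensor-side
    hemisphere; the fraction converges to the 2-pi solid-angle acceptance
    of 0.5.  ``sensorward_only`` forces every direction sensor-ward (1.0).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sensorward_only:
        return 1.0
    rng = np.random.default_rng(seed)
    cos_theta = rng.uniform(-1.0, 1.0, n_samples)
    return float(np.mean(cos_theta < 0.0))


# ---------------------------------------------------------------------------
# track / gamma rendering

_DIRECTIONS = np.array(
    [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
)


def beta_path_length(energy_kev: float, detector: DetectorModel) -> int:
    """Pixel path length surrogate L(E) = round(k * E^p), at least 1."""
    return max(1, int(round(detector.beta_range_k * energy_kev ** detector.beta_range_p)))


def _alpha_disc_pixels(
    emission: Emission, detector: DetectorModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filled-disc pixels with a truncated-Gaussian radial energy profile."""
    pitch = detector.pixel_pitch_um
    diameter = rng.normal(detector.alpha_diameter_mean_um, detector.alpha_diameter_sd_um)
    diameter = max(diameter, 3.0 * pitch)
    radius_px = diameter / (2.0 * pitch)
    cx, cy = emission.x, emission.y
    lo_c = max(int(np.floor(cx - radius_px)), 0)
    hi_c = min(int(np.ceil(cx + radius_px)), detector.grid_size - 1)
    lo_r = max(int(np.floor(cy - radius_px)), 0)
    hi_r = min(int(np.ceil(cy + radius_px)), detector.grid_size - 1)
    cols, rows = np.meshgrid(
        np.arange(lo_c, hi_c + 1), np.arange(lo_r, hi_r + 1), indexing="ij"
    )
    cols, rows = cols.ravel(), rows.ravel()
    r2 = (cols - cx) ** 2 + (rows - cy) ** 2
    inside = r2 <= radius_px**2
    cols, rows, r2 = cols[inside], rows[inside], r2[inside]
    sigma = radius_px / 2.0
    weights = np.exp(-r2 / (2.0 * sigma**2))
    return cols, rows, weights


def _beta_walk_pixels(
    emission: Emission, detector: DetectorModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Self-avoiding persistent random walk; length grows with energy."""
    n_target = beta_path_length(emission.energy_kev, detector)
    g = detector.grid_size
    col = min(max(int(round(emission.x)), 0), g - 1)
    row = min(max(int(round(emission.y)), 0), g - 1)
    visited = {(col, row)}
    cols, rows = [col], [row]
    direction = rng.integers(0, 8)
    while len(cols) < n_target:
        # persistence: usually keep heading, sometimes kink by +-45 degrees
        turn = rng.choice([0, 1, -1], p=[0.7, 0.15, 0.15])
        candidates = [direction + turn] + list(rng.permutation(8))
        for d in candidates:
            d %= 8
            dc, dr = _DIRECTIONS[d]
            nxt = (col + int(dc), row + int(dr))
            if nxt in visited or not (0 <= nxt[0] < g and 0 <= nxt[1] < g):
                continue
            direction = d
            col, row = nxt
            visited.add(nxt)
            cols.append(col)
            rows.append(row)
            break
        else:
            break  # walk boxed itself in; stop early
    n = len(cols)
    weights = rng.dirichlet(np.full(n, 5.0)) if n > 1 else np.ones(1)
    return np.array(cols), np.array(rows), weights


def render_track_hits(
    emission: Emission,
    detector: DetectorModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[PixelHit]:
    """Render one accepted emission into pixel hits.

    Alphas become filled discs (diameter sampled from the detector model,
    radially decreasing energy profile); betas and Auger electrons become
    self-avoiding random-walk chains.  Pixel energies sum exactly to the
    measured emission energy; hit times are the emission time plus
    right-skewed jitter, quantized to the sampling quantum.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if emission.mode == "alpha":
        measured = detector.saturate_alpha_energy(emission.energy_kev)
        cols, rows, weights = _alpha_disc_pixels(emission, detector, rng)
    else:
        measured = emission.energy_kev
        cols, rows, weights = _beta_walk_pixels(emission, detector, rng)
    energies = measured * weights / weights.sum()
    jitter = _sample_hit_jitter(rng, len(cols), detector.intra_track_fwhm_ns)
    times = quantize_time(
        np.maximum(emission.time_ns + jitter, 0.0), detector.time_quantum_ns
    )
    return [
        PixelHit(col=int(c), row=int(r), toa=float(t), energy=float(e))
        for c, r, t, e in zip(cols, rows, times, energies)
    ]


def render_gamma_stream(
    emissions: Sequence[Emission],
    detector: DetectorModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    duration_s: Optional[float] = None,
) -> list[GammaEvent]:
    """Gamma list-mode stream: coincident 511 keV events plus background.

    Each positron emission yields, with the configured coincidence
    detection probability, a 511 keV event (energy smeared by the detector
    resolution) at the emission time plus Gaussian coincidence-time jitter
    whose FWHM is the configured coincidence time resolution.  Background
    singles arrive as a Poisson process at the configured rate.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma_ctr = detector.ctr_fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    events: list[GammaEvent] = []
    for e in emissions:
        if e.mode != "beta_plus":
            continue
        if rng.random() >= detector.gamma_coincidence_prob:
            continue
        t = max(e.time_ns + rng.normal(0.0, sigma_ctr), 0.0)
        energy = max(rng.normal(511.0, detector.gamma_energy_resolution * 511.0), 0.0)
        events.append(
            GammaEvent(
                time=float(t),
                pulse_area=float(energy * detector.gamma_pulse_area_per_kev),
                energy=float(energy),
            )
        )
    if detector.gamma_background_rate_bq > 0:
        if duration_s is None:
            t_max_ns = max((e.time_ns for e in emissions), default=0.0)
            duration_s = t_max_ns / 1e9
        n_bg = rng.poisson(detector.gamma_background_rate_bq * duration_s)
        bg_times = rng.uniform(0.0, duration_s * 1e9, n_bg)
        lo, hi = detector.gamma_background_energy_kev
        bg_energies = rng.uniform(lo, hi, n_bg)
        events.extend(
            GammaEvent(
                time=float(t),
                pulse_area=float(en * detector.gamma_pulse_area_per_kev),
                energy=float(en),
            )
            for t, en in zip(bg_times, bg_energies)
        )
    events = [e for e in events if e.energy >= detector.gamma_threshold_kev]
    events.sort(key=lambda e: e.time)
    return events


# ---------------------------------------------------------------------------
# end-to-end acquisition


TRUTH_COLUMNS = (
    "track_id",
    "nuclide",
    "mode",
    "emitted_kev",
    "measured_kev",
    "x_px",
    "y_px",
    "time_ns",
    "n_pixels",
)


def simulate_acquisition(
    scene: SourceScene,
    chains: Sequence[NuclideChain],
    detector: DetectorModel,
    seed: int,
    out_dir: Union[str, Path],
) -> tuple[Path, Path, Path]:
    """Simulate a full acquisition and write both list-mode files + truth.

    Applies hemisphere acceptance per emission, renders accepted charged
    emissions into pixel hits and positron annihilations into the gamma
    stream, and writes ``pixels.tsv``, ``gammas.tsv`` and ``truth.tsv``
    (one row per detected track with its true particle type, nuclide,
    energies and position).  Fully reproducible for a fixed seed.
    """
    heads = [c.head for c in chains]
    if len(set(heads)) != len(heads):
        raise ValidationError(f"conflicting duplicate chain heads: {heads}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    decay_rng, accept_rng, render_rng, gamma_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    emissions: list[Emission] = []
    for chain in chains:
        emissions.extend(sample_decays(scene, chain, rng=decay_rng))
    emissions.sort(key=lambda e: e.time_ns)

    cos_theta = accept_rng.uniform(-1.0, 1.0, len(emissions))
    accepted = [e for e, c in zip(emissions, cos_theta) if c < 0.0]

    all_hits: list[PixelHit] = []
    truth_rows: list[tuple] = []
    for track_id, e in enumerate(accepted):
        hits = render_track_hits(e, detector, rng=render_rng)
        all_hits.extend(hits)
        truth_rows.append(
            (
                track_id,
                e.nuclide,
                e.mode,
                e.emitted_kev,
                sum(h.energy for h in hits),
                e.x,
                e.y,
                e.time_ns,
                len(hits),
            )
        )
    all_hits.sort(key=lambda h: h.toa)

    gammas = render_gamma_stream(
        accepted, detector, rng=gamma_rng, duration_s=scene.duration_s
    )

    pixel_path = write_listmode(all_hits, out_dir / "pixels.tsv", kind="pixel")
    gamma_path = write_listmode(gammas, out_dir / "gammas.tsv", kind="gamma")
    truth_path = out_dir / "truth.tsv"
    lines = ["\t".join(TRUTH_COLUMNS)]
    for row in truth_rows:
        lines.append(
            "\t".join(
                str(v) if isinstance(v, (int, str)) else repr(float(v)) for v in row
            )
        )
    truth_path.write_text("\n".join(lines) + "\n")
    return pixel_path, gamma_path, truth_path
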