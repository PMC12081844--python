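"""Decay-chain walking, decay sampling, acceptance and track rendering."""

import numpy as np
import pytest

from qpid import synthetic_source as ss
from qpid.core_model import TIME_QUANTUM_NS, ValidationError, read_listmode


@pytest.mark.parametrize(
    "head,expected",
    [
        ("Ra-223", (4.0, 2.0, 0.0)),   # 4 alpha + 2 beta- to stable Pb-207
        ("F-18", (0.0, 0.0, 1.0)),     # a single positron
        ("Th-227", (5.0, 2.0, 0.0)),   # one extra alpha on top of Ra-223
    ],
)
def test_chain_emission_counts(head, expected):
    chain = ss.NuclideChain.from_library(head)
    assert ss.chain_emission_counts(chain) == expected


def test_cyclic_chain_rejected():
    b = ss.DecayBranch(mode="alpha", fraction=1.0, daughter="A", energy_kev=5000.0)
    chain = ss.NuclideChain(head="A", nuclides={"A": (b,)})
    with pytest.raises(ValidationError, match="cycle"):
        chain.validate()


def test_branch_fractions_must_sum_to_one():
    b = ss.DecayBranch(mode="alpha", fraction=0.5, daughter="B", energy_kev=5000.0)
    chain = ss.NuclideChain(head="A", nuclides={"A": (b,), "B": ()})
    with pytest.raises(ValidationError, match="sum to 1"):
        chain.validate()


class TestSampleDecays:
    def test_poisson_decay_count(self):
        # 100 Bq for 10 s: within 4 sigma of 1000 decays
        scene = ss.SourceScene(
            sources=[ss.PointSource("F-18", 100.0, 128.0, 128.0)],
            duration_s=10.0,
            seed=11,
        )
        chain = ss.NuclideChain.from_library("F-18")
        emissions = ss.sample_decays(scene, chain)
        assert abs(len(emissions) - 1000) < 4 * np.sqrt(1000)

    def test_ra223_charged_multiplicity(self):
        scene = ss.SourceScene(
            sources=[ss.PointSource("Ra-223", 50.0, 128.0, 128.0)],
            duration_s=10.0,
            seed=12,
        )
        chain = ss.NuclideChain.from_library("Ra-223")
        emissions = ss.sample_decays(scene, chain)
        n_decays = sum(1 for e in emissions if e.nuclide == "Ra-223")
        assert emissions and abs(len(emissions) / n_decays - 6.0) < 1e-12

    def test_mylar_absorption_window(self):
        # the 5716 keV alpha line arrives 1.5-2 MeV lighter
        scene = ss.SourceScene(
            sources=[ss.PointSource("Ra-223", 30.0, 128.0, 128.0)],
            duration_s=5.0,
            seed=13,
        )
        chain = ss.NuclideChain.from_library("Ra-223")
        alphas = [
            e for e in ss.sample_decays(scene, chain)
            if e.mode == "alpha" and e.nuclide == "Ra-223"
        ]
        assert alphas
        for e in alphas:
            assert 5716.0 - 2000.0 <= e.energy_kev <= 5716.0 - 1500.0
            assert e.emitted_kev == 5716.0

    def test_zero_activity_gives_empty_list(self):
        scene = ss.SourceScene(
            sources=[ss.PointSource("F-18", 0.0, 10.0, 10.0)], duration_s=5.0
        )
        assert ss.sample_decays(scene, ss.NuclideChain.from_library("F-18")) == []

    def test_ingrowth_mode_delays_daughters(self):
        # with explicit lifetimes, Pb-211 (36 min half-life) decays fall
        # outside a 5 s acquisition, truncating the observed cascade
        scene = ss.SourceScene(
            sources=[ss.PointSource("Ra-223", 100.0, 128.0, 128.0)],
            duration_s=5.0,
            prompt_chain=False,
            seed=14,
        )
        chain = ss.NuclideChain.from_library("Ra-223")
        emissions = ss.sample_decays(scene, chain)
        modes = {e.mode for e in emissions}
        assert "beta_minus" not in modes
        assert all(e.time_ns <= 5e9 for e in emissions)


class TestAcceptance:
    def test_hemisphere_fraction_converges(self):
        frac = ss.geometric_acceptance_fraction(10**6, seed=1)
        assert abs(frac - 0.5) < 0.002

    def test_forced_sensorward(self):
        assert ss.geometric_acceptance_fraction(100, seed=1, sensorward_only=True) == 1.0

    def test_error_scales_as_sqrt_n(self):
        errs_small = [
            abs(ss.geometric_acceptance_fraction(10**3, seed=s) - 0.5)
            for s in range(30)
        ]
        errs_large = [
            abs(ss.geometric_acceptance_fraction(10**5, seed=s) - 0.5)
            for s in range(30)
        ]
        ratio = np.mean(errs_small) / np.mean(errs_large)
        assert 4.0 < ratio < 25.0  # ~sqrt(100) = 10 up to noise


class TestRenderTrackHits:
    def test_alpha_disc_size_and_energy_conservation(self, detector):
        e = ss.Emission("Ra-223", "alpha", 5800.0, 5800.0, 128.0, 128.0, 1e6)
        det = ss.DetectorModel(alpha_saturation_enabled=False)
        hits = ss.render_track_hits(e, det, seed=2)
        # a >=400 um disc at 55 um pitch covers >= 30 pixels
        assert len(hits) >= 30
        assert abs(sum(h.energy for h in hits) - 5800.0) < 0.1

    def test_alpha_saturation_reduces_measured_energy(self):
        det = ss.DetectorModel()  # saturation on by default
        e = ss.Emission("Ra-223", "alpha", 4000.0, 5716.0, 128.0, 128.0, 1e6)
        hits = ss.render_track_hits(e, det, seed=2)
        expected = det.alpha_sat_slope * 4000.0 + (1 - det.alpha_sat_slope) * 3000.0
        assert abs(sum(h.energy for h in hits) - expected) < 0.1

    def test_auger_track_is_subpixel_range(self, detector):
        e = ss.Emission("Zr-89", "auger", 12.7, 12.7, 100.0, 100.0, 0.0)
        sizes = [
            len(ss.render_track_hits(e, detector, seed=s)) for s in range(20)
        ]
        assert all(1 <= n <= 3 for n in sizes)

    def test_beta_length_monotone_in_energy(self, detector):
        lengths = [
            ss.beta_path_length(E, detector) for E in (12.7, 100.0, 400.0, 900.0)
        ]
        assert lengths == sorted(lengths)
        assert lengths[0] == 1 and lengths[-1] >= 20

    def test_beta_energy_conservation(self, detector):
        e = ss.Emission("F-18", "beta_plus", 500.0, 500.0, 128.0, 128.0, 1e6)
        hits = ss.render_track_hits(e, detector, seed=4)
        assert abs(sum(h.energy for h in hits) - 500.0) < 0.1

    def test_hit_times_quantized(self, detector):
        e = ss.Emission("F-18", "beta_plus", 500.0, 500.0, 128.0, 128.0, 1e6)
        for h in ss.render_track_hits(e, detector, seed=4):
            assert h.toa % TIME_QUANTUM_NS == pytest.approx(0.0, abs=1e-9)

    def test_emissions_far_apart_stay_separated(self, detector):
        e1 = ss.Emission("F-18", "beta_plus", 500.0, 500.0, 128.0, 128.0, 1e6)
        e2 = ss.Emission("F-18", "beta_plus", 500.0, 500.0, 128.0, 128.0, 1e6 + 1000.0)
        h1 = ss.render_track_hits(e1, detector, seed=5)
        h2 = ss.render_track_hits(e2, detector, seed=6)
        gap = min(h.toa for h in h2) - max(h.toa for h in h1)
        assert gap > 40.0  # larger than any aggregation window


class TestGammaStream:
    def test_coincident_fraction_matches_probability(self):
        det = ss.DetectorModel()  # p = 0.023
        emissions = [
            ss.Emission("F-18", "beta_plus", 400.0, 400.0, 10.0, 10.0, t * 1e5)
            for t in range(10**4)
        ]
        events = ss.render_gamma_stream(emissions, det, seed=8)
        assert abs(len(events) - 230) < 60  # 4 sigma Poisson band

    def test_empty_without_positrons_or_background(self):
        det = ss.DetectorModel(gamma_background_rate_bq=0.0)
        emissions = [ss.Emission("Ra-223", "alpha", 4000.0, 5716.0, 10.0, 10.0, 0.0)]
        assert ss.render_gamma_stream(emissions, det, seed=1) == []

    def test_gamma_energies_near_511(self):
        det = ss.DetectorModel(gamma_coincidence_prob=1.0)
        emissions = [
            ss.Emission("F-18", "beta_plus", 400.0, 400.0, 10.0, 10.0, t * 1e5)
            for t in range(500)
        ]
        energies = np.array([g.energy for g in ss.render_gamma_stream(emissions, det, seed=9)])
        assert abs(np.mean(energies) - 511.0) < 5.0


class TestSimulateAcquisition:
    def test_f18_truth_contains_only_positrons(self, tmp_path):
        scene = ss.SourceScene(
            sources=[ss.PointSource("F-18", 50.0, 128.0, 128.0)], duration_s=2.0
        )
        _, _, truth = ss.simulate_acquisition(
            scene, [ss.NuclideChain.from_library("F-18")], ss.DetectorModel(), 1, tmp_path
        )
        rows = truth.read_text().splitlines()[1:]
        assert rows and all(r.split("\t")[2] == "beta_plus" for r in rows)

    def test_mixed_scene_has_both_particle_types(self, mixed_scene_run):
        rows = mixed_scene_run["truth_path"].read_text().splitlines()[1:]
        modes = {r.split("\t")[2] for r in rows}
        assert "alpha" in modes and "beta_plus" in modes

    def test_same_seed_byte_identical(self, tmp_path):
        scene = ss.SourceScene(
            sources=[ss.PointSource("F-18", 30.0, 100.0, 100.0)], duration_s=1.0
        )
        chain = [ss.NuclideChain.from_library("F-18")]
        det = ss.DetectorModel(gamma_coincidence_prob=0.5)
        paths_a = ss.simulate_acquisition(scene, chain, det, 42, tmp_path / "a")
        paths_b = ss.simulate_acquisition(scene, chain, det, 42, tmp_path / "b")
        for pa, pb in zip(paths_a, paths_b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_duplicate_chain_heads_rejected(self, tmp_path):
        scene = ss.SourceScene(
            sources=[ss.PointSource("F-18", 30.0, 100.0, 100.0)], duration_s=1.0
        )
        chain = ss.NuclideChain.from_library("F-18")
        with pytest.raises(ValidationError, match="conflicting"):
            ss.simulate_acquisition(scene, [chain, chain], ss.DetectorModel(), 1, tmp_path)

    def test_hit_count_conserved_through_file(self, tmp_path):
        scene = ss.SourceScene(
            sources=[ss.PointSource("F-18", 50.0, 128.0, 128.0)], duration_s=2.0
        )
        pixel_path, _, truth = ss.simulate_acquisition(
            scene, [ss.NuclideChain.from_library("F-18")], ss.DetectorModel(), 2, tmp_path
        )
        hits = read_listmode(pixel_path, "pixel")
        n_from_truth = sum(
            int(r.split("\t")[8]) for r in truth.read_text().splitlines()[1:]
        )
        assert len(hits) == n_from_truth
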