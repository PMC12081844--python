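import numpy as np
import pytest

from qpid import synthetic_source as ss
from qpid.core_model import PixelHit


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def detector():
    return ss.DetectorModel()


def make_hit(col=10, row=10, toa=0.0, energy=100.0, calibrated=True):
    return PixelHit(col=col, row=row, toa=toa, energy=energy, calibrated=calibrated)


@pytest.fixture(scope="session")
def mixed_scene_run(tmp_path_factory):
    """A small mixed Ra-223 + F-18 acquisition with truth, shared by tests.

    Ingrowth mode keeps chain emissions temporally separated so one truth
    row corresponds to one reconstructed track.
    """
    out = tmp_path_factory.mktemp("mixed_run")
    scene = ss.SourceScene(
        sources=[
            ss.PointSource("Ra-223", 20.0, 80.0, 80.0),
            ss.PointSource("F-18", 200.0, 180.0, 180.0),
        ],
        duration_s=5.0,
        prompt_chain=False,
        seed=3,
    )
    detector = ss.DetectorModel(gamma_coincidence_prob=0.2)
    chains = [
        ss.NuclideChain.from_library("Ra-223"),
        ss.NuclideChain.from_library("F-18"),
    ]
    pixel_path, gamma_path, truth_path = ss.simulate_acquisition(
        scene, chains, detector, seed=7, out_dir=out
    )
    return {
        "scene": scene,
        "detector": detector,
        "pixel_path": pixel_path,
        "gamma_path": gamma_path,
        "truth_path": truth_path,
    }
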