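import numpy as np
import pytest

from palm_mcquant import synth


def well_separated_positions(n: int = 50, image_px: int = 64, pixel_nm: float = 160.0,
                             spacing_px: int = 8, seed: int = 7) -> np.ndarray:
    """Emitter positions on a jittered grid, at least ~spacing_px apart."""
    rng = np.random.default_rng(seed)
    pos = []
    per_row = image_px // spacing_px - 1
    for k in range(n):
        gx = k % per_row
        gy = k // per_row
        pos.append(
            (
                (gx + 1) * spacing_px + rng.uniform(-2, 2),
                (gy + 1) * spacing_px + rng.uniform(-2, 2),
            )
        )
    return np.array(pos) * pixel_nm


@pytest.fixture(scope="session")
def default_stack():
    """The default synthetic acquisition: 50 well-separated emitters,
    activation probability 0.05, 16-bit frames with Poisson noise."""
    pos = well_separated_positions()
    cfg = synth.FrameSimConfig(
        image_size=(64, 64), positions_nm=pos, activation_prob=0.05,
        n_frames=1000, seed=3,
    )
    frames, truth = synth.simulate_stack(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def background_stack():
    cfg = synth.FrameSimConfig(
        image_size=(64, 64), positions_nm=np.empty((0, 2)), n_frames=200, seed=5
    )
    frames, truth = synth.simulate_stack(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def dense_scene():
    """Dual-color scene spanning concentric to disjoint pairs, dense enough
    that rendered footprints approximate the ground-truth disks."""
    cfg = synth.SceneSimConfig(
        offsets_nm=(0.0, 100.0, 200.0, 300.0, 400.0, 500.0, 700.0),
        molecules_per_cluster=400,
        seed=5,
    )
    red, green, truth = synth.simulate_scene(cfg)
    return cfg, red, green, truth
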