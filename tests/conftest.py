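import numpy as np
import pytest

from bleachdmd import BleachStack, RegionSpec, SimConfig, fit_dmd, simulate_stack


@pytest.fixture(scope="session")
def paper_sim():
    """The canonical validation stack (seed 0) and its ground truth."""
    return simulate_stack(SimConfig(seed=0))


@pytest.fixture(scope="session")
def paper_model(paper_sim):
    stack, _ = paper_sim
    return fit_dmd(stack, rank=3)


@pytest.fixture()
def small_config():
    """A fast two-region configuration for pipeline-level tests."""
    return SimConfig(
        width=48,
        height=36,
        n_frames=40,
        regions=[
            RegionSpec("rectangle", (4, 4, 28, 40), 190.0, 0.02),
            RegionSpec("circle", (18, 30, 7), 190.0, 0.12),
        ],
        seed=3,
    )


def exponential_stack(patterns, rates, n_frames=20, dt=1.0, amplitude=100.0):
    """Float stack built exactly as a sum of patterns times exp(-k t).

    ``patterns`` are 2D boolean masks with disjoint support; the stack
    is noiseless and exactly rank len(patterns).
    """
    t = np.arange(n_frames) * dt
    h, w = patterns[0].shape
    frames = np.zeros((n_frames, h, w))
    for mask, k in zip(patterns, rates):
        frames += amplitude * mask[None] * np.exp(-k * t)[:, None, None]
    return BleachStack(frames=frames, dt=dt)


@pytest.fixture()
def rank2_toy():
    """4-pixel stack: pixels {0,1} decay at 0.1/s, pixels {2,3} at 0.3/s."""
    p1 = np.zeros((2, 2), bool)
    p1[0] = True
    p2 = ~p1
    return exponential_stack([p1, p2], [0.1, 0.3], n_frames=10)
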