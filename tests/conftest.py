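import numpy as np
import pytest
from hypothesis import settings

from wmfish import simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tess50():
    """50-cell tessellation on 512x512, seed 7: (labels, wall_image)."""
    return simulate.generate_cell_tessellation(
        50, (512, 512), wall_width=3, wall_amplitude=100.0, seed=7, background_level=10.0
    )


@pytest.fixture(scope="session")
def dataset_small():
    """Small full dataset with noise and autofluorescence: (stack, truth, cfg)."""
    cfg = simulate.SimConfig(
        image_shape=(320, 320), n_cells=16, count_law=("poisson", 8.0),
        spot_amplitude=50.0, noise_sigma=3.0, n_autofluor_blobs=2,
        protein_pattern="nuclear_blob", seed=13,
    )
    stack, truth = simulate.simulate_dataset(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def dataset_clean():
    """Noise-free dataset with fixed-amplitude spots: (stack, truth, cfg)."""
    cfg = simulate.SimConfig(
        image_shape=(448, 448), n_cells=20, count_law=("poisson", 20.0),
        spot_amplitude=50.0, noise_sigma=0.0, n_autofluor_blobs=0,
        protein_pattern="proportional_to_count", seed=29,
    )
    stack, truth = simulate.simulate_dataset(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def ring_truth():
    """Tessellation + envelope-ring protein structure: (labels, protein, mask)."""
    labels, _ = simulate.generate_cell_tessellation(30, (448, 448), seed=21)
    protein, mask, _ = simulate.simulate_protein_channel(labels, "envelope_ring", seed=22)
    return labels, protein, mask


def render_isolated_spots(n_side=10, spacing=55, amplitude=50.0, sigma=1.5,
                          background=10.0, seed=5):
    """Grid of isolated spots at random sub-pixel offsets; returns (image, positions)."""
    rng = np.random.default_rng(seed)
    size = n_side * spacing + 2 * 30
    img = np.full((size, size), background)
    pos = []
    for i in range(n_side):
        for j in range(n_side):
            yc = 30 + i * spacing + rng.uniform(-0.5, 0.5)
            xc = 30 + j * spacing + rng.uniform(-0.5, 0.5)
            simulate._render_gaussian_2d(img, yc, xc, amplitude, sigma)
            pos.append((yc, xc))
    return img, np.array(pos)
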