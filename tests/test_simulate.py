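"""Simulator ground-truth guarantees: partition, conservation, determinism,
analytic spot photometry, and the configured count/placement laws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from wmfish import simulate
from wmfish.simulate import (
    SimConfig, degrade, draw_counts, generate_cell_tessellation,
    generate_dataset, simulate_coloc_spots, simulate_dataset,
    simulate_protein_channel, simulate_spot_channel,
)


class TestTessellation:
    def test_partition_every_pixel_wall_or_one_cell(self, tess50):
        labels, wall = tess50
        assert len(np.unique(labels[labels > 0])) == 50
        # exhaustive scan: wall pixels are exactly the bright ridge pixels
        wall_mask = labels == 0
        assert np.all(wall[wall_mask] == 110.0)
        assert np.all(wall[~wall_mask] == 10.0)
        # labels are 1..50 consecutive
        assert np.array_equal(np.unique(labels), np.arange(51))

    def test_cells_are_single_connected_components(self, tess50):
        from scipy import ndimage as ndi
        labels, _ = tess50
        for lab in range(1, 51):
            _, n = ndi.label(labels == lab)
            assert n == 1

    def test_deterministic_under_seed(self):
        a = generate_cell_tessellation(12, (128, 128), seed=7)
        b = generate_cell_tessellation(12, (128, 128), seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = generate_cell_tessellation(12, (128, 128), seed=8)
        assert not np.array_equal(a[0], c[0])

    def test_single_cell_fills_interior(self):
        labels, wall = generate_cell_tessellation(1, (128, 128), wall_width=3, seed=0)
        assert set(np.unique(labels)) == {0, 1}
        # border frame is wall; the single cell occupies the interior
        assert labels[64, 64] == 1
        assert np.all(labels[:3, :] == 0) and np.all(labels[:, -3:] == 0)

    def test_shape_too_small_raises_with_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            generate_cell_tessellation(200, (64, 64), seed=0)


class TestSpotChannel:
    def test_zero_count_law_gives_constant_background(self, tess50):
        labels, _ = tess50
        img, spots, counts = simulate_spot_channel(labels, ("fixed", 0), seed=1)
        assert np.all(img == 10.0)
        assert len(spots) == 0 and counts.sum() == 0

    def test_counts_override_tally(self, tess50):
        labels, _ = tess50
        img, spots, counts = simulate_spot_channel(
            labels, counts_override={1: 3, 2: 5}, seed=1)
        assert len(spots) == 8
        assert spots["cell_id"].value_counts().to_dict() == {1: 3, 2: 5}
        assert counts[1] == 3 and counts[2] == 5 and counts.drop([1, 2]).sum() == 0

    def test_every_spot_inside_its_cell(self, dataset_small):
        _, truth, _ = dataset_small
        iy = truth.spots["y"].round().astype(int)
        ix = truth.spots["x"].round().astype(int)
        assert np.all(truth.label_map[iy, ix] == truth.spots["cell_id"])

    def test_conservation_counts_equal_spot_rows(self, dataset_small):
        _, truth, _ = dataset_small
        assert int(truth.counts.sum()) == len(truth.spots)
        per_cell = truth.spots["cell_id"].value_counts()
        for cell, n in per_cell.items():
            assert truth.counts[cell] == n

    @pytest.mark.parametrize("sigma", [1.5, 2.5])
    def test_integrated_intensity_matches_gaussian_integral(self, sigma):
        # analytic oracle: integral of A*exp(-r^2/2s^2) over the plane = A*2*pi*s^2
        img = np.zeros((64, 64))
        simulate._render_gaussian_2d(img, 31.3, 30.7, 50.0, sigma)
        expected = 50.0 * 2 * np.pi * sigma**2
        assert img.sum() == pytest.approx(expected, rel=0.01)

    def test_poisson_law_sample_mean(self):
        # distributional check: Poisson(20) over 200 cells
        rng = np.random.default_rng(0)
        counts = draw_counts(("poisson", 20.0), 200, rng)
        assert abs(counts.mean() - 20.0) < 3 * np.sqrt(20.0 / 200)

    def test_negbin_law_overdispersed(self):
        rng = np.random.default_rng(1)
        counts = draw_counts(("negbin", 20.0, 2.0), 4000, rng)
        assert abs(counts.mean() - 20.0) < 1.0
        # variance = m + m^2/r = 220
        assert counts.var() > 2 * counts.mean()

    def test_invalid_law_rejected(self):
        rng = np.random.default_rng(0)
        for law in [("gauss", 3), ("poisson",), ("negbin", 5.0), ("fixed", -1)]:
            with pytest.raises(ValueError):
                draw_counts(law, 5, rng)


class TestProteinChannel:
    def test_pattern_none_is_empty(self, tess50):
        labels, _ = tess50
        img, mask, levels = simulate_protein_channel(labels, "none", seed=0)
        assert not img.any() and not mask.any() and not levels.any()

    def test_envelope_ring_closed_annulus_inside_cell(self, ring_truth):
        from scipy import ndimage as ndi
        labels, _, mask = ring_truth
        for cell in np.unique(labels[labels > 0]):
            ring = mask & (labels == cell)
            assert ring.any()
            # morphological closure check: the ring encloses a hole
            filled = ndi.binary_fill_holes(ring)
            assert filled.sum() > ring.sum()
            # strictly inside: every ring pixel carries the cell's label
            assert np.all(labels[ring] == cell)

    def test_proportional_to_count_is_alpha_times_count(self, tess50):
        labels, _ = tess50
        counts = pd.Series(0, index=np.arange(1, 51))
        counts[7] = 4
        img, mask, levels = simulate_protein_channel(
            labels, "proportional_to_count", protein_alpha=10.0,
            true_counts=counts, seed=0)
        assert levels[7] == 40.0
        assert np.all(img[labels == 7] == 40.0)

    def test_proportional_without_counts_raises(self, tess50):
        labels, _ = tess50
        with pytest.raises(ValueError, match="true_counts"):
            simulate_protein_channel(labels, "proportional_to_count", seed=0)


class TestDegrade:
    def test_identity_when_disabled(self):
        img = np.random.default_rng(0).uniform(0, 100, (64, 64))
        out = degrade(img, noise_sigma=0.0, n_autofluor_blobs=0)
        assert np.array_equal(out, img)

    def test_noise_sd_matches_request(self):
        out = degrade(np.full((512, 512), 100.0), noise_sigma=5.0, seed=1)
        assert abs(out.std() - 5.0) / 5.0 < 0.05

    def test_autofluor_blob_suppressed_by_bandpass(self):
        # a blob 20x wider than the PSF must respond far less than a
        # matched spot of equal peak height (scale-space selectivity)
        from wmfish.spots import bandpass_filter
        spot = np.zeros((256, 256))
        simulate._render_gaussian_2d(spot, 128, 128, 50.0, 1.5)
        blob = degrade(np.zeros((256, 256)), noise_sigma=0.0, n_autofluor_blobs=1,
                       autofluor_amplitude=50.0, autofluor_sigma=30.0, seed=3)
        r_spot = bandpass_filter(spot, 1.5).max()
        r_blob = bandpass_filter(blob, 1.5).max()
        assert r_blob < 0.1 * r_spot

    def test_deterministic(self):
        img = np.full((64, 64), 10.0)
        assert np.array_equal(degrade(img, 5.0, 2, seed=4), degrade(img, 5.0, 2, seed=4))


class TestDataset:
    def test_dataset_deterministic(self, dataset_small):
        stack, truth, cfg = dataset_small
        stack2, truth2 = simulate_dataset(cfg)
        assert np.array_equal(stack, stack2)
        assert truth.spots.equals(truth2.spots)
        assert truth.counts.equals(truth2.counts)

    def test_roundtrip_through_files(self, tmp_path, dataset_small):
        from wmfish.io import read_stack
        _, _, cfg = dataset_small
        paths = generate_dataset(cfg, tmp_path / "ds")
        stack, truth = simulate_dataset(cfg)
        assert np.array_equal(read_stack(paths["stack"]).data, stack)
        spots = pd.read_csv(paths["spots"])
        assert len(spots) == len(truth.spots)
        assert np.allclose(spots[["y", "x"]], truth.spots[["y", "x"]])
        import yaml
        with open(paths["config"]) as fh:
            echoed = yaml.safe_load(fh)
        assert echoed["seed"] == cfg.seed
        assert tuple(echoed["image_shape"]) == cfg.image_shape

    def test_rnase_preset_has_zero_spots(self, tmp_path):
        cfg = SimConfig(image_shape=(128, 128), n_cells=4, count_law=("fixed", 0),
                        n_autofluor_blobs=2, seed=5, protein_pattern="none")
        paths = generate_dataset(cfg, tmp_path / "rnase")
        assert len(pd.read_csv(paths["spots"])) == 0

    def test_coloc_preset_flag_mean_matches_probability(self, ring_truth):
        labels, _, mask = ring_truth
        p = 0.45
        _, spots, _ = simulate_coloc_spots(labels, mask, ("poisson", 15.0), p, seed=9)
        n = len(spots)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(spots["coloc_flag"].mean() - p) < 3 * se

    def test_truth_coloc_flag_iff_center_in_mask(self, dataset_small):
        _, truth, _ = dataset_small
        iy = truth.spots["y"].round().astype(int)
        ix = truth.spots["x"].round().astype(int)
        assert np.array_equal(truth.spots["coloc_flag"].to_numpy(),
                              truth.mask[iy, ix])


@given(st.integers(0, 2**31 - 1))
def test_config_validation_accepts_any_seed(seed):
    cfg = SimConfig(image_shape=(64, 64), n_cells=1, seed=seed)
    assert cfg.seed == seed


@pytest.mark.parametrize("field,value", [
    ("image_shape", (32, 32)), ("n_cells", 0), ("noise_sigma", -1.0),
    ("protein_pattern", "stripes"), ("count_law", ("fixed", -2)),
])
def test_config_invariants_enforced(field, value):
    with pytest.raises(ValueError):
        SimConfig(**{field: value})
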