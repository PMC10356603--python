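"""Spot detection: band-pass selectivity, candidate maxima vs brute force,
threshold plateau behavior, sub-pixel fit accuracy, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from wmfish import simulate
from wmfish.spots import (
    SpotDetectionParams, ThresholdCurve, bandpass_filter, build_threshold_curve,
    detect_candidates, detect_spots, detect_spots_stack, fit_spots,
    select_threshold,
)
from .conftest import render_isolated_spots


class TestBandpass:
    def test_constant_image_zero_response(self):
        resp = bandpass_filter(np.full((64, 64), 123.0), 1.5)
        assert np.max(np.abs(resp)) < 1e-9 * 123.0

    def test_matched_spot_peaks_at_center(self):
        img = np.zeros((64, 64))
        simulate._render_gaussian_2d(img, 30.0, 33.0, 50.0, 1.5)
        resp = bandpass_filter(img, 1.5)
        assert np.unravel_index(np.argmax(resp), resp.shape) == (30, 33)
        # closed-form scale-space response of a Gaussian blob sigma_s under a
        # normalized LoG at sigma_f: peak = 2A (sigma_f^2 sigma_s^2)/(sigma_f^2+sigma_s^2)^2
        s = 1.5
        expected = 2 * 50.0 * (s**2 * s**2) / (s**2 + s**2) ** 2
        assert resp.max() == pytest.approx(expected, rel=0.02)

    def test_broad_blob_suppressed(self):
        # blob 10x the PSF width at equal peak height: response < 10%
        spot = np.zeros((256, 256))
        simulate._render_gaussian_2d(spot, 128, 128, 50.0, 1.5)
        blob = np.zeros((256, 256))
        yy, xx = np.mgrid[0:256, 0:256]
        blob += 50.0 * np.exp(-((yy - 128.0) ** 2 + (xx - 128.0) ** 2) / (2 * 15.0**2))
        r_spot = bandpass_filter(spot, 1.5).max()
        r_blob = bandpass_filter(blob, 1.5).max()
        assert r_blob < 0.1 * r_spot


def brute_force_candidates(img, min_sep):
    """Independent O(n^2) oracle: strict 8-neighborhood maxima, then greedy
    suppression by descending response with (y, x) tie-break."""
    h, w = img.shape
    maxima = []
    for y in range(h):
        for x in range(w):
            v = img[y, x]
            if v <= 0:
                continue
            neigh = [img[yy, xx]
                     for yy in range(max(0, y - 1), min(h, y + 2))
                     for xx in range(max(0, x - 1), min(w, x + 2))
                     if (yy, xx) != (y, x)]
            if all(v > n for n in neigh):
                maxima.append((y, x, v))
    maxima.sort(key=lambda t: (-t[2], t[0], t[1]))
    kept = []
    for y, x, v in maxima:
        if all((y - ky) ** 2 + (x - kx) ** 2 >= min_sep**2 - 1e-9 for ky, kx, _ in kept):
            kept.append((y, x, v))
    return kept


class TestCandidates:
    def test_two_distant_spots_found(self):
        img = np.full((40, 40), 1.0)
        simulate._render_gaussian_2d(img, 10, 10, 20.0, 1.5)
        simulate._render_gaussian_2d(img, 10, 20, 20.0, 1.5)
        cand = detect_candidates(bandpass_filter(img, 1.5), min_separation=3)
        assert len(cand) == 2

    def test_close_peaks_suppressed_keeping_brighter(self):
        img = np.zeros((24, 24))
        img[10, 10] = 5.0
        img[10, 12] = 4.0
        cand = detect_candidates(img, min_separation=3)
        assert len(cand) == 1
        assert (cand.iloc[0]["y"], cand.iloc[0]["x"]) == (10, 10)

    def test_zero_image_empty(self):
        assert len(detect_candidates(np.zeros((32, 32)), 3)) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equivalence_with_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 10, (48, 48))
        got = detect_candidates(img, min_separation=3)
        expected = brute_force_candidates(img, 3)
        assert len(got) == len(expected)
        assert np.allclose(got[["y", "x"]].to_numpy(),
                           [(y, x) for y, x, _ in expected])

    def test_min_separation_invariant(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 10, (96, 96))
        cand = detect_candidates(img, min_separation=4)
        pts = cand[["y", "x"]].to_numpy(float)
        from scipy.spatial.distance import pdist
        if len(pts) > 1:
            assert pdist(pts).min() >= 4 - 1e-9


class TestThresholdCurve:
    def test_step_function_counts(self):
        cand = pd.DataFrame({"y": np.arange(100), "x": np.arange(100),
                             "response": np.full(100, 7.0)})
        curve = build_threshold_curve(cand, 20, lower=7e-3)
        below = curve.thresholds < 7.0
        assert np.all(curve.counts[below] == 100)
        assert np.all(curve.counts[~below] == 0)

    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=200))
    def test_counts_non_increasing(self, responses):
        cand = pd.DataFrame({"response": responses})
        curve = build_threshold_curve(cand, 40)
        assert np.all(np.diff(curve.counts) <= 0)

    def test_empty_candidates_degenerate_curve_then_error(self):
        curve = build_threshold_curve(pd.DataFrame({"response": []}))
        assert len(curve.thresholds) == 0
        with pytest.raises(ValueError, match="no candidates"):
            select_threshold(curve)

    def test_gap_selection_between_noise_and_signal(self):
        # well-separated noise and spot responses: selected threshold must
        # fall strictly inside the gap
        resp = np.concatenate([np.linspace(0.5, 2.0, 300), np.full(100, 50.0)])
        cand = pd.DataFrame({"response": resp})
        curve = select_threshold(build_threshold_curve(cand, 60))
        assert 2.0 < curve.selected < 50.0
        assert not curve.low_confidence

    def test_featureless_curve_falls_back_low_confidence(self):
        # counts decaying steeply at every grid step -> no plateau
        curve = ThresholdCurve(np.geomspace(1, 100, 20),
                               (10**np.linspace(4, 0, 20)).astype(int))
        with pytest.warns(UserWarning, match="no threshold plateau"):
            curve = select_threshold(curve)
        assert curve.low_confidence


class TestFitSpots:
    def test_noise_free_subpixel_accuracy(self):
        img = np.full((48, 48), 10.0)
        simulate._render_gaussian_2d(img, 20.3, 31.7, 50.0, 1.5)
        cand = detect_candidates(bandpass_filter(img, 1.5), 2)
        fitted, diag = fit_spots(img, cand, fit_radius=3, psf_sigma=1.5)
        assert len(fitted) == 1
        assert abs(fitted.iloc[0]["y"] - 20.3) < 0.05
        assert abs(fitted.iloc[0]["x"] - 31.7) < 0.05
        assert fitted.iloc[0]["amplitude"] == pytest.approx(50.0, rel=0.05)
        assert fitted.iloc[0]["background"] == pytest.approx(10.0, rel=0.05)

    def test_flat_background_candidate_dropped(self):
        img = np.full((32, 32), 10.0)
        cand = pd.DataFrame({"y": [16], "x": [16], "response": [1.0]})
        fitted, diag = fit_spots(img, cand, fit_radius=3, psf_sigma=1.5)
        assert len(fitted) == 0


class TestDetectSpots:
    def test_noise_free_grid_fully_recovered(self):
        img, pos = render_isolated_spots(n_side=6, seed=5)
        tab, curve, diag = detect_spots(img, SpotDetectionParams())
        assert len(tab) == 36
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pos).query(tab[["y", "x"]].to_numpy())
        assert np.median(d) <= 0.05

    def test_noisy_subpixel_error(self):
        # SNR 10: amplitude 50, noise 5 -> median center error <= 0.2 px
        img, pos = render_isolated_spots(n_side=10, seed=5)
        noisy = simulate.degrade(img, noise_sigma=5.0, seed=1)
        tab, _, _ = detect_spots(noisy, SpotDetectionParams())
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pos).query(tab[["y", "x"]].to_numpy())
        assert np.median(d) <= 0.2

    def test_deterministic_rerun(self, dataset_small):
        stack, _, _ = dataset_small
        t1, _, _ = detect_spots(stack[1], SpotDetectionParams())
        t2, _, _ = detect_spots(stack[1], SpotDetectionParams())
        pd.testing.assert_frame_equal(t1, t2)

    def test_count_recovery_on_synthetic_truth(self, dataset_small):
        from wmfish.quantify import assign_spots, count_per_cell
        stack, truth, _ = dataset_small
        tab, _, _ = detect_spots(stack[1], SpotDetectionParams())
        tab = assign_spots(tab, truth.label_map)
        det = count_per_cell(tab, truth.label_map)
        tc = truth.counts.reindex(det.index).fillna(0)
        assert np.corrcoef(det, tc)[0, 1] >= 0.9

    def test_threshold_stability_within_plateau(self):
        # counting is threshold-stable: <= 10% variation across the plateau
        rng = np.random.default_rng(2)
        img = np.full((800, 800), 10.0)
        pos = rng.uniform(15, 785, size=(500, 2))
        for yc, xc in pos:
            simulate._render_gaussian_2d(img, yc, xc, 50.0, 1.5)
        noisy = simulate.degrade(img, noise_sigma=5.0, seed=3)
        tab, curve, _ = detect_spots(noisy, SpotDetectionParams())
        assert curve.plateau_span is not None
        i0, i1 = curve.plateau_span
        plateau_counts = curve.counts[i0:i1 + 1]
        assert (plateau_counts.max() - plateau_counts.min()) <= 0.1 * plateau_counts.max()

    def test_depth_consistency_across_planes(self):
        # 3 planes with identical statistics: per-plane mean counts within 10%
        planes = []
        for z in range(3):
            cfg = simulate.SimConfig(image_shape=(448, 448), n_cells=20,
                                     count_law=("fixed", 15), noise_sigma=5.0,
                                     protein_pattern="none", n_autofluor_blobs=0,
                                     seed=100 + z)
            stack, _ = simulate.simulate_dataset(cfg)
            planes.append(stack[1])
        spots, diag = detect_spots_stack(np.stack(planes), SpotDetectionParams())
        per_plane = spots.groupby("z").size()
        assert len(per_plane) == 3
        assert (per_plane.max() - per_plane.min()) / per_plane.mean() < 0.1

    def test_no_duplicate_detections(self, dataset_small):
        from scipy.spatial.distance import pdist
        stack, _, _ = dataset_small
        params = SpotDetectionParams()
        tab, _, _ = detect_spots(stack[1], params)
        assert pdist(tab[["y", "x"]].to_numpy()).min() >= params.min_separation - 1e-9


def test_params_validation():
    with pytest.raises(ValueError):
        SpotDetectionParams(psf_sigma_xy=0)
    with pytest.raises(ValueError):
        SpotDetectionParams(min_separation=0.5)
    with pytest.raises(ValueError):
        SpotDetectionParams(fit_quality_min=1.5)
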