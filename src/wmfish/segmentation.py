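"""Cell segmentation from the cell-wall stain channel.

Cells in cleared plant tissue are separated by walls that the SR2200 dye
renders as bright ridges.  Segmentation is classical marker-controlled
watershed: the smoothed wall image is treated as a landscape whose catchment
basins are cells; markers are the h-minima of that landscape, and watershed
lines (the ridges) are kept as label 0 so wall pixels belong to no cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import h_minima
from skimage.segmentation import clear_border as _sk_clear_border
from skimage.segmentation import relabel_sequential, watershed

__all__ = ["SegmentationParams", "segment_cells", "filter_cells", "match_labels"]


@dataclass
class SegmentationParams:
    """Watershed parameters.

    ``smoothing_sigma`` (px) smooths the wall channel for the watershed
    landscape; ``ridge_sigma`` (px) is the lighter smoothing used to
    threshold the bright wall ridge itself, which is excluded from all
    cells; ``marker_h`` is the h-minima depth used to seed basins
    (intensity units); ``min_cell_area`` (px²) drops basins too small to be
    cells; ``clear_border`` removes cells touching the image frame.
    """

    smoothing_sigma: float = 2.0
    ridge_sigma: float = 1.0
    marker_h: float = 5.0
    min_cell_area: int = 100
    clear_border: bool = False

    def __post_init__(self):
        if self.smoothing_sigma <= 0 or self.ridge_sigma <= 0:
            raise ValueError("sigmas must be > 0")
        if self.min_cell_area < 0:
            raise ValueError("min_cell_area must be >= 0")


def segment_cells(wall_image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment cells from a 2D wall-stain image.

    Returns a label map (0 = wall/watershed line, 1..n = cells, 4-connected
    components, labeled consecutively).  A constant image yields a single
    label over the frame interior with a warning.
    """
    params = params or SegmentationParams()
    img = np.asarray(wall_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_cells expects a 2D image")
    if not np.all(np.isfinite(img)):
        raise ValueError("wall image contains non-finite values")

    smoothed = ndi.gaussian_filter(img, params.smoothing_sigma)
    if np.ptp(smoothed) < 1e-12:
        warnings.warn("constant wall image: no ridges detected, returning one cell")
        labels = np.zeros(img.shape, dtype=np.int32)
        labels[1:-1, 1:-1] = 1
        return labels

    # markers: one per h-minimum basin of the wall landscape
    minima = h_minima(smoothed, params.marker_h)
    markers, n_markers = ndi.label(minima)
    if n_markers == 0:
        warnings.warn("no h-minima found; falling back to global minimum marker")
        markers = (smoothed == smoothed.min()).astype(np.int32)
        markers, _ = ndi.label(markers)

    labels = watershed(smoothed, markers, connectivity=1).astype(np.int32)

    # the watershed line is conceptual, but the physical wall ridge has
    # width: exclude bright ridge pixels (Otsu on a lightly smoothed wall
    # image) so wall pixels belong to no cell
    ridge_ref = ndi.gaussian_filter(img, params.ridge_sigma)
    labels[ridge_ref > threshold_otsu(ridge_ref)] = 0

    # spurious oversegmentation (two markers in one cell) leaves basins that
    # touch directly, with no wall band between them — real cells are always
    # separated by the excluded ridge.  Merge directly touching labels.
    labels = _merge_touching_labels(labels)

    return filter_cells(labels, params.min_cell_area, params.clear_border)


def _merge_touching_labels(labels: np.ndarray) -> np.ndarray:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    n = int(labels.max())
    if n < 2:
        return labels
    pairs = []
    for a, b in ((labels[:-1, :], labels[1:, :]), (labels[:, :-1], labels[:, 1:])):
        touch = (a > 0) & (b > 0) & (a != b)
        pairs.append(np.stack([a[touch], b[touch]]))
    pairs = np.concatenate(pairs, axis=1)
    if pairs.size == 0:
        return labels
    graph = coo_matrix((np.ones(pairs.shape[1]), (pairs[0] - 1, pairs[1] - 1)),
                       shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    mapping = np.concatenate([[0], comp + 1])
    return mapping[labels].astype(np.int32)


def filter_cells(labels: np.ndarray, min_cell_area: int = 0, clear_border: bool = False) -> np.ndarray:
    """Drop labels below ``min_cell_area`` (and frame-touching ones if
    ``clear_border``), then relabel consecutively 1..n."""
    labels = np.asarray(labels).copy()
    if clear_border:
        labels = _sk_clear_border(labels)
    if min_cell_area > 0:
        ids, areas = np.unique(labels[labels > 0], return_counts=True)
        small = ids[areas < min_cell_area]
        if len(small):
            labels[np.isin(labels, small)] = 0
    out, _, _ = relabel_sequential(labels)
    return out.astype(np.int32)


def match_labels(pred: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.7) -> dict:
    """Greedy one-to-one matching of predicted to true cells by IoU.

    Pairs are taken in descending IoU order; a pair counts as matched when
    IoU >= ``iou_threshold``.  Returns a dict with ``pairs`` (DataFrame
    pred_id, truth_id, iou), ``precision``, ``recall``, ``mean_iou``,
    ``n_pred``, ``n_truth``.  Empty prediction gives precision 0 by
    convention.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth label maps must have the same shape")

    pred_ids = np.unique(pred[pred > 0])
    truth_ids = np.unique(truth[truth > 0])
    n_pred, n_truth = len(pred_ids), len(truth_ids)
    if n_pred == 0 or n_truth == 0:
        return {
            "pairs": pd.DataFrame(columns=["pred_id", "truth_id", "iou"]),
            "precision": 0.0, "recall": 0.0, "mean_iou": float("nan"),
            "n_pred": n_pred, "n_truth": n_truth,
        }

    # joint histogram of (pred, truth) labels -> intersection areas
    both = (pred > 0) & (truth > 0)
    pairs, inter = np.unique(
        np.stack([pred[both], truth[both]]), axis=1, return_counts=True
    )
    pred_area = dict(zip(*np.unique(pred[pred > 0], return_counts=True)))
    truth_area = dict(zip(*np.unique(truth[truth > 0], return_counts=True)))
    iou = np.array([
        inter[k] / (pred_area[pairs[0, k]] + truth_area[pairs[1, k]] - inter[k])
        for k in range(pairs.shape[1])
    ])

    order = np.argsort(-iou, kind="stable")
    used_p, used_t, matched = set(), set(), []
    for k in order:
        p, t = int(pairs[0, k]), int(pairs[1, k])
        if iou[k] < iou_threshold:
            break
        if p in used_p or t in used_t:
            continue
        used_p.add(p); used_t.add(t)
        matched.append((p, t, float(iou[k])))

    df = pd.DataFrame(matched, columns=["pred_id", "truth_id", "iou"])
    return {
        "pairs": df,
        "precision": len(df) / n_pred,
        "recall": len(df) / n_truth,
        "mean_iou": float(df["iou"].mean()) if len(df) else float("nan"),
        "n_pred": n_pred,
        "n_truth": n_truth,
    }
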