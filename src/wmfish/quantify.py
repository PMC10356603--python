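"""Per-cell quantification: spot assignment, counts, intensities, log ratios.

The label map from segmentation is the spatial frame: every detected spot is
assigned to the cell under its center, per-cell transcript counts N_c and
channel intensities are tabulated, and the per-cell log ratio
L_c = ln((I_rna + eps) / (I_prot + eps)) drives the RNA/protein imbalance
heatmaps.  Spots on wall pixels (label 0) stay in the table but are
unassigned and excluded from counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stats import pearson_r2

__all__ = [
    "assign_spots",
    "count_per_cell",
    "measure_intensity",
    "log_ratio",
    "build_cell_table",
    "render_cell_heatmap",
    "verify_count_intensity_correlation",
]

logger = logging.getLogger(__name__)

UNASSIGNED = -1  # cell_id of spots on wall/background pixels

DEFAULT_EPSILON = 1.0  # log-ratio pseudocount, intensity units (16-bit scale)


def assign_spots(spots: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Fill ``cell_id`` with the label under each spot center.

    The center rule (label at the rounded sub-pixel center) is the
    conventional choice for sub-resolution objects.  Spots landing on label
    0 get ``cell_id = -1`` (unassigned); they stay in the table but do not
    contribute to any per-cell count.
    """
    out = spots.copy()
    if len(out) == 0:
        return out
    iy = out["y"].round().astype(int)
    ix = out["x"].round().astype(int)
    if (iy < 0).any() or (ix < 0).any() or (iy >= labels.shape[0]).any() or (ix >= labels.shape[1]).any():
        raise ValueError("spot coordinates outside label map bounds")
    lab = labels[iy, ix]
    out["cell_id"] = np.where(lab > 0, lab, UNASSIGNED).astype(int)
    return out


def count_per_cell(spots: pd.DataFrame, labels: np.ndarray) -> pd.Series:
    """Per-cell spot counts N_c; every label appears, zeros included.

    Conservation: ``counts.sum() + n_unassigned == len(spots)``.
    """
    cell_ids = np.unique(labels[labels > 0]).astype(int)
    counts = pd.Series(0, index=cell_ids, name="n_spots", dtype=int)
    if len(spots):
        assigned = spots[spots["cell_id"] > 0]
        tally = assigned["cell_id"].value_counts()
        counts.loc[tally.index.intersection(counts.index)] = tally
    return counts


def measure_intensity(
    channel: np.ndarray,
    labels: np.ndarray,
    background_correction: bool = False,
) -> pd.DataFrame:
    """Mean and total pixel intensity per cell.

    With ``background_correction`` the median intensity of label-0 (wall/
    background) pixels is subtracted and the per-cell results are floored at
    0.  (Subtraction happens before summing, not per clipped pixel, so
    zero-mean noise does not bias the corrected totals.)
    """
    channel = np.asarray(channel, float)
    if channel.shape != labels.shape:
        raise ValueError("channel and label map shapes differ")
    img = channel
    if background_correction:
        bg = float(np.median(channel[labels == 0])) if (labels == 0).any() else 0.0
        img = channel - bg
    cell_ids = np.unique(labels[labels > 0]).astype(int)
    means = ndi.mean(img, labels=labels, index=cell_ids)
    sums = ndi.sum_labels(img, labels=labels, index=cell_ids)
    if background_correction:
        means = np.clip(means, 0.0, None)
        sums = np.clip(sums, 0.0, None)
    return pd.DataFrame({"mean": means, "total": sums}, index=cell_ids)


def log_ratio(i_rna, i_prot, epsilon: float = DEFAULT_EPSILON):
    """Per-cell log ratio L_c = ln((I_rna + eps) / (I_prot + eps)).

    The pseudocount keeps empty cells finite (both zero -> 0 exactly) and is
    constant for a run.  Antisymmetric under channel swap.
    """
    i_rna = np.asarray(i_rna, float)
    i_prot = np.asarray(i_prot, float)
    if (i_rna < 0).any() or (i_prot < 0).any():
        raise ValueError("intensities must be non-negative")
    return np.log((i_rna + epsilon) / (i_prot + epsilon))


def build_cell_table(
    labels: np.ndarray,
    spots: pd.DataFrame | None = None,
    rna_channel: np.ndarray | None = None,
    protein_channel: np.ndarray | None = None,
    background_correction: bool = False,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Assemble the per-cell table: area, centroid, N_c, intensities, L_c.

    Columns are added only for the channels supplied; colocalization columns
    (K_c, F_c) are filled by :mod:`wmfish.coloc`.
    """
    cell_ids = np.unique(labels[labels > 0]).astype(int)
    areas = ndi.sum_labels(np.ones_like(labels), labels=labels, index=cell_ids)
    centroids = ndi.center_of_mass(np.ones_like(labels), labels=labels, index=cell_ids)
    table = pd.DataFrame({
        "cell_id": cell_ids,
        "area": areas.astype(int),
        "centroid_y": [c[0] for c in centroids],
        "centroid_x": [c[1] for c in centroids],
    }).set_index("cell_id")

    if spots is not None:
        table["n_spots"] = count_per_cell(spots, labels)
    if rna_channel is not None:
        rna = measure_intensity(rna_channel, labels, background_correction)
        table["rna_mean"] = rna["mean"]
        table["rna_total"] = rna["total"]
    if protein_channel is not None:
        prot = measure_intensity(protein_channel, labels, background_correction)
        table["protein_mean"] = prot["mean"]
        table["protein_total"] = prot["total"]
    if rna_channel is not None and protein_channel is not None:
        table["log_ratio"] = log_ratio(table["rna_mean"], table["protein_mean"], epsilon)
    return table


def render_cell_heatmap(
    labels: np.ndarray,
    values: pd.Series,
    colormap_name: str = "viridis",
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Paint each cell with a colormap color for its value.

    Wall pixels are black; cells missing from ``values`` are neutral gray
    (and logged).  Returns ``(rgb_image, colorbar_metadata)`` where the
    metadata records the colormap name and value range so the render can be
    inverted up to colormap quantization.
    """
    import matplotlib
    import warnings as _warnings

    cmap = matplotlib.colormaps[colormap_name]
    cell_ids = np.unique(labels[labels > 0]).astype(int)
    vals = values.reindex(cell_ids)
    missing = vals.index[vals.isna()]
    if len(missing):
        logger.warning("no value for cells %s: rendered gray", list(missing))

    finite = vals.dropna()
    if value_range is None:
        if len(finite):
            vmin, vmax = float(finite.min()), float(finite.max())
        else:
            vmin, vmax = 0.0, 1.0
    else:
        vmin, vmax = map(float, value_range)
    degenerate = vmax <= vmin
    if degenerate:
        _warnings.warn("degenerate value range: single-color render")

    rgb = np.zeros(labels.shape + (3,), float)  # walls black
    for cell in cell_ids:
        region = labels == cell
        v = vals.get(cell)
        if pd.isna(v):
            rgb[region] = 0.5  # neutral gray
        else:
            t = 0.5 if degenerate else (float(v) - vmin) / (vmax - vmin)
            rgb[region] = cmap(float(np.clip(t, 0.0, 1.0)))[:3]
    meta = {"colormap": colormap_name, "vmin": vmin, "vmax": vmax,
            "missing_cells": [int(c) for c in missing]}
    return rgb, meta


def verify_count_intensity_correlation(cell_table: pd.DataFrame,
                                       intensity_col: str = "rna_mean") -> tuple[float, float, float]:
    """Sanity check that per-cell intensity tracks the transcript count.

    Least-squares line of intensity vs N_c; returns (slope, intercept, R²).
    This is the control used before trusting intensity-based readouts: if
    fluorescence per cell does not correlate with the number of detected
    molecules, the channel is dominated by something other than the probes.
    """
    if "n_spots" not in cell_table or intensity_col not in cell_table:
        raise ValueError("cell table needs n_spots and the intensity column")
    df = cell_table[["n_spots", intensity_col]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 cells")
    x = df["n_spots"].to_numpy(float)
    y = df[intensity_col].to_numpy(float)
    if np.var(x) == 0:
        raise ValueError("no variation in spot counts")
    slope, intercept = np.polyfit(x, y, 1)
    _, r2, _ = pearson_r2(x, y)
    return float(slope), float(intercept), float(r2)
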