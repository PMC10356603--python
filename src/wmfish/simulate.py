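"""Synthetic whole-mount smFISH microscopy generator with exact ground truth.

Emulates the statistical structure of cleared plant tissue imaged by confocal
smFISH: a tessellated field of cells whose walls are bright ridges (the
cell-wall stain channel), diffraction-limited mRNA spots whose per-cell counts
follow a configurable law (the smFISH channel), a protein-reporter channel
rendered as nuclear blobs, nuclear-envelope rings, or a cytoplasmic level
proportional to the transcript count, and degradation by Gaussian noise plus
large smooth autofluorescent blobs.

Every generated image is paired with its ground truth (label map, spot list,
per-cell counts and protein levels, protein mask), so each downstream stage of
the quantification pipeline can be tested for recovery without external data.
A single seed determines the whole dataset; channels draw from fixed offsets of
it so toggling one channel does not perturb the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.morphology import disk

__all__ = [
    "SimConfig",
    "GroundTruth",
    "draw_counts",
    "generate_cell_tessellation",
    "simulate_spot_channel",
    "simulate_coloc_spots",
    "simulate_protein_channel",
    "degrade",
    "simulate_dataset",
    "generate_dataset",
]

# fixed per-channel offsets of the dataset seed (reproducibility when
# toggling channels on/off)
_SEED_TESS = 0
_SEED_SPOTS = 1_000_003
_SEED_PROTEIN = 2_000_003
_SEED_NOISE_RNA = 3_000_017
_SEED_NOISE_WALL = 4_000_037
_SEED_NOISE_PROT = 5_000_063

_MIN_MEAN_CELL_AREA = 100  # px², precondition of the tessellation


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Amplitudes and levels are in arbitrary intensity units; lengths in pixels.
    ``count_law`` is ``("fixed", k)``, ``("poisson", lam)`` or
    ``("negbin", mean, dispersion)`` where dispersion is the Gamma shape
    parameter of the Poisson-mixture (variance = mean + mean²/dispersion).
    """

    image_shape: tuple[int, int] = (512, 512)
    n_z: int = 1
    n_cells: int = 50
    wall_width: int = 3
    wall_amplitude: float = 100.0
    psf_sigma_xy: float = 1.5
    psf_sigma_z: float = 1.0
    spot_amplitude: float = 50.0
    count_law: tuple = ("poisson", 20.0)
    protein_pattern: str = "nuclear_blob"  # nuclear_blob | envelope_ring | proportional_to_count | none
    protein_mean: float = 80.0
    protein_sd: float = 20.0
    protein_alpha: float = 10.0  # intensity per transcript, proportional_to_count
    noise_sigma: float = 5.0
    background_level: float = 10.0
    n_autofluor_blobs: int = 3
    autofluor_amplitude: float = 30.0
    autofluor_sigma: float = 30.0
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(s) for s in self.image_shape)
        if len(shape) != 2 or min(shape) < 64:
            raise ValueError(f"image_shape must be 2D and at least 64x64, got {shape}")
        self.image_shape = shape
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("wall_amplitude", "psf_sigma_xy", "psf_sigma_z", "spot_amplitude",
                     "protein_mean", "protein_sd", "noise_sigma", "background_level",
                     "autofluor_amplitude", "autofluor_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.protein_pattern not in ("nuclear_blob", "envelope_ring",
                                        "proportional_to_count", "none"):
            raise ValueError(f"unknown protein_pattern {self.protein_pattern!r}")
        _validate_count_law(self.count_law)


@dataclass
class GroundTruth:
    """Exact truth for one simulated dataset.

    ``spots`` has columns (z, y, x, cell_id, coloc_flag); ``counts`` and
    ``protein`` map cell id -> truth; ``mask`` is the protein structure
    support.
    """

    label_map: np.ndarray
    spots: pd.DataFrame
    counts: pd.Series
    protein: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if int(self.counts.sum()) != len(self.spots):
            raise ValueError("sum of counts must equal number of spots")


def _validate_count_law(law) -> None:
    if not isinstance(law, (tuple, list)) or not law:
        raise ValueError(f"invalid count_law {law!r}")
    kind = law[0]
    if kind == "fixed":
        if len(law) != 2 or law[1] < 0:
            raise ValueError(f"fixed law needs a non-negative count: {law!r}")
    elif kind == "poisson":
        if len(law) != 2 or law[1] < 0:
            raise ValueError(f"poisson law needs lambda >= 0: {law!r}")
    elif kind == "negbin":
        if len(law) != 3 or law[1] < 0 or law[2] <= 0:
            raise ValueError(f"negbin law needs (mean >= 0, dispersion > 0): {law!r}")
    else:
        raise ValueError(f"unknown count_law kind {kind!r}")


def draw_counts(law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` per-cell molecule counts from a count law."""
    _validate_count_law(law)
    kind = law[0]
    if kind == "fixed":
        return np.full(n, int(law[1]), dtype=int)
    if kind == "poisson":
        return rng.poisson(law[1], size=n).astype(int)
    # negative binomial as Gamma-Poisson mixture: mean m, shape r
    m, r = law[1], law[2]
    lam = rng.gamma(shape=r, scale=m / r, size=n) if m > 0 else np.zeros(n)
    return rng.poisson(lam).astype(int)


# ---------------------------------------------------------------------------
# tessellation
# ---------------------------------------------------------------------------

def generate_cell_tessellation(
    n_cells: int,
    image_shape: tuple[int, int],
    wall_width: int = 3,
    wall_amplitude: float = 100.0,
    seed: int = 0,
    background_level: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Tessellate the field into ``n_cells`` Voronoi cells with ridge walls.

    Cells are the Voronoi regions of seed points sampled with a minimum
    mutual distance; walls are the inter-region boundaries dilated to
    ``wall_width`` plus a border frame, so every cell (including border
    cells) is a closed region.  Returns ``(label_map, wall_image)`` where the
    label map has labels 1..n_cells and 0 on walls, and the wall image is
    ``background_level`` everywhere except ``background_level +
    wall_amplitude`` on wall pixels.
    """
    h, w = image_shape
    interior_area = (h - 2 * wall_width) * (w - 2 * wall_width)
    if interior_area / n_cells < _MIN_MEAN_CELL_AREA:
        min_side = int(np.ceil(np.sqrt(n_cells * _MIN_MEAN_CELL_AREA))) + 2 * wall_width
        raise ValueError(
            f"image {h}x{w} too small for {n_cells} cells: mean cell area must be "
            f">= {_MIN_MEAN_CELL_AREA} px²; need at least ~{min_side}x{min_side}"
        )
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        labels = _voronoi_labels(n_cells, (h, w), wall_width, rng)
        if labels is not None:
            break
    else:  # pragma: no cover - dart throwing essentially always succeeds
        raise RuntimeError("could not place a valid tessellation; enlarge the image")

    wall_mask = labels == 0
    wall_image = np.full((h, w), float(background_level))
    wall_image[wall_mask] += wall_amplitude
    return labels, wall_image


def _voronoi_labels(n_cells, shape, wall_width, rng):
    h, w = shape
    margin = wall_width + 2
    if n_cells == 1:
        seeds = np.array([[h / 2, w / 2]])
    else:
        # dart throwing with a minimum seed separation keeps cells from
        # being swallowed by the dilated wall
        min_dist = 0.55 * np.sqrt((h - 2 * margin) * (w - 2 * margin) / n_cells)
        seeds = []
        for _ in range(200 * n_cells):
            p = rng.uniform([margin, margin], [h - margin, w - margin])
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_dist**2 for q in seeds):
                seeds.append(p)
                if len(seeds) == n_cells:
                    break
        if len(seeds) < n_cells:
            return None
        seeds = np.array(seeds)

    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    _, nearest = cKDTree(seeds).query(pts, k=1)
    labels = (nearest.reshape(h, w) + 1).astype(np.int32)

    # ridge = pixels adjacent to a different region, dilated to wall_width
    boundary = np.zeros((h, w), bool)
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    radius = max(0, (wall_width - 1) // 2)
    if radius:
        boundary = ndi.binary_dilation(boundary, structure=disk(radius))
    labels[boundary] = 0
    # border frame is wall so border cells are closed
    labels[:wall_width, :] = 0
    labels[-wall_width:, :] = 0
    labels[:, :wall_width] = 0
    labels[:, -wall_width:] = 0

    present = np.unique(labels[labels > 0])
    if len(present) != n_cells:
        return None
    # each cell must remain a single 4-connected component
    for lab in present:
        _, ncomp = ndi.label(labels == lab)
        if ncomp != 1:
            return None
    return labels


# ---------------------------------------------------------------------------
# spot channel
# ---------------------------------------------------------------------------

def _render_gaussian_2d(image, yc, xc, amplitude, sigma):
    """Add an isotropic 2D Gaussian peak sampled at pixel centers."""
    h, w = image.shape
    r = int(np.ceil(5 * sigma))
    y0, y1 = max(0, int(yc) - r), min(h, int(yc) + r + 1)
    x0, x1 = max(0, int(xc) - r), min(w, int(xc) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    image[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - yc) ** 2 + (xx - xc) ** 2) / (2.0 * sigma**2)
    )


def _cell_pixel_index(labels):
    """Map cell id -> (ys, xs) arrays of its interior pixels."""
    objects = ndi.find_objects(labels)
    out = {}
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        ys, xs = np.nonzero(labels[sl] == lab)
        out[lab] = (ys + sl[0].start, xs + sl[1].start)
    return out


def simulate_spot_channel(
    labels: np.ndarray,
    count_law=("poisson", 20.0),
    psf_sigma_xy: float = 1.5,
    spot_amplitude: float = 50.0,
    background_level: float = 10.0,
    seed: int = 0,
    counts_override: Optional[dict[int, int]] = None,
) -> tuple[np.ndarray, pd.DataFrame, pd.Series]:
    """Render the smFISH channel for a label map.

    Each cell draws its molecule count from ``count_law`` (or takes it from
    ``counts_override``); spot centers are uniform over the cell interior at
    sub-pixel positions; each spot is an isotropic Gaussian of peak
    ``spot_amplitude`` added over ``background_level``.

    Returns ``(spot_image, true_spots, true_counts)`` with ``true_spots``
    columns (z, y, x, cell_id, coloc_flag).
    """
    if psf_sigma_xy <= 0:
        raise ValueError("psf_sigma_xy must be > 0")
    rng = np.random.default_rng(seed)
    cell_ids = np.unique(labels[labels > 0])
    pix = _cell_pixel_index(labels)

    if counts_override is not None:
        counts = np.array([int(counts_override.get(int(c), 0)) for c in cell_ids])
    else:
        counts = draw_counts(count_law, len(cell_ids), rng)

    image = np.full(labels.shape, float(background_level))
    rows = []
    for i, cell in enumerate(cell_ids):
        ys, xs = pix.get(int(cell), (np.array([]), np.array([])))
        if len(ys) == 0:
            if counts[i] > 0:
                warnings.warn(f"cell {cell} has no interior pixels; count forced to 0")
                counts[i] = 0
            continue
        for _ in range(counts[i]):
            j = rng.integers(len(ys))
            yc = ys[j] + rng.uniform(-0.49, 0.49)
            xc = xs[j] + rng.uniform(-0.49, 0.49)
            _render_gaussian_2d(image, yc, xc, spot_amplitude, psf_sigma_xy)
            rows.append((0.0, yc, xc, int(cell), False))

    spots = pd.DataFrame(rows, columns=["z", "y", "x", "cell_id", "coloc_flag"])
    true_counts = pd.Series(counts, index=cell_ids.astype(int), name="count")
    return image, spots, true_counts


def simulate_coloc_spots(
    labels: np.ndarray,
    mask: np.ndarray,
    count_law=("poisson", 15.0),
    p_coloc: float = 0.4,
    psf_sigma_xy: float = 1.5,
    spot_amplitude: float = 50.0,
    background_level: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, pd.Series]:
    """Render a spot channel where each spot lands inside ``mask`` with
    probability ``p_coloc`` (and outside it otherwise), within its cell.

    Ground-truth ``coloc_flag`` records the realized placement.  Cells whose
    intersection with the mask is empty place all spots outside.
    """
    if not 0 <= p_coloc <= 1:
        raise ValueError("p_coloc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cell_ids = np.unique(labels[labels > 0])
    image = np.full(labels.shape, float(background_level))
    rows = []
    counts = []
    for cell in cell_ids:
        region = labels == cell
        inside = np.nonzero(region & mask)
        outside = np.nonzero(region & ~mask)
        n = int(draw_counts(count_law, 1, rng)[0])
        counts.append(n)
        for _ in range(n):
            want_in = rng.random() < p_coloc and len(inside[0]) > 0
            ys, xs = (inside if want_in else outside)
            if len(ys) == 0:
                ys, xs = np.nonzero(region)
                want_in = bool(mask[ys[0], xs[0]])
            j = rng.integers(len(ys))
            yc = ys[j] + rng.uniform(-0.49, 0.49)
            xc = xs[j] + rng.uniform(-0.49, 0.49)
            _render_gaussian_2d(image, yc, xc, spot_amplitude, psf_sigma_xy)
            rows.append((0.0, yc, xc, int(cell), bool(want_in)))
    spots = pd.DataFrame(rows, columns=["z", "y", "x", "cell_id", "coloc_flag"])
    true_counts = pd.Series(counts, index=cell_ids.astype(int), name="count")
    return image, spots, true_counts


# ---------------------------------------------------------------------------
# protein channel
# ---------------------------------------------------------------------------

def simulate_protein_channel(
    labels: np.ndarray,
    protein_pattern: str = "nuclear_blob",
    protein_mean: float = 80.0,
    protein_sd: float = 20.0,
    protein_alpha: float = 10.0,
    true_counts: Optional[pd.Series] = None,
    ring_width: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Render the protein-reporter channel.

    ``nuclear_blob`` paints a filled disc at the deepest interior point of
    each cell; ``envelope_ring`` paints a closed annulus around that disc
    (the nuclear envelope); ``proportional_to_count`` paints the whole cell
    at intensity ``alpha * N_c`` (requires ``true_counts``); ``none`` yields
    a zero image.  Per-cell intensity is Normal(mean, sd) clipped at 0 for
    the first two patterns.

    Returns ``(protein_image, true_mask, true_protein)``.
    """
    rng = np.random.default_rng(seed)
    image = np.zeros(labels.shape, float)
    mask = np.zeros(labels.shape, bool)
    cell_ids = np.unique(labels[labels > 0]).astype(int)
    intensity = pd.Series(0.0, index=cell_ids, name="protein")

    if protein_pattern == "none":
        return image, mask, intensity
    if protein_pattern == "proportional_to_count":
        if true_counts is None:
            raise ValueError("proportional_to_count requires true_counts")
        for cell in cell_ids:
            region = labels == cell
            val = protein_alpha * float(true_counts.get(cell, 0))
            image[region] = val
            mask |= region & (val > 0)
            intensity[cell] = val
        return image, mask, intensity

    objects = ndi.find_objects(labels)
    for cell in cell_ids:
        sl = objects[cell - 1]
        # pad the bbox so the EDT sees the cell boundary correctly
        y0 = max(0, sl[0].start - 1); y1 = min(labels.shape[0], sl[0].stop + 1)
        x0 = max(0, sl[1].start - 1); x1 = min(labels.shape[1], sl[1].stop + 1)
        region = labels[y0:y1, x0:x1] == cell
        edt = ndi.distance_transform_edt(region)
        cy, cx = np.unravel_index(np.argmax(edt), edt.shape)
        dmax = edt[cy, cx]
        yy, xx = np.mgrid[0 : region.shape[0], 0 : region.shape[1]]
        d = np.hypot(yy - cy, xx - cx)
        val = max(0.0, rng.normal(protein_mean, protein_sd))
        if protein_pattern == "nuclear_blob":
            r = min(0.5 * dmax + 1.0, dmax - 1.0) if dmax > 4 else max(1.0, dmax - 1.0)
            struct = region & (d <= max(r, 1.0))
        elif protein_pattern == "envelope_ring":
            r_out = max(2.5, min(0.6 * dmax + 1.0, dmax - 1.0))
            r_in = max(1.0, r_out - ring_width)
            struct = region & (d <= r_out) & (d > r_in)
        else:
            raise ValueError(f"unknown protein_pattern {protein_pattern!r}")
        image[y0:y1, x0:x1][struct] = val
        mask[y0:y1, x0:x1] |= struct
        intensity[cell] = val
    return image, mask, intensity


# ---------------------------------------------------------------------------
# degradation
# ---------------------------------------------------------------------------

def degrade(
    image: np.ndarray,
    noise_sigma: float = 5.0,
    n_autofluor_blobs: int = 0,
    autofluor_amplitude: float = 30.0,
    autofluor_sigma: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """Add i.i.d. Gaussian noise and large smooth autofluorescent blobs.

    Blobs emulate out-of-focus tissue autofluorescence: wide Gaussians
    (``autofluor_sigma`` far above the PSF scale) at random positions.
    Output is clipped at 0.  Identity when both degradations are off.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    out = np.asarray(image, float).copy()
    rng = np.random.default_rng(seed)
    if n_autofluor_blobs > 0:
        h, w = out.shape
        for _ in range(int(n_autofluor_blobs)):
            yc = rng.uniform(0, h)
            xc = rng.uniform(0, w)
            r = int(np.ceil(3 * autofluor_sigma))
            y0, y1 = max(0, int(yc) - r), min(h, int(yc) + r + 1)
            x0, x1 = max(0, int(xc) - r), min(w, int(xc) + r + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            out[y0:y1, x0:x1] += autofluor_amplitude * np.exp(
                -((yy - yc) ** 2 + (xx - xc) ** 2) / (2.0 * autofluor_sigma**2)
            )
    if noise_sigma > 0:
        out += rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# dataset orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig):
    """Generate one full multichannel dataset in memory.

    Returns ``(stack, truth)`` where ``stack`` is a (3, y, x) float array in
    channel order (wall, rna, protein) and ``truth`` is a :class:`GroundTruth`.
    One RNG stream per dataset, split per channel by fixed seed offsets.
    """
    cfg = config
    labels, wall = generate_cell_tessellation(
        cfg.n_cells, cfg.image_shape, cfg.wall_width, cfg.wall_amplitude,
        seed=cfg.seed + _SEED_TESS, background_level=cfg.background_level,
    )
    rna, spots, counts = simulate_spot_channel(
        labels, cfg.count_law, cfg.psf_sigma_xy, cfg.spot_amplitude,
        cfg.background_level, seed=cfg.seed + _SEED_SPOTS,
    )
    protein, mask, prot_levels = simulate_protein_channel(
        labels, cfg.protein_pattern, cfg.protein_mean, cfg.protein_sd,
        cfg.protein_alpha, true_counts=counts, seed=cfg.seed + _SEED_PROTEIN,
    )
    # record truth coloc flags against the protein mask
    if len(spots) and mask.any():
        iy = spots["y"].round().astype(int).clip(0, labels.shape[0] - 1)
        ix = spots["x"].round().astype(int).clip(0, labels.shape[1] - 1)
        spots["coloc_flag"] = mask[iy, ix]

    deg = dict(
        noise_sigma=cfg.noise_sigma,
        n_autofluor_blobs=cfg.n_autofluor_blobs,
        autofluor_amplitude=cfg.autofluor_amplitude,
        autofluor_sigma=cfg.autofluor_sigma,
    )
    wall = degrade(wall, seed=cfg.seed + _SEED_NOISE_WALL,
                   **{**deg, "n_autofluor_blobs": 0})
    rna = degrade(rna, seed=cfg.seed + _SEED_NOISE_RNA, **deg)
    protein = degrade(protein, seed=cfg.seed + _SEED_NOISE_PROT,
                      **{**deg, "n_autofluor_blobs": 0})

    stack = np.stack([wall, rna, protein]).astype(np.float32)
    truth = GroundTruth(label_map=labels, spots=spots, counts=counts,
                        protein=prot_levels, mask=mask)
    return stack, truth


def generate_dataset(config: SimConfig, out_dir) -> dict[str, Path]:
    """Write a simulated dataset to ``out_dir``.

    Files: ``stack.tif`` (channels wall, rna, protein), ``truth_labels.tif``,
    ``truth_mask.tif``, ``truth_spots.csv`` (z,y,x,cell_id,coloc_flag),
    ``truth_cells.csv`` (cell_id,count,protein_mean), ``config.yaml``.
    Round-trips losslessly through :func:`wmfish.io.read_stack`.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, truth = simulate_dataset(config)
    paths = {
        "stack": out / "stack.tif",
        "labels": out / "truth_labels.tif",
        "mask": out / "truth_mask.tif",
        "spots": out / "truth_spots.csv",
        "cells": out / "truth_cells.csv",
        "config": out / "config.yaml",
    }
    try:
        tifffile.imwrite(paths["stack"], stack, photometric="minisblack",
                         metadata={"axes": "CYX"})
        tifffile.imwrite(paths["labels"], truth.label_map.astype(np.uint16))
        tifffile.imwrite(paths["mask"], truth.mask.astype(np.uint8))
        truth.spots.to_csv(paths["spots"], index=False)
        cells = pd.DataFrame({
            "cell_id": truth.counts.index,
            "count": truth.counts.values,
            "protein_mean": truth.protein.reindex(truth.counts.index).values,
        })
        cells.to_csv(paths["cells"], index=False)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(asdict(config), fh, sort_keys=False)
    except OSError as exc:  # surface the failing path
        raise OSError(f"failed writing dataset to {out}: {exc}") from exc
    return paths
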