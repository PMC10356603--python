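"""File formats, run configuration and the end-to-end pipeline driver.

Conventions, enforced everywhere: coordinates are 0-based pixel indices in
(y, x) order with pixel centers at integer coordinates; CSVs are UTF-8,
comma-separated, header row, '.' decimal; label maps and masks are
single-channel TIFF; stacks are (z?, channel, y, x) with channel roles
wall / rna / protein.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import coloc as _coloc
from . import quantify as _quantify
from . import segmentation as _segmentation
from . import spots as _spots

__all__ = ["ImageStack", "RunConfig", "read_stack", "run_pipeline"]

logger = logging.getLogger(__name__)

CHANNEL_ROLES = ("wall", "rna", "protein")


@dataclass
class ImageStack:
    """Multichannel image with voxel geometry and channel roles.

    ``data`` is (channel, y, x) or (z, channel, y, x); ``channels`` maps a
    role name to its channel index.
    """

    data: np.ndarray
    channels: dict[str, int]
    pixel_size_um: Optional[float] = None
    z_step_um: Optional[float] = None
    source: Optional[str] = None

    def __post_init__(self):
        if self.data.ndim not in (3, 4):
            raise ValueError("stack must be (channel, y, x) or (z, channel, y, x)")
        n_ch = self.data.shape[-3]
        for role, idx in self.channels.items():
            if not 0 <= idx < n_ch:
                raise ValueError(f"channel_map role {role!r} -> index {idx} "
                                 f"but file has {n_ch} channels")
        if len(set(self.channels.values())) != len(self.channels):
            raise ValueError("channel roles must map to distinct indices")

    def get(self, role: str, z: int | None = None) -> np.ndarray:
        """One 2D plane of a channel role (plane 0 of a stack by default)."""
        if role not in self.channels:
            raise KeyError(f"stack has no {role!r} channel")
        idx = self.channels[role]
        if self.data.ndim == 3:
            return self.data[idx]
        return self.data[z if z is not None else 0, idx]

    @property
    def n_z(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[0]


def read_stack(path, channel_map: dict[str, int] | None = None) -> ImageStack:
    """Read a TIFF / OME-TIFF into the internal (z?, channel, y, x) order.

    ``channel_map`` assigns roles by index, e.g. ``{"wall": 0, "rna": 1}``;
    without it, a 3-channel file gets the default (wall, rna, protein)
    order.  Pixel size is taken from OME metadata when present, else left
    unknown.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        axes = tf.series[0].axes if tf.series else ""
        pixel_size = _ome_pixel_size(tf)

    if data.ndim == 2:
        data = data[None]  # single channel
        axes = "CYX"
    if data.ndim == 3 and axes and axes not in ("CYX", "QYX", "SYX", "IYX"):
        # e.g. plain multi-page TIFF reported as ZYX/IYX: pages are channels
        pass
    if data.ndim == 4 and axes == "CZYX":
        data = np.moveaxis(data, 0, 1)  # -> ZCYX

    if channel_map is None:
        n_ch = data.shape[-3]
        channel_map = {role: i for i, role in enumerate(CHANNEL_ROLES[:n_ch])}
    if pixel_size is None:
        logger.info("pixel size unknown for %s", path)
    return ImageStack(data=data, channels=dict(channel_map),
                      pixel_size_um=pixel_size, source=str(path))


def _ome_pixel_size(tf) -> Optional[float]:
    try:
        if tf.ome_metadata:
            import re
            m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tf.ome_metadata)
            if m:
                return float(m.group(1))
    except Exception:
        pass
    return None


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    input_path: str
    out_dir: str
    channel_map: dict[str, int] = field(default_factory=lambda: {"wall": 0, "rna": 1, "protein": 2})
    pixel_size_um: Optional[float] = None
    segmentation: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    coloc: Optional[dict] = None  # None disables colocalization
    background_correction: bool = False
    epsilon: float = _quantify.DEFAULT_EPSILON
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    def config_hash(self) -> str:
        # hash of the analysis parameters; output location is not part of it
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute segment -> detect -> quantify (-> coloc) -> outputs.

    Writes the label map (16-bit TIFF), spot table, cell table, threshold
    curve, heatmaps, and a diagnostics JSON to ``config.out_dir``; every
    table carries the run's config hash.  Returns a dict of output paths
    plus the in-memory tables.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logger.info("run %s: input=%s", chash, config.input_path)

    stack = read_stack(config.input_path, config.channel_map)
    wall = np.asarray(stack.get("wall"), float)

    seg_params = _segmentation.SegmentationParams(**config.segmentation)
    labels = _segmentation.segment_cells(wall, seg_params)
    logger.info("segmentation: %d cells", labels.max())
    tifffile.imwrite(out / "labels.tif", labels.astype(np.uint16))

    det_params = _spots.SpotDetectionParams(**config.detection)
    rna = np.asarray(stack.get("rna"), float)
    spot_table, curve, diag = _spots.detect_spots(rna, det_params)
    logger.info("detection: %d spots", len(spot_table))
    spot_table = _quantify.assign_spots(spot_table, labels)

    protein = None
    if "protein" in stack.channels:
        protein = np.asarray(stack.get("protein"), float)

    cell_table = _quantify.build_cell_table(
        labels, spots=spot_table, rna_channel=rna, protein_channel=protein,
        background_correction=config.background_correction, epsilon=config.epsilon,
    )

    outputs = {"labels": out / "labels.tif"}
    if config.coloc is not None:
        if protein is None:
            raise ValueError("colocalization requested but no protein channel mapped")
        cparams = _coloc.ColocParams(**config.coloc)
        mask = _coloc.segment_protein_mask(protein, labels, cparams)
        tifffile.imwrite(out / "protein_mask.tif", mask.astype(np.uint8))
        spot_table = _coloc.flag_colocalized(spot_table, mask, cparams.tolerance_radius)
        ctab = _coloc.coloc_fraction(spot_table, labels)
        cell_table["k_coloc"] = ctab["k_coloc"]
        cell_table["coloc_fraction"] = ctab["fraction"]
        outputs["protein_mask"] = out / "protein_mask.tif"

    # tables, stamped with the config hash
    spot_table = spot_table.copy()
    spot_table["config_hash"] = chash
    cell_out = cell_table.reset_index(names="cell_id")
    cell_out["config_hash"] = chash
    spot_table.to_csv(out / "spots.csv", index=False)
    cell_out.to_csv(out / "cells.csv", index=False)
    outputs["spots"] = out / "spots.csv"
    outputs["cells"] = out / "cells.csv"
    if curve is not None:
        cdf = curve.to_frame()
        cdf["selected"] = curve.selected
        cdf.to_csv(out / "threshold_curve.csv", index=False)
        outputs["threshold_curve"] = out / "threshold_curve.csv"

    # per-cell heatmaps (count, RNA mean, log ratio when available)
    heat_cols = [c for c in ("n_spots", "rna_mean", "log_ratio") if c in cell_table]
    for col in heat_cols:
        rgb, meta = _quantify.render_cell_heatmap(labels, cell_table[col])
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(rgb)
        ax.set_axis_off()
        ax.set_title(col)
        fig.savefig(out / f"heatmap_{col}.png", dpi=120, metadata={"Software": None})
        plt.close(fig)
        with open(out / f"heatmap_{col}.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        outputs[f"heatmap_{col}"] = out / f"heatmap_{col}.png"

    diag = {**diag, "n_cells": int(labels.max()), "config_hash": chash}
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2, default=float)
    outputs["diagnostics"] = out / "diagnostics.json"

    return {"outputs": outputs, "labels": labels, "spots": spot_table,
            "cells": cell_table, "diagnostics": diag}
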