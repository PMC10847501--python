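"""Image/table readers and writers plus configuration handling."""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .colorimetry import CameraModel, CMFSet
from .inversion import ParameterGrid, RecoveryResult
from .optics import StackConfig, WavelengthGrid

__all__ = [
    "read_image",
    "write_image",
    "write_result",
    "load_config",
    "stack_from_config",
    "camera_from_config",
    "parameter_grid_from_config",
    "wavelength_grid_from_config",
]

logger = logging.getLogger(__name__)


def read_image(path) -> tuple[np.ndarray, int]:
    """Read an 8/16-bit RGB PNG or TIFF; returns (raster, bit_depth)."""
    arr = iio.imread(path)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(
            f"{path}: expected a 3-channel RGB image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path}: unsupported sample type {arr.dtype}")
    return arr.astype(np.int64), depth


def write_image(path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write an integer RGB raster as PNG (8-bit) or TIFF (16-bit)."""
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    iio.imwrite(path, np.asarray(image).astype(dtype))


# 20 visually distinct colors for the indexed cluster map (tab20-like).
_PALETTE = [
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
    (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
    (188, 189, 34), (23, 190, 207), (174, 199, 232), (255, 187, 120),
    (152, 223, 138), (255, 152, 150), (197, 176, 213), (196, 156, 148),
    (247, 182, 210), (199, 199, 199), (219, 219, 141), (158, 218, 229),
]


def write_result(result: RecoveryResult, prefix) -> dict:
    """Persist a recovery: float TIFF maps, indexed cluster PNG, summary CSV.

    Background pixels are NaN in the thickness/RI/confidence maps.  Returns
    the mapping of artifact kind to written path.
    """
    prefix = str(prefix)
    paths = {
        "thickness": prefix + "_thickness.tif",
        "ri": prefix + "_ri.tif",
        "confidence": prefix + "_confidence.tif",
        "clusters": prefix + "_clusters.png",
        "summary": prefix + "_summary.csv",
    }
    conf = result.confidence_map.astype(np.float32).copy()
    conf[result.background_mask] = np.nan
    tifffile.imwrite(paths["thickness"], result.thickness_map.astype(np.float32))
    tifffile.imwrite(paths["ri"], result.ri_map.astype(np.float32))
    tifffile.imwrite(paths["confidence"], conf)

    labels = result.cluster_labels.astype(np.uint8)
    img = Image.fromarray(labels, mode="P")
    palette = []
    for i in range(256):
        palette.extend(_PALETTE[i % len(_PALETTE)])
    img.putpalette(palette)
    img.save(paths["clusters"])

    columns = [
        "cluster", "t_nm", "n", "confidence", "pooled_min_mse",
        "pixel_count", "sampled", "mean_deviation_pct",
    ]
    pd.DataFrame(result.summary, columns=columns).to_csv(paths["summary"], index=False)
    return paths


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def wavelength_grid_from_config(cfg: dict) -> WavelengthGrid:
    sub = cfg.get("wavelengths", {})
    return WavelengthGrid(
        sub.get("start_nm", 400.0), sub.get("stop_nm", 800.0), sub.get("step_nm", 1.0)
    )


def stack_from_config(cfg: dict) -> StackConfig:
    sub = cfg.get("stack", {})
    substrate = sub.get("substrate", "air")
    if substrate == "air":
        return StackConfig(ambient_index=sub.get("ambient_index", 1.0))
    if substrate == "silicon":
        return StackConfig.silicon()
    table = pd.read_csv(sub["substrate_table"], comment="#")
    return StackConfig(
        ambient_index=sub.get("ambient_index", 1.0),
        substrate="tabulated",
        substrate_index_table=table,
    )


def camera_from_config(cfg: dict) -> CameraModel:
    sub = cfg.get("camera", {})
    cmfs = None
    if sub.get("cmfs_csv"):
        cmfs = CMFSet.from_csv(sub["cmfs_csv"])
    return CameraModel(
        bit_depth=sub.get("bit_depth", 8),
        gamma=sub.get("gamma", 2.2),
        value_variation=sub.get("value_variation", 0),
        cmfs=cmfs,
    )


def parameter_grid_from_config(cfg: dict) -> ParameterGrid:
    sub = cfg.get("grid", {})
    return ParameterGrid(
        t_min=sub.get("t_min", 0.0),
        t_max=sub.get("t_max", 1200.0),
        t_step=sub.get("t_step", 1.0),
        n_min=sub.get("n_min", 1.33),
        n_max=sub.get("n_max", 1.55),
        n_step=sub.get("n_step", 1e-3),
    )
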