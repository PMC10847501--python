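"""Resolution limits of color-based film metrology vs camera bit depth.

Two films can only be told apart if their quantized RGB triplets differ by
more than the camera's pixel-value instability ``v`` in at least one channel.
For a given bit depth and ``v``, the resolution along an axis (thickness or
RI) is the smallest separation ``delta`` such that *every* reference
structure over the biological parameter range remains distinguishable from
its ``delta``-shifted twin (worst case over references).  Separations are
probed on a logarithmic ladder; the ladder ceiling is returned when no probed
separation qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .colorimetry import CameraModel, spectra_to_rgb
from .optics import StackConfig, WavelengthGrid, tmm_reflectance

__all__ = ["SensitivityConfig", "resolution_limit", "sensitivity_curves"]


@dataclass
class SensitivityConfig:
    bit_depths: Sequence[int] = (8, 10, 12, 14, 16)
    variations: Sequence[int] = (0, 1, 2)
    reference_thicknesses: Sequence[float] = (300.0, 450.0, 600.0, 750.0)
    ri_range: tuple = (1.33, 1.55)
    ri_samples: int = 21
    # log-ladder floors/ceilings per axis
    ri_floor: float = 1e-6
    ri_ceiling: float = 0.1
    t_floor_nm: float = 0.01
    t_ceiling_nm: float = 100.0
    probes_per_decade: int = 10
    wavelength_grid: WavelengthGrid = field(default_factory=WavelengthGrid)

    def __post_init__(self) -> None:
        if len(self.bit_depths) == 0:
            raise ValueError("bit_depths must be non-empty")
        if self.ri_floor <= 0 or self.t_floor_nm <= 0:
            raise ValueError("search floors must be positive")

    def references(self) -> tuple:
        """(t, n) reference pairs covering the biological range."""
        if self.ri_samples < 1 or len(self.reference_thicknesses) == 0:
            raise ValueError("empty reference sampling")
        ns = np.linspace(*self.ri_range, self.ri_samples)
        tt, nn = np.meshgrid(self.reference_thicknesses, ns, indexing="ij")
        return tt.ravel(), nn.ravel()

    def probe_ladder(self, axis: str) -> np.ndarray:
        lo, hi = (
            (self.ri_floor, self.ri_ceiling)
            if axis == "ri"
            else (self.t_floor_nm, self.t_ceiling_nm)
        )
        decades = np.log10(hi) - np.log10(lo)
        count = int(round(decades * self.probes_per_decade)) + 1
        return np.logspace(np.log10(lo), np.log10(hi), count)


def _quantize(t, n, stack, camera, grid: WavelengthGrid) -> np.ndarray:
    spectra = tmm_reflectance(
        np.asarray(t)[:, None], np.asarray(n)[:, None], grid.wavelengths[None, :], stack
    )
    return spectra_to_rgb(spectra, grid, camera)


def resolution_limit(
    axis: str,
    bit_depth: int,
    variation: int,
    config: SensitivityConfig = SensitivityConfig(),
    stack: StackConfig = StackConfig(),
) -> float:
    """Smallest probed separation distinguishable at every reference structure.

    Distinguishable means at least one channel of the quantized triplets
    differs by more than ``variation`` code values.
    """
    if axis not in ("thickness", "ri"):
        raise ValueError("axis must be 'thickness' or 'ri'")
    camera = CameraModel(bit_depth=bit_depth)
    grid = config.wavelength_grid
    t_ref, n_ref = config.references()
    base = _quantize(t_ref, n_ref, stack, camera, grid).astype(np.int64)
    ladder = config.probe_ladder(axis)
    for delta in ladder:
        if axis == "ri":
            shifted = _quantize(t_ref, n_ref + delta, stack, camera, grid)
        else:
            shifted = _quantize(t_ref + delta, n_ref, stack, camera, grid)
        diff = np.abs(shifted.astype(np.int64) - base).max(axis=1)
        if np.all(diff > variation):
            return float(delta)
    return float(ladder[-1])


def sensitivity_curves(
    config: SensitivityConfig = SensitivityConfig(),
    stack: StackConfig = StackConfig(),
) -> pd.DataFrame:
    """Full sweep: one row per (axis, bit_depth, variation)."""
    rows = []
    for axis in ("ri", "thickness"):
        for b in config.bit_depths:
            for v in config.variations:
                rows.append(
                    {
                        "axis": axis,
                        "bit_depth": int(b),
                        "variation": int(v),
                        "resolution": resolution_limit(axis, b, v, config, stack),
                    }
                )
    return pd.DataFrame(rows)
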