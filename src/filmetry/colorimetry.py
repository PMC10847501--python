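"""Camera colorimetry: reflectance spectrum -> quantized RGB code values.

The simulated camera reproduces the color pipeline used to render thin-film
interference colors: numerical integration of the reflectance spectrum with
the CIE 1931 2-degree observer color-matching functions, conversion to a
normalized linear RGB space with the standard sRGB/D65 matrix, gamut handling
(scale so the maximum component is 1.0, clip negatives to 0.0), a pure
power-law gamma of 2.2, and rescaling/rounding to the integer code-value range
of the camera's bit depth.  Optional integer jitter per channel models pixel
value instability of real sensors.

A :class:`CMFSet` may alternatively hold a *camera's* native r/g/b sensitivity
curves (``space="rgb"``), in which case the integration yields linear RGB
directly and no matrix is applied; learned CMFs use this mode.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .optics import Spectrum, WavelengthGrid

__all__ = [
    "CMFSet",
    "CameraModel",
    "cie_1931_cmfs",
    "spectrum_to_tristimulus",
    "tristimulus_to_linear_rgb",
    "encode_rgb",
    "decode_rgb",
    "simulate_camera",
    "spectra_to_rgb",
    "XYZ_TO_LINEAR_SRGB",
]

# Standard sRGB (D65 reference white) XYZ -> linear RGB matrix.
XYZ_TO_LINEAR_SRGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


@dataclass
class CMFSet:
    """Three sensitivity curves on a wavelength grid.

    ``space`` is ``"xyz"`` for observer-style curves (x, y, z; converted to RGB
    by matrix) or ``"rgb"`` for native camera curves used directly.
    ``normalized`` controls whether integration divides by the luminance-curve
    integral (True for the bundled observer; learned absolute curves use
    False).
    """

    grid: WavelengthGrid
    curves: np.ndarray  # shape (3, n_wavelengths)
    space: str = "xyz"
    normalized: bool = True
    # Physical sensitivities are non-negative; unconstrained fits may produce
    # signed "effective" curves (e.g. matrix-mixed observer curves).
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.shape != (3, len(self.grid)):
            raise ValueError("curves must have shape (3, len(grid))")
        if not self.allow_negative and np.any(self.curves < 0):
            raise ValueError("sensitivity curves must be non-negative")
        if self.space not in ("xyz", "rgb"):
            raise ValueError(f"unknown CMF space {self.space!r}")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": self.grid.wavelengths,
                "r": self.curves[0],
                "g": self.curves[1],
                "b": self.curves[2],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, space: str = "rgb", normalized: bool = False) -> "CMFSet":
        df = pd.read_csv(path, comment="#")
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(wl[1] - wl[0]))
        cols = ["r", "g", "b"] if "r" in df.columns else ["x", "y", "z"]
        curves = np.stack([df[c].to_numpy(dtype=float) for c in cols])
        return cls(grid, curves, space=space, normalized=normalized)


def cie_1931_cmfs(grid: WavelengthGrid = WavelengthGrid()) -> CMFSet:
    """Bundled CIE 1931 2-degree observer CMFs interpolated onto ``grid``."""
    ref = importlib.resources.files("filmetry.data") / "cie1931_2deg_1nm.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    target = grid.wavelengths
    if target.min() < wl.min() or target.max() > wl.max():
        raise ValueError("requested grid outside the bundled CMF table range")
    curves = np.stack(
        [np.interp(target, wl, df[c].to_numpy(dtype=float)) for c in ("x", "y", "z")]
    )
    return CMFSet(grid, curves, space="xyz", normalized=True)


@dataclass
class CameraModel:
    """Quantizing camera: bit depth B, power-law gamma, integer value jitter v."""

    bit_depth: int = 8
    gamma: float = 2.2
    value_variation: int = 0
    cmfs: Optional[CMFSet] = None

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 10, 12, 14, 16):
            raise ValueError("bit_depth must be one of 8, 10, 12, 14, 16")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.value_variation < 0:
            raise ValueError("value_variation must be >= 0")

    @property
    def max_code(self) -> int:
        return (1 << self.bit_depth) - 1

    def resolved_cmfs(self, grid: WavelengthGrid) -> CMFSet:
        if self.cmfs is not None:
            return self.cmfs
        return cie_1931_cmfs(grid)

    def with_bit_depth(self, bit_depth: int) -> "CameraModel":
        return replace(self, bit_depth=bit_depth)

    def fingerprint(self) -> str:
        c = self.cmfs
        cmf_tag = "cie1931" if c is None else f"custom(sum={c.curves.sum():.6f},{c.space})"
        return f"B={self.bit_depth},gamma={self.gamma:g},v={self.value_variation},cmfs={cmf_tag}"


def _check_same_grid(a: WavelengthGrid, b: WavelengthGrid) -> None:
    if a != b:
        raise ValueError(f"wavelength grid mismatch: {a} vs {b}")


def spectrum_to_tristimulus(
    spectrum: Spectrum, cmfs: CMFSet, illuminant: Optional[Spectrum] = None
) -> np.ndarray:
    """Integrate a reflectance spectrum against the three sensitivity curves.

    Components are ``sum(S * I * curve) * step``, divided (for normalized CMF
    sets) by ``sum(I * y) * step`` so that a perfect reflector under the
    illuminant has luminance component exactly 1.0.  The default illuminant is
    flat (equal energy).
    """
    _check_same_grid(spectrum.grid, cmfs.grid)
    spd = spectrum.values
    if illuminant is not None:
        _check_same_grid(spectrum.grid, illuminant.grid)
        spd = spd * illuminant.values
        weight = illuminant.values
    else:
        weight = np.ones_like(spd)
    step = spectrum.grid.step_nm
    raw = cmfs.curves @ spd * step
    if cmfs.normalized:
        raw = raw / (float(cmfs.curves[1] @ weight) * step)
    return raw


def tristimulus_to_linear_rgb(xyz: np.ndarray, space: str = "xyz") -> np.ndarray:
    """Matrix conversion plus gamut handling (scale max to 1, clip negatives)."""
    xyz = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("tristimulus values must be finite")
    rgb = xyz @ XYZ_TO_LINEAR_SRGB.T if space == "xyz" else xyz.copy()
    peak = rgb.max(axis=-1, keepdims=True)
    scale = np.where(peak > 1.0, peak, 1.0)
    rgb = rgb / scale
    return np.clip(rgb, 0.0, 1.0)


def encode_rgb(linear: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Gamma-encode and quantize: ``round(c**(1/gamma) * (2**B - 1))``.

    Rounding is half-away-from-zero (values are non-negative, so
    ``floor(x + 0.5)``).
    """
    linear = np.asarray(linear, dtype=float)
    if np.any(linear < 0) or np.any(linear > 1):
        raise ValueError("linear components must lie in [0, 1]")
    encoded = np.power(linear, 1.0 / camera.gamma)
    codes = np.floor(encoded * camera.max_code + 0.5).astype(np.int32)
    return codes


def decode_rgb(codes: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Inverse of :func:`encode_rgb` up to quantization: code -> linear value."""
    codes = np.asarray(codes, dtype=float)
    return np.power(codes / camera.max_code, camera.gamma)


def _apply_jitter(codes: np.ndarray, camera: CameraModel, rng: np.random.Generator) -> np.ndarray:
    v = camera.value_variation
    if v == 0:
        return codes
    jitter = rng.integers(-v, v + 1, size=codes.shape, dtype=np.int32)
    return np.clip(codes + jitter, 0, camera.max_code)


def simulate_camera(
    spectrum: Spectrum,
    camera: CameraModel,
    seed: int | np.random.Generator | None = 0,
    illuminant: Optional[Spectrum] = None,
) -> np.ndarray:
    """Full spectrum -> quantized RGB triplet pipeline, with optional jitter."""
    cmfs = camera.resolved_cmfs(spectrum.grid)
    tri = spectrum_to_tristimulus(spectrum, cmfs, illuminant)
    linear = tristimulus_to_linear_rgb(tri, space=cmfs.space)
    codes = encode_rgb(linear, camera)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _apply_jitter(codes, camera, rng)


def spectra_to_rgb(
    spectra: np.ndarray,
    grid: WavelengthGrid,
    camera: CameraModel,
    illuminant: Optional[Spectrum] = None,
) -> np.ndarray:
    """Vectorized jitter-free pipeline for an (N, n_wavelengths) spectrum batch."""
    spectra = np.asarray(spectra, dtype=float)
    cmfs = camera.resolved_cmfs(grid)
    spd = spectra
    if illuminant is not None:
        _check_same_grid(grid, illuminant.grid)
        spd = spd * illuminant.values
        weight = illuminant.values
    else:
        weight = np.ones(len(grid))
    tri = spd @ cmfs.curves.T * grid.step_nm
    if cmfs.normalized:
        tri = tri / (float(cmfs.curves[1] @ weight) * grid.step_nm)
    linear = tristimulus_to_linear_rgb(tri, space=cmfs.space)
    return encode_rgb(linear, camera)
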