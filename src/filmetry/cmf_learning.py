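"""Supervised estimation of camera color-matching functions.

A camera's channel response to a reflectance spectrum is linear in the
spectrum once the gamma encoding is inverted.  Expanding each unknown
sensitivity curve on smooth non-linear basis functions (Gaussian radial
functions by default) turns CMF estimation from (spectrum, RGB) pairs into
ridge-regularized linear least squares per channel, optionally with a
non-negativity constraint on the basis coefficients.  The basis size controls
the spectral resolution of the recovered curves.

The learned :class:`~filmetry.colorimetry.CMFSet` is returned in camera
("rgb") space with absolute scaling (``normalized=False``): its integrals map
spectra directly to linear channel values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .colorimetry import CameraModel, CMFSet, decode_rgb, simulate_camera
from .optics import FilmParams, Spectrum, WavelengthGrid

__all__ = [
    "TrainingPair",
    "BasisConfig",
    "basis_matrix",
    "fit_cmfs",
    "predict_rgb",
    "validate_cmfs",
]


@dataclass
class TrainingPair:
    """One calibration film: its reflectance spectrum and the observed triplet."""

    spectrum: Spectrum
    observed_rgb: np.ndarray
    film_meta: Optional[FilmParams] = None

    def __post_init__(self) -> None:
        self.observed_rgb = np.asarray(self.observed_rgb)
        if self.observed_rgb.shape != (3,):
            raise ValueError("observed_rgb must be a triplet")


@dataclass
class BasisConfig:
    """Regression basis: family, size, kernel width, ridge weight, constraint."""

    kind: str = "gaussian_rbf"
    count: int = 24
    width_nm: Optional[float] = None  # default: 1.5x the center spacing
    ridge: float = 1e-6
    nonneg: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_rbf", "bspline"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.count < 3:
            raise ValueError("count must be >= 3")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")


def basis_matrix(grid: WavelengthGrid, basis: BasisConfig) -> np.ndarray:
    """Evaluate the basis functions on the grid; shape (n_wavelengths, count)."""
    wl = grid.wavelengths
    centers = np.linspace(wl[0], wl[-1], basis.count)
    spacing = centers[1] - centers[0]
    width = basis.width_nm if basis.width_nm is not None else 1.5 * spacing
    if basis.kind == "gaussian_rbf":
        return np.exp(-0.5 * ((wl[:, None] - centers[None, :]) / width) ** 2)
    # Cubic B-spline bumps on the same centers; width scales the support.
    u = np.abs(wl[:, None] - centers[None, :]) / width
    out = np.zeros_like(u)
    m1 = u < 1
    out[m1] = (4 - 6 * u[m1] ** 2 + 3 * u[m1] ** 3) / 6
    m2 = (u >= 1) & (u < 2)
    out[m2] = (2 - u[m2]) ** 3 / 6
    return out


def _features(spectra: np.ndarray, grid: WavelengthGrid, basis: BasisConfig) -> np.ndarray:
    # y_channel = sum_l S(l) C(l) dl with C = Phi @ w  =>  y = (S @ Phi * dl) @ w
    phi = basis_matrix(grid, basis)
    return spectra @ phi * grid.step_nm


def fit_cmfs(
    pairs: Sequence[TrainingPair],
    basis: BasisConfig = BasisConfig(),
    camera_gamma: float = 2.2,
    bit_depth: int = 8,
) -> CMFSet:
    """Least-squares CMF estimate from (spectrum, RGB) calibration pairs.

    Observed code values are linearized (rescaled to [0, 1] and inverse-gamma
    mapped) so the model is linear in the basis coefficients.  With
    ``basis.nonneg`` the coefficients are constrained non-negative (NNLS on
    the ridge-augmented system), which guarantees non-negative curves for
    non-negative bases.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    grid = pairs[0].spectrum.grid
    for p in pairs:
        if p.spectrum.grid != grid:
            raise ValueError("all training spectra must share one wavelength grid")
    if basis.ridge == 0 and len(pairs) < basis.count:
        raise ValueError(
            f"underdetermined fit: {len(pairs)} pairs for {basis.count} basis "
            "functions with ridge=0; add pairs, reduce count, or set ridge > 0"
        )

    spectra = np.stack([p.spectrum.values for p in pairs])
    codes = np.stack([p.observed_rgb for p in pairs]).astype(float)
    camera = CameraModel(bit_depth=bit_depth, gamma=camera_gamma)
    linear = decode_rgb(codes, camera)  # (n_pairs, 3)

    F = _features(spectra, grid, basis)  # (n_pairs, count)
    k = basis.count
    if basis.ridge > 0:
        A = np.vstack([F, np.sqrt(basis.ridge) * np.eye(k)])
        pad = np.zeros((k, 3))
        Y = np.vstack([linear, pad])
    else:
        A, Y = F, linear

    coefs = np.empty((3, k))
    for c in range(3):
        if basis.nonneg:
            coefs[c], _ = nnls(A, Y[:, c])
        else:
            coefs[c] = np.linalg.lstsq(A, Y[:, c], rcond=None)[0]

    phi = basis_matrix(grid, basis)
    curves = coefs @ phi.T
    return CMFSet(
        grid, curves, space="rgb", normalized=False, allow_negative=not basis.nonneg
    )


def make_training_pairs(
    camera: CameraModel,
    stack=None,
    grid: WavelengthGrid = WavelengthGrid(),
    n_films: int = 65,
    t_range_nm: tuple = (50.0, 1000.0),
    n_range: tuple = (1.45, 1.50),
    seed: int = 0,
) -> list[TrainingPair]:
    """Synthetic calibration set emulating spin-coated polymer films on silicon.

    Thickness and index sweep their ranges jointly (evenly spaced pairs), the
    default ranges matching a PMMA-on-silicon wafer series.  Observed triplets
    come from the camera model itself (including its jitter setting).
    """
    from .optics import StackConfig, reflectance_spectrum

    if stack is None:
        stack = StackConfig.silicon()
    ts = np.linspace(*t_range_nm, n_films)
    ns = np.linspace(*n_range, n_films)
    rng = np.random.default_rng(seed)
    pairs = []
    for t, n in zip(ts, ns):
        film = FilmParams(t, n)
        spec = reflectance_spectrum(film, stack, grid)
        rgb = simulate_camera(spec, camera, seed=rng)
        pairs.append(TrainingPair(spec, rgb, film_meta=film))
    return pairs


def predict_rgb(cmfs: CMFSet, spectrum: Spectrum, camera: CameraModel) -> np.ndarray:
    """Jitter-free forward prediction through a learned CMF set."""
    cam = CameraModel(
        bit_depth=camera.bit_depth, gamma=camera.gamma, value_variation=0, cmfs=cmfs
    )
    return simulate_camera(spectrum, cam, seed=0)


def validate_cmfs(
    cmfs: CMFSet, heldout: Sequence[TrainingPair], camera: CameraModel
) -> dict:
    """Per-channel RMSE and max absolute error (code values) on held-out pairs."""
    if len(heldout) == 0:
        raise ValueError("heldout set must be non-empty")
    preds = np.stack([predict_rgb(cmfs, p.spectrum, camera) for p in heldout])
    obs = np.stack([p.observed_rgb for p in heldout]).astype(float)
    err = preds - obs
    return {
        "rmse": np.sqrt(np.mean(err**2, axis=0)),
        "max_error": np.max(np.abs(err), axis=0),
        "n": len(heldout),
    }
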