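"""Phantom generator: camera images with known (thickness, RI) ground truth.

Phantoms emulate micrographs of dehydrated specimens stretched on the dark
nanostructured substrate: a bright thin-film foreground over a near-black
background (the substrate reflects only a few percent of visible light),
optional dark occlusion spots where supporting pillars show through, and
integer pixel-value jitter of a few code values.  Every generator is
deterministic in its seed, and the truth maps let each pipeline stage be
tested end to end without experimental data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .colorimetry import CameraModel, spectra_to_rgb
from .optics import FilmParams, StackConfig, WavelengthGrid, tmm_reflectance

__all__ = [
    "Phantom",
    "make_uniform_cell_phantom",
    "make_gradient_cell_phantom",
    "make_metamer_phantom",
]

# Default pixel pitch: 0.1 um per pixel, so a ~30 um specimen spans ~300 px,
# matching the scale of a x100 objective on a typical sensor.
PIXEL_PITCH_UM = 0.1


@dataclass
class Phantom:
    rgb_image: np.ndarray  # (H, W, 3) integer code values
    truth_thickness: np.ndarray  # nm, NaN on background
    truth_ri: np.ndarray  # NaN on background
    foreground_mask: np.ndarray  # True on recoverable film pixels
    occlusion_mask: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        shape = self.rgb_image.shape[:2]
        for arr in (self.truth_thickness, self.truth_ri, self.foreground_mask,
                    self.occlusion_mask):
            if arr.shape != shape:
                raise ValueError("truth/mask shapes must match the image")


def film_rgb(
    t_nm: float,
    n: float,
    camera: CameraModel,
    stack: StackConfig = StackConfig(),
    grid: WavelengthGrid = WavelengthGrid(),
) -> np.ndarray:
    """Jitter-free quantized triplet of a single film."""
    spectra = tmm_reflectance(
        np.array([[t_nm]]), np.array([[n]]), grid.wavelengths[None, :], stack
    )
    return spectra_to_rgb(spectra, grid, camera)[0]


def _background_level(camera: CameraModel, pct: float = 1.0) -> int:
    return int(round(camera.max_code * pct / 100.0))


def _jitter_image(image: np.ndarray, camera: CameraModel, rng) -> np.ndarray:
    v = camera.value_variation
    if v == 0:
        return image
    jit = rng.integers(-v, v + 1, size=image.shape, dtype=np.int64)
    return np.clip(image + jit, 0, camera.max_code)


def _finalize(image, camera):
    dtype = np.uint16 if camera.bit_depth > 8 else np.uint8
    return image.astype(dtype)


def make_uniform_cell_phantom(
    t_nm: float,
    n: float,
    side_px: int,
    camera: CameraModel,
    stack: StackConfig = StackConfig(),
    n_occlusions: int = 0,
    seed: int = 0,
    *,
    cell_fraction: float = 0.6,
    background_pct: float = 1.0,
    grid: WavelengthGrid = WavelengthGrid(),
) -> Phantom:
    """Uniform square specimen of constant (t, n) on a near-black background.

    Occlusions are dark circular spots (substrate pillars seen through the
    film) placed without overlap inside the cell.
    """
    if side_px < 8:
        raise ValueError("side_px must be >= 8")
    rng = np.random.default_rng(seed)
    base = film_rgb(t_nm, n, camera, stack, grid)
    bg = _background_level(camera, background_pct)

    image = np.full((side_px, side_px, 3), bg, dtype=np.int64)
    cell = int(round(side_px * cell_fraction))
    lo = (side_px - cell) // 2
    hi = lo + cell
    fg = np.zeros((side_px, side_px), dtype=bool)
    fg[lo:hi, lo:hi] = True

    occl = np.zeros_like(fg)
    if n_occlusions > 0:
        radius = max(2, cell // 12)
        if n_occlusions * math.pi * radius**2 >= cell**2:
            raise ValueError("occlusions exceed the foreground area")
        yy, xx = np.mgrid[0:side_px, 0:side_px]
        centers = []
        attempts = 0
        while len(centers) < n_occlusions:
            attempts += 1
            if attempts > 1000 * n_occlusions:
                raise ValueError("could not place non-overlapping occlusions")
            cy = rng.integers(lo + radius + 1, hi - radius - 1)
            cx = rng.integers(lo + radius + 1, hi - radius - 1)
            if any((cy - y) ** 2 + (cx - x) ** 2 <= (2 * radius + 2) ** 2
                   for y, x in centers):
                continue
            centers.append((cy, cx))
            occl |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    film_mask = fg & ~occl
    image[film_mask] = base
    image = _jitter_image(image, camera, rng)

    truth_t = np.full((side_px, side_px), np.nan)
    truth_n = np.full((side_px, side_px), np.nan)
    truth_t[film_mask] = t_nm
    truth_n[film_mask] = n
    return Phantom(_finalize(image, camera), truth_t, truth_n, film_mask, occl, seed)


def make_gradient_cell_phantom(
    t_range_nm: tuple,
    n_range: tuple,
    shape: tuple,
    camera: CameraModel,
    stack: StackConfig = StackConfig(),
    seed: int = 0,
    *,
    raised_edge: bool = False,
    t_snap_nm: float = 1.0,
    n_snap: float = 1e-3,
    background_pct: float = 1.0,
    grid: WavelengthGrid = WavelengthGrid(),
) -> Phantom:
    """Elliptical specimen with smoothly varying thickness and RI fields.

    Thickness ramps linearly across the specimen and RI varies radially; both
    fields are affinely rescaled so their extrema equal the requested range
    ends, then snapped to the given grid steps (the recovery table can only
    return grid nodes).  ``raised_edge`` adds a thickness bump near the
    specimen boundary, mimicking the raised rim of stretched specimens.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h * 0.4, w * 0.4
    rad = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    fg = rad <= 1.0

    def rescale(fieldvals, lo, hi):
        vals = fieldvals[fg]
        vmin, vmax = vals.min(), vals.max()
        if vmax == vmin:
            return np.full_like(fieldvals, 0.5 * (lo + hi))
        return lo + (fieldvals - vmin) * (hi - lo) / (vmax - vmin)

    t_field = xx.astype(float)
    if raised_edge:
        t_field = t_field + 0.3 * (w) * np.clip(rad - 0.7, 0, None) / 0.3
    t_field = rescale(t_field, *t_range_nm)
    n_field = rescale(np.sqrt(rad), *n_range)

    t_field = np.round(t_field / t_snap_nm) * t_snap_nm
    n_field = np.round(n_field / n_snap) * n_snap

    bg = _background_level(camera, background_pct)
    image = np.full((h, w, 3), bg, dtype=np.int64)
    pairs = np.stack([t_field[fg], n_field[fg]], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    spectra = tmm_reflectance(
        uniq[:, 0:1], uniq[:, 1:2], grid.wavelengths[None, :], stack
    )
    colors = spectra_to_rgb(spectra, grid, camera)
    image[fg] = colors[inverse]
    image = _jitter_image(image, camera, rng)

    truth_t = np.full((h, w), np.nan)
    truth_n = np.full((h, w), np.nan)
    truth_t[fg] = t_field[fg]
    truth_n[fg] = n_field[fg]
    occl = np.zeros((h, w), dtype=bool)
    return Phantom(_finalize(image, camera), truth_t, truth_n, fg, occl, seed)


def make_metamer_phantom(
    pair: tuple,
    which: int,
    n_px: int,
    camera: CameraModel,
    stack: StackConfig = StackConfig(),
    seed: int = 0,
    *,
    closeness_bound: int = 12,
    grid: WavelengthGrid = WavelengthGrid(),
) -> Phantom:
    """Uniform patch of one member of a metameric film pair.

    The pair must actually be metameric under the camera: the two jitter-free
    triplets may differ by at most ``closeness_bound`` code values in any
    channel, otherwise the pair is rejected with the observed distances.
    """
    a, b = pair
    if not isinstance(a, FilmParams):
        a, b = FilmParams(*a), FilmParams(*b)
    if which not in (0, 1):
        raise ValueError("which must be 0 or 1")
    rgb_a = film_rgb(a.thickness_nm, a.refractive_index, camera, stack, grid)
    rgb_b = film_rgb(b.thickness_nm, b.refractive_index, camera, stack, grid)
    dist = np.abs(rgb_a.astype(np.int64) - rgb_b.astype(np.int64))
    if dist.max() > closeness_bound:
        raise ValueError(
            f"pair is not metameric at bound {closeness_bound}: "
            f"channel distances {dist.tolist()} (triplets {rgb_a.tolist()} "
            f"vs {rgb_b.tolist()})"
        )
    member = (a, b)[which]
    color = (rgb_a, rgb_b)[which]
    side = math.ceil(math.sqrt(n_px))
    rng = np.random.default_rng(seed)
    image = np.tile(color.astype(np.int64), (side, side, 1))
    image = _jitter_image(image, camera, rng)
    truth_t = np.full((side, side), member.thickness_nm)
    truth_n = np.full((side, side), member.refractive_index)
    fg = np.ones((side, side), dtype=bool)
    occl = np.zeros((side, side), dtype=bool)
    return Phantom(_finalize(image, camera), truth_t, truth_n, fg, occl, seed)
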