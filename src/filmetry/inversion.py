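"""Machine-learning recovery of per-pixel thickness and refractive index.

The inverse problem is solved by grid search against a precomputed lookup
table: simulate the quantized RGB triplet of every (thickness, RI) node once,
then, for each group of similarly colored pixels, compare observed and
simulated triplets through the mean-square-error cost

    MSE(t, n) = (1/3) * sum_i (X_i - Xhat_i(t, n))^2

where X is the measured triplet and Xhat the table entry.  Because distinct
films can map to nearly identical triplets (metamerism), per-pixel cost maps
may carry several local minima; averaging ("pooling") the cost maps of many
pixels from one color cluster suppresses the spurious minima and leaves a
single basin at the true parameters.

Pixels are grouped by k-means on their RGB values, growing the cluster count
until the average relative deviation from the cluster centroids falls below a
threshold (2% by default); dark clusters are flagged as the substrate
background and excluded from recovery.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .colorimetry import CameraModel, spectra_to_rgb
from .optics import StackConfig, WavelengthGrid, tmm_reflectance

__all__ = [
    "ParameterGrid",
    "RGBTable",
    "ClusterSet",
    "CostMap",
    "RecoveryResult",
    "build_lut",
    "cluster_pixels",
    "cost_map",
    "candidate_probabilities",
    "pool_cost_maps",
    "pooled_cost_map",
    "recover_maps",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12  # regularizer in the inverse-MSE probability rule

# Rec. 709 luma weights, applied to gamma-decoded (linear) channel values.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class ParameterGrid:
    """Search grid over thickness (nm) and refractive index."""

    t_min: float = 0.0
    t_max: float = 1200.0
    t_step: float = 1.0
    n_min: float = 1.33
    n_max: float = 1.55
    n_step: float = 1e-3

    def __post_init__(self) -> None:
        if self.t_step <= 0 or self.n_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.t_min > self.t_max or self.n_min > self.n_max:
            raise ValueError("grid bounds out of order")

    @property
    def t_values(self) -> np.ndarray:
        k = int(round((self.t_max - self.t_min) / self.t_step)) + 1
        return self.t_min + self.t_step * np.arange(k)

    @property
    def n_values(self) -> np.ndarray:
        k = int(round((self.n_max - self.n_min) / self.n_step)) + 1
        return self.n_min + self.n_step * np.arange(k)

    @property
    def shape(self) -> tuple:
        return (len(self.t_values), len(self.n_values))


class CandidateMin(NamedTuple):
    t_nm: float
    n: float
    mse: float
    probability: float


@dataclass
class RGBTable:
    """Quantized RGB triplet per (t, n) grid node, plus build provenance."""

    grid: ParameterGrid
    entries: np.ndarray  # (n_t, n_n, 3) int32
    bit_depth: int
    fingerprint: str = ""

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int32)
        if self.entries.shape != self.grid.shape + (3,):
            raise ValueError("entries shape does not match grid")
        if self.entries.min() < 0 or self.entries.max() > (1 << self.bit_depth) - 1:
            raise ValueError("table entries outside the camera code range")
        if not self.fingerprint:
            self.fingerprint = _table_digest(self.entries)

    def to_csv(self, path, sidecar: Optional[str] = None) -> None:
        tt, nn = np.meshgrid(self.grid.t_values, self.grid.n_values, indexing="ij")
        flat = self.entries.reshape(-1, 3)
        pd.DataFrame(
            {
                "t_nm": tt.ravel(),
                "n": nn.ravel(),
                "r": flat[:, 0],
                "g": flat[:, 1],
                "b": flat[:, 2],
            }
        ).to_csv(path, index=False)
        meta = {
            "grid": vars(self.grid) if not hasattr(self.grid, "__dataclass_fields__")
            else {f: getattr(self.grid, f) for f in self.grid.__dataclass_fields__},
            "bit_depth": self.bit_depth,
            "fingerprint": self.fingerprint,
        }
        sidecar = sidecar or str(path) + ".meta.json"
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path, sidecar: Optional[str] = None) -> "RGBTable":
        sidecar = sidecar or str(path) + ".meta.json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        grid = ParameterGrid(**meta["grid"])
        df = pd.read_csv(path)
        entries = df[["r", "g", "b"]].to_numpy(dtype=np.int32).reshape(grid.shape + (3,))
        return cls(grid, entries, meta["bit_depth"], meta["fingerprint"])


def _table_digest(entries: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(entries).tobytes()).hexdigest()[:16]


def build_lut(
    grid: ParameterGrid,
    stack: StackConfig = StackConfig(),
    camera: CameraModel = None,
    wavelength_grid: WavelengthGrid = WavelengthGrid(),
) -> RGBTable:
    """Simulate the jitter-free RGB triplet at every (t, n) node."""
    camera = camera or CameraModel()
    t_vals = grid.t_values
    n_vals = grid.n_values
    wl = wavelength_grid.wavelengths
    entries = np.empty(grid.shape + (3,), dtype=np.int32)
    for j, n in enumerate(n_vals):  # chunk over RI to bound memory
        spectra = tmm_reflectance(t_vals[:, None], n, wl[None, :], stack)
        entries[:, j, :] = spectra_to_rgb(spectra, wavelength_grid, camera)
    config = (
        f"{grid}|{stack.fingerprint()}|B={camera.bit_depth},gamma={camera.gamma:g},"
        f"cmfs={'cie1931' if camera.cmfs is None else 'custom'}|{wavelength_grid}"
    )
    digest = hashlib.sha256(
        config.encode() + np.ascontiguousarray(entries).tobytes()
    ).hexdigest()[:16]
    return RGBTable(grid, entries, camera.bit_depth, fingerprint=digest)


# ---------------------------------------------------------------------------
# Pixel clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterSet:
    labels: np.ndarray  # per-pixel cluster id, image shape
    centroids: np.ndarray  # (k, 3)
    mean_deviation_pct: np.ndarray  # (k,)
    background_ids: set = field(default_factory=set)

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    @property
    def foreground_ids(self) -> list:
        return [i for i in range(self.n_clusters) if i not in self.background_ids]


def _cluster_deviations(pixels: np.ndarray, labels: np.ndarray, centroids: np.ndarray):
    """Mean relative deviation (%) of pixels from their centroid, per cluster."""
    devs = np.empty(len(centroids))
    for cid, c in enumerate(centroids):
        members = pixels[labels == cid]
        norm = np.linalg.norm(c)
        if len(members) == 0:
            devs[cid] = 0.0
            continue
        dist = np.linalg.norm(members - c, axis=1)
        if norm == 0:
            devs[cid] = 0.0 if np.all(dist == 0) else np.inf
        else:
            devs[cid] = 100.0 * float(np.mean(dist)) / norm
    return devs


def _background_flags(
    centroids: np.ndarray, bit_depth: int, gamma: float, cutoff_pct: float
) -> np.ndarray:
    # Substrate pixels have uniformly low code values; a cluster is background
    # when every centroid channel sits below the cutoff fraction of full
    # scale.  (A decoded-luminance cutoff would misclassify attainable
    # free-standing-film colors, whose peak reflectance is only ~15%.)
    max_code = (1 << bit_depth) - 1
    del gamma  # kept for signature stability; cutoff acts on code values
    return np.max(centroids, axis=1) < cutoff_pct / 100.0 * max_code


def cluster_pixels(
    image: np.ndarray,
    deviation_threshold_pct: float = 2.0,
    seed: int = 0,
    *,
    bit_depth: Optional[int] = None,
    gamma: float = 2.2,
    max_k: int = 100,
    background_cutoff_pct: float = 5.0,
) -> ClusterSet:
    """k-means color segmentation with an automatically chosen cluster count.

    k grows from 1 until the across-cluster average of the mean relative
    deviation from the centroid (foreground clusters only) drops below the
    threshold.  Clusters whose gamma-decoded centroid luminance is below
    ``background_cutoff_pct`` of full scale are flagged as substrate
    background.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image is empty")
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("image must be an (H, W, 3) raster")
    if bit_depth is None:
        bit_depth = 16 if image.dtype == np.uint16 else 8
    pixels = image.reshape(-1, 3).astype(float)

    best = None
    for k in range(1, max_k + 1):
        if k >= len(pixels):
            k = len(pixels)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(pixels)
        centroids = km.cluster_centers_
        devs = _cluster_deviations(pixels, labels, centroids)
        bg = _background_flags(centroids, bit_depth, gamma, background_cutoff_pct)
        fg_devs = devs[~bg]
        avg = float(np.mean(fg_devs)) if len(fg_devs) else 0.0
        max_dev = float(np.max(fg_devs)) if len(fg_devs) else 0.0
        logger.info(
            "k=%d: avg foreground deviation %.3f%%, max %.3f%%, %d background",
            k, avg, max_dev, int(bg.sum()),
        )
        best = ClusterSet(
            labels.reshape(image.shape[:2]),
            centroids,
            devs,
            set(np.where(bg)[0].tolist()),
        )
        if avg < deviation_threshold_pct or k == len(pixels):
            break
    return best


# ---------------------------------------------------------------------------
# Cost maps
# ---------------------------------------------------------------------------


@dataclass
class CostMap:
    grid: ParameterGrid
    values: np.ndarray  # (n_t, n_n) MSE in squared code values
    minima: list = field(default_factory=list)  # CandidateMin entries


def _detect_minima(values: np.ndarray, grid: ParameterGrid) -> list:
    """Low-cost basins of the 3x3-smoothed map, one candidate per basin.

    Quantized tables make cost maps piecewise constant, so pointwise local
    minima fragment into many tied plateau nodes.  Detection therefore works
    on basins: the map is smoothed with a 3x3 mean, thresholded at 4x its
    smoothed global minimum, and each 8-connected component of the
    sub-threshold region yields one candidate minimum — the node of smallest
    raw MSE in the component (plateau ties resolved toward the plateau
    center).  Metameric pixels thus report one candidate per basin.
    """
    smoothed = ndimage.uniform_filter(values, size=3, mode="nearest")
    gmin = smoothed.min()
    region = smoothed <= 4.0 * gmin + _EPS
    labels, ncomp = ndimage.label(region, structure=np.ones((3, 3), dtype=bool))
    mins = []
    slices = ndimage.find_objects(labels)
    for comp in range(1, ncomp + 1):
        sl = slices[comp - 1]
        local_mask = labels[sl] == comp
        local_raw = values[sl]
        vmin = local_raw[local_mask].min()
        idx = np.argwhere(local_mask & (local_raw <= vmin))
        center = idx.mean(axis=0)
        li, lj = idx[int(np.argmin(np.sum((idx - center) ** 2, axis=1)))]
        i, j = li + sl[0].start, lj + sl[1].start
        mins.append(
            CandidateMin(
                float(grid.t_values[i]), float(grid.n_values[j]),
                float(values[i, j]), 0.0,
            )
        )
    mins.sort(key=lambda m: (m.mse, m.t_nm, m.n))
    return _with_probabilities(mins)


def _with_probabilities(mins: list) -> list:
    inv = np.array([1.0 / (m.mse + _EPS) for m in mins])
    probs = inv / inv.sum()
    return [m._replace(probability=float(p)) for m, p in zip(mins, probs)]


def cost_map(pixel: np.ndarray, table: RGBTable, bit_depth: Optional[int] = None) -> CostMap:
    """Eq.-style MSE between one pixel triplet and every table entry."""
    pixel = np.asarray(pixel, dtype=np.int64)
    if pixel.shape != (3,):
        raise ValueError("pixel must be an RGB triplet")
    if bit_depth is not None and bit_depth != table.bit_depth:
        raise ValueError(
            f"bit depth mismatch: pixel {bit_depth} vs table {table.bit_depth}"
        )
    diff = table.entries.astype(np.int64) - pixel
    values = np.mean(diff.astype(float) ** 2, axis=-1)
    return CostMap(table.grid, values, _detect_minima(values, table.grid))


def candidate_probabilities(cmap: CostMap) -> list:
    """Inverse-MSE weights over the detected minima, normalized to sum to 1."""
    if not cmap.minima:
        raise ValueError("cost map has no detected minima")
    return [(m.t_nm, m.n, m.probability) for m in _with_probabilities(cmap.minima)]


def pool_cost_maps(maps: Sequence[CostMap]) -> CostMap:
    """Node-wise arithmetic mean of cost maps; minima re-detected on the mean."""
    if len(maps) == 0:
        raise ValueError("no cost maps to pool")
    grid = maps[0].grid
    for m in maps:
        if m.grid != grid:
            raise ValueError("cost maps are on different parameter grids")
    pooled = np.mean([m.values for m in maps], axis=0)
    return CostMap(grid, pooled, _detect_minima(pooled, grid))


def pooled_cost_map(pixels: np.ndarray, table: RGBTable) -> CostMap:
    """Mean cost map of many pixels computed in one pass.

    Algebraically identical to averaging per-pixel maps: the mean over pixels
    of (X_i - Xhat_i)^2 expands into first and second moments of the pixel
    values, so the pooled map needs a single traversal of the table.
    """
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 3)
    m1 = pixels.mean(axis=0)
    m2 = (pixels**2).mean(axis=0)
    e = table.entries.astype(float)
    values = np.mean(m2 - 2.0 * m1 * e + e**2, axis=-1)
    values = np.clip(values, 0.0, None)  # guard tiny negative rounding
    return CostMap(table.grid, values, _detect_minima(values, table.grid))


# ---------------------------------------------------------------------------
# Full recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    thickness_map: np.ndarray  # nm, NaN on background
    ri_map: np.ndarray  # dimensionless, NaN on background
    confidence_map: np.ndarray  # [0, 1], 0 on background
    cluster_labels: np.ndarray
    background_mask: np.ndarray  # True where background
    summary: list = field(default_factory=list)  # per foreground cluster
    clusters: Optional[ClusterSet] = None


def _assign_from_pooled(cmap: CostMap) -> tuple:
    """Pick the (t, n) node for a pooled map.

    The quantized table is piecewise constant, so the pooled minimum is a
    plateau of exactly tied nodes; taking a plateau corner would bias the
    estimate by up to the plateau width.  The assignment is therefore the
    plateau node closest to the plateau's center of mass (deterministic;
    row-major first on ties).  When the minimum value is attained in several
    disconnected regions (exact metameric ties), the region with the lowest
    smoothed cost wins.
    """
    values = cmap.values
    mask = values == values.min()
    labels, ncomp = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if ncomp > 1:
        smoothed = ndimage.uniform_filter(values, size=3, mode="nearest")
        scores = ndimage.minimum(smoothed, labels, index=np.arange(1, ncomp + 1))
        comp = int(np.argmin(scores)) + 1
    else:
        comp = 1
    idx = np.argwhere(labels == comp)
    center = idx.mean(axis=0)
    order = np.sum((idx - center) ** 2, axis=1)
    i, j = idx[int(np.argmin(order))]
    t = float(cmap.grid.t_values[i])
    n = float(cmap.grid.n_values[j])
    # confidence: probability of the detected minimum nearest the assignment
    if cmap.minima:
        d = [((m.t_nm - t) / cmap.grid.t_step) ** 2 + ((m.n - n) / cmap.grid.n_step) ** 2
             for m in cmap.minima]
        conf = cmap.minima[int(np.argmin(d))].probability
    else:
        conf = 1.0
    return t, n, conf


def recover_maps(
    image: np.ndarray,
    table: RGBTable,
    sample_size: int = 1000,
    threshold_pct: float = 2.0,
    seed: int = 0,
    *,
    max_k: int = 100,
    background_cutoff_pct: float = 5.0,
    gamma: float = 2.2,
) -> RecoveryResult:
    """Cluster an RGB image and recover one (t, n) per foreground cluster.

    For each foreground cluster, up to ``sample_size`` pixels are sampled
    without replacement, their pooled cost map is minimized, and the result is
    assigned to every pixel of the cluster.  Background clusters (dark
    substrate) are masked with NaN.
    """
    image = np.asarray(image)
    max_code = (1 << table.bit_depth) - 1
    if image.max() > max_code:
        raise ValueError(
            f"image code values exceed the table's {table.bit_depth}-bit range"
        )
    clusters = cluster_pixels(
        image,
        threshold_pct,
        seed,
        bit_depth=table.bit_depth,
        gamma=gamma,
        max_k=max_k,
        background_cutoff_pct=background_cutoff_pct,
    )
    shape = image.shape[:2]
    thickness = np.full(shape, np.nan)
    ri = np.full(shape, np.nan)
    confidence = np.zeros(shape)
    background = np.zeros(shape, dtype=bool)
    for cid in clusters.background_ids:
        background[clusters.labels == cid] = True

    rng = np.random.default_rng(seed)
    summary = []
    if not clusters.foreground_ids:
        warnings.warn("image contains only background clusters; nothing recovered")
    for cid in clusters.foreground_ids:
        member_mask = clusters.labels == cid
        pixels = image[member_mask].reshape(-1, 3)
        if len(pixels) > sample_size:
            pick = rng.choice(len(pixels), size=sample_size, replace=False)
            sample = pixels[pick]
        else:
            sample = pixels
        pooled = pooled_cost_map(sample, table)
        t, n, conf = _assign_from_pooled(pooled)
        thickness[member_mask] = t
        ri[member_mask] = n
        confidence[member_mask] = conf
        best = min(pooled.minima, key=lambda m: m.mse) if pooled.minima else None
        logger.info(
            "cluster %d: %d px (%d sampled), t=%.1f nm, n=%.4f, confidence %.3f, "
            "pooled min MSE %.4g, LUT %s",
            cid, len(pixels), len(sample), t, n, conf,
            best.mse if best else float("nan"), table.fingerprint,
        )
        summary.append(
            {
                "cluster": int(cid),
                "t_nm": t,
                "n": n,
                "confidence": conf,
                "pooled_min_mse": best.mse if best else float("nan"),
                "pixel_count": int(len(pixels)),
                "sampled": int(len(sample)),
                "mean_deviation_pct": float(clusters.mean_deviation_pct[cid]),
            }
        )
    return RecoveryResult(
        thickness, ri, confidence, clusters.labels, background, summary, clusters
    )
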