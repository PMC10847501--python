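"""Forward optical model: normal-incidence reflectance of a single thin film.

A dehydrated specimen stretched over a dark nanostructured substrate behaves as
a single homogeneous dielectric layer.  Its reflection spectrum under normally
incident white light carries thin-film interference fringes whose positions and
contrast encode the layer thickness ``t`` (nm) and refractive index ``n``.

Two independent implementations are provided:

* :func:`reflectance_spectrum` — transfer matrix method (TMM), the production
  path, supporting an arbitrary (possibly absorbing, tabulated) substrate;
* :func:`airy_reflectance` — the closed-form two-interface (Airy) solution,
  kept as an independent oracle for testing the TMM.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "FilmParams",
    "StackConfig",
    "Spectrum",
    "reflectance_spectrum",
    "airy_reflectance",
    "tmm_reflectance",
]


class ConfigurationError(ValueError):
    """Raised when a stack/grid configuration is inconsistent."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling in nm (default 400–800 nm, 1 nm step)."""

    start_nm: float = 400.0
    stop_nm: float = 800.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.stop_nm):
            raise ValueError("start_nm must be < stop_nm")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass(frozen=True)
class FilmParams:
    """A single non-dispersive film: thickness in nm, real refractive index."""

    thickness_nm: float
    refractive_index: float

    def __post_init__(self) -> None:
        if self.thickness_nm < 0:
            raise ValueError("thickness_nm must be >= 0")
        if self.refractive_index < 1.0:
            raise ValueError("refractive_index must be >= 1.0")


@dataclass(frozen=True)
class StackConfig:
    """Optical environment of the film.

    The default configuration is a free-standing film surrounded by air on
    both sides.  ``substrate="tabulated"`` switches to a half-space substrate
    whose complex index n - i*k is linearly interpolated from a
    ``wavelength_nm,n,k`` table (e.g. the bundled silicon table).
    """

    ambient_index: float = 1.0
    substrate: str = "air"  # "air" | "tabulated"
    substrate_index_table: Optional[pd.DataFrame] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.ambient_index < 1.0:
            raise ValueError("ambient_index must be >= 1.0")
        if self.substrate not in ("air", "tabulated"):
            raise ValueError(f"unknown substrate tag {self.substrate!r}")
        if self.substrate == "tabulated" and self.substrate_index_table is None:
            raise ConfigurationError("tabulated substrate requires an index table")

    @classmethod
    def silicon(cls) -> "StackConfig":
        """Film on a crystalline-silicon half space (approximate n,k table)."""
        ref = importlib.resources.files("filmetry.data") / "silicon_nk.csv"
        with importlib.resources.as_file(ref) as path:
            table = pd.read_csv(path, comment="#")
        return cls(substrate="tabulated", substrate_index_table=table)

    def substrate_index(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Complex substrate index n - i*k at each wavelength."""
        wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        if self.substrate == "air":
            return np.full(wavelengths_nm.shape, self.ambient_index, dtype=complex)
        tab = self.substrate_index_table
        wl = tab["wavelength_nm"].to_numpy(dtype=float)
        if wavelengths_nm.min() < wl.min() - 1e-9 or wavelengths_nm.max() > wl.max() + 1e-9:
            raise ConfigurationError(
                f"substrate table covers {wl.min():g}-{wl.max():g} nm but grid spans "
                f"{wavelengths_nm.min():g}-{wavelengths_nm.max():g} nm"
            )
        n = np.interp(wavelengths_nm, wl, tab["n"].to_numpy(dtype=float))
        k = np.interp(wavelengths_nm, wl, tab["k"].to_numpy(dtype=float))
        return n - 1j * k

    def fingerprint(self) -> str:
        if self.substrate == "air":
            return f"air(ambient={self.ambient_index:g})"
        tab = self.substrate_index_table
        return (
            f"tabulated(ambient={self.ambient_index:g},"
            f"rows={len(tab)},nsum={tab['n'].sum():.6f},ksum={tab['k'].sum():.6f})"
        )


@dataclass
class Spectrum:
    """Reflectance (0–1) sampled on a wavelength grid."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("values length does not match grid")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.grid.wavelengths, "reflectance": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        df = pd.read_csv(path)
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        step = float(wl[1] - wl[0]) if len(wl) > 1 else 1.0
        grid = WavelengthGrid(float(wl[0]), float(wl[-1]), step)
        return cls(grid, df["reflectance"].to_numpy(dtype=float))


def tmm_reflectance(
    thickness_nm,
    refractive_index,
    wavelengths_nm,
    stack: StackConfig = StackConfig(),
) -> np.ndarray:
    """Transfer-matrix reflectance, broadcasting over thickness/index/wavelength.

    Uses the characteristic matrix of the single layer,
    ``M = [[cos d, i sin d / n], [i n sin d, cos d]]`` with the phase thickness
    ``d = 2 pi n t / lambda``, and the field solution
    ``r = (n0 B - C) / (n0 B + C)`` where ``[B, C] = M @ [1, ns]``.
    """
    t = np.asarray(thickness_nm, dtype=float)
    n = np.asarray(refractive_index, dtype=float)
    wl = np.asarray(wavelengths_nm, dtype=float)
    t, n, wl_b = np.broadcast_arrays(t, n, wl)
    ns = np.broadcast_to(stack.substrate_index(wl), wl_b.shape)
    n0 = stack.ambient_index

    delta = 2.0 * np.pi * n * t / wl_b
    cosd = np.cos(delta)
    sind = np.sin(delta)
    # [B, C] = M @ [1, ns]
    B = cosd + 1j * sind / n * ns
    C = 1j * n * sind + cosd * ns
    r = (n0 * B - C) / (n0 * B + C)
    R = np.abs(r) ** 2
    return np.clip(R.real, 0.0, 1.0)


def reflectance_spectrum(
    film: FilmParams,
    stack: StackConfig = StackConfig(),
    grid: WavelengthGrid = WavelengthGrid(),
) -> Spectrum:
    """Normal-incidence reflectance spectrum of a single film (TMM)."""
    values = tmm_reflectance(
        film.thickness_nm, film.refractive_index, grid.wavelengths, stack
    )
    return Spectrum(grid, values)


def airy_reflectance(film: FilmParams, ambient_index: float, wavelength_nm) -> np.ndarray:
    """Closed-form Airy reflectance of a film in a uniform ambient medium.

    Independent of :func:`tmm_reflectance`: built from the two Fresnel
    interface coefficients and the geometric series for multiple internal
    reflections, ``r = (r01 + r12 e^{2 i beta}) / (1 + r01 r12 e^{2 i beta})``
    with ``beta = 2 pi n t / lambda``.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    n0 = ambient_index
    n1 = film.refractive_index
    r01 = (n0 - n1) / (n0 + n1)
    r12 = (n1 - n0) / (n1 + n0)
    beta = 2.0 * np.pi * n1 * film.thickness_nm / wl
    phase = np.exp(2j * beta)
    r = (r01 + r12 * phase) / (1.0 + r01 * r12 * phase)
    out = np.abs(r) ** 2
    return out if out.ndim else float(out)
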