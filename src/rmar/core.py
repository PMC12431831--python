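"""Core in-memory containers for 2D spectral-CT image data.

All images are 2D ``float64`` arrays of CT numbers in Hounsfield units
(water = 0 HU, air = -1000 HU), row-major, 0-based, with row 0 at the
top.  Pixel spacing is ``(row, col)`` in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = ["CTImage", "VMISeries", "MBIPair", "MaskSet"]


def _as_float_2d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _as_bool_2d(a, name: str, shape) -> np.ndarray:
    arr = np.asarray(a, dtype=bool)
    if arr.shape != tuple(shape):
        raise ValueError(f"{name} shape {arr.shape} != expected {tuple(shape)}")
    return arr


@dataclass
class CTImage:
    """One 2D CT slice in Hounsfield units.

    Parameters
    ----------
    pixels : 2D array of CT numbers (HU), finite.
    spacing : (row, col) pixel size in mm, strictly positive.
    energy_kev : optional monochromatic energy label.
    provenance : free-text tag, e.g. ``"vmi"``, ``"artifact"``, ``"corrected"``.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    energy_kev: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = _as_float_2d(self.pixels, "pixels")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.energy_kev is not None:
            self.energy_kev = float(self.energy_kev)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self, **changes) -> "CTImage":
        out = replace(self, **changes)
        out.pixels = out.pixels.copy()
        return out


@dataclass
class VMISeries:
    """An ordered, co-registered series of VMIs at increasing energies."""

    images: list[CTImage]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("VMISeries requires at least one image")
        shape = self.images[0].shape
        spacing = self.images[0].spacing
        for im in self.images:
            if im.shape != shape:
                raise ValueError("all images in a series must share one shape")
            if im.spacing != spacing:
                raise ValueError("all images in a series must share one spacing")
            if im.energy_kev is None:
                raise ValueError("every image in a series needs an energy label")
            if not (40.0 <= im.energy_kev <= 200.0):
                raise ValueError(
                    f"series energy {im.energy_kev} keV outside [40, 200]"
                )
        e = self.energies_kev
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"energies must be strictly increasing, got {e}")

    @property
    def energies_kev(self) -> np.ndarray:
        return np.array([im.energy_kev for im in self.images], dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    @property
    def spacing(self) -> tuple[float, float]:
        return self.images[0].spacing

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[CTImage]:
        return iter(self.images)

    def at(self, energy_kev: float) -> CTImage:
        """Return the image labelled ``energy_kev`` (exact match)."""
        for im in self.images:
            if im.energy_kev == energy_kev:
                return im
        raise KeyError(f"no image at {energy_kev} keV in {list(self.energies_kev)}")

    def subset(self, energies: Sequence[float]) -> "VMISeries":
        return VMISeries([self.at(e) for e in sorted(energies)])


@dataclass
class MBIPair:
    """Co-registered water/bone material basis images in g/cm^3.

    Negative bone-basis values are physical for water-like materials
    that are not pure water (e.g. solid water) and are never clipped.
    """

    water: np.ndarray
    bone: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.water = _as_float_2d(self.water, "water")
        self.bone = _as_float_2d(self.bone, "bone")
        if self.water.shape != self.bone.shape:
            raise ValueError("water and bone basis images must share one shape")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.water.shape

    def copy(self) -> "MBIPair":
        return MBIPair(self.water.copy(), self.bone.copy(), self.spacing)


@dataclass
class MaskSet:
    """Binary masks on one pixel grid.

    ``artifact`` (f_M1) flags artifact-affected pixels, ``artifact_free``
    (f_M0) the clean pixels; together with ``metal`` they partition the
    body ``support`` exactly.  Metal is handled separately and never
    belongs to either f_M0 or f_M1.
    """

    artifact: np.ndarray
    artifact_free: np.ndarray
    metal: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=bool)
        shape = self.support.shape
        self.artifact = _as_bool_2d(self.artifact, "artifact", shape)
        self.artifact_free = _as_bool_2d(self.artifact_free, "artifact_free", shape)
        self.metal = _as_bool_2d(self.metal, "metal", shape)
        if np.any(self.artifact & self.metal):
            raise ValueError("artifact mask overlaps metal")
        if np.any(self.artifact_free & self.metal):
            raise ValueError("artifact-free mask overlaps metal")
        if np.any(self.artifact & ~self.support):
            raise ValueError("artifact mask extends outside support")
        body = self.support & ~self.metal
        if not np.array_equal(self.artifact_free, body & ~self.artifact):
            raise ValueError("f_M0 != support - metal - f_M1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.support.shape
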