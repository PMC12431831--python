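"""Virtual monochromatic image (VMI) synthesis and two-material decomposition.

In dual-energy CT the HU value of a VMI at energy ``E`` is an affine
function of the per-pixel basis-material densities::

    HU(E) = (1000 / rho_w) * [ (m1(E)/m_w(E)) * f1 + (m2(E)/m_w(E)) * f2 ] - 1000

where ``m_i(E)`` are mass attenuation coefficients (cm^2/g), ``rho_w``
is the water density and ``f1``, ``f2`` are the basis density images
(g/cm^3); here basis 1 is water and basis 2 is cortical bone.  Given
VMIs at two distinct energies the relation is inverted pixelwise as an
exact 2x2 linear solve — image-domain material decomposition.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import CTImage, MBIPair, VMISeries

__all__ = [
    "AttenuationTable",
    "mass_atten",
    "synthesize_vmi",
    "synthesize_series",
    "decompose_mbi",
]

#: relative determinant tolerance below which an energy pair is rejected
COND_TOL = 1e-8


@dataclass
class AttenuationTable:
    """Mass attenuation coefficients m(E) per material on an energy grid.

    ``samples`` maps a material name to ``(energies_kev, mu_over_rho)``
    arrays with strictly increasing energies and positive coefficients.
    Interpolation between grid points is linear in log-log space, which
    preserves monotone power-law behaviour of photoelectric absorption.
    """

    samples: dict[str, tuple[np.ndarray, np.ndarray]]
    rho_w: float = 1.0

    def __post_init__(self) -> None:
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, (e, mu) in self.samples.items():
            e = np.asarray(e, dtype=float)
            mu = np.asarray(mu, dtype=float)
            if e.shape != mu.shape or e.ndim != 1 or e.size < 2:
                raise ValueError(f"malformed samples for {name!r}")
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"energies for {name!r} not strictly increasing")
            if np.any(mu <= 0):
                raise ValueError(f"non-positive coefficient for {name!r}")
            if e[0] > 40.0 or e[-1] < 200.0:
                raise ValueError(
                    f"table for {name!r} spans [{e[0]}, {e[-1]}] keV; "
                    "must cover at least [40, 200]"
                )
            clean[name] = (e, mu)
        self.samples = clean

    @property
    def materials(self) -> list[str]:
        return sorted(self.samples)

    def span(self, material: str) -> tuple[float, float]:
        e, _ = self._get(material)
        return float(e[0]), float(e[-1])

    def _get(self, material: str) -> tuple[np.ndarray, np.ndarray]:
        try:
            return self.samples[material]
        except KeyError:
            raise KeyError(
                f"unknown material {material!r}; have {self.materials}"
            ) from None

    def __call__(self, material: str, energy_kev) -> np.ndarray | float:
        return mass_atten(self, material, energy_kev)

    @classmethod
    def from_file(cls, path: str | Path, rho_w: float = 1.0) -> "AttenuationTable":
        """Read a plain-text table (columns: material, keV, cm^2/g)."""
        raw: dict[str, list[tuple[float, float]]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            mat, e, mu = line.split()
            raw.setdefault(mat, []).append((float(e), float(mu)))
        samples = {}
        for mat, rows in raw.items():
            rows.sort()
            e = np.array([r[0] for r in rows])
            mu = np.array([r[1] for r in rows])
            samples[mat] = (e, mu)
        return cls(samples=samples, rho_w=rho_w)

    @classmethod
    def default(cls) -> "AttenuationTable":
        """The packaged standard-reference table (water, bone, titanium)."""
        ref = importlib.resources.files("rmar.data") / "attenuation_nist.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_file(path)


def mass_atten(table: AttenuationTable, material: str, energy_kev):
    """Mass attenuation coefficient (cm^2/g) at ``energy_kev``.

    Exact at grid points; log-log linear in between.  Raises for
    energies outside the tabulated span.
    """
    e_grid, mu_grid = table._get(material)
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < e_grid[0]) or np.any(e > e_grid[-1]):
        raise ValueError(
            f"energy {energy_kev} keV outside tabulated span "
            f"[{e_grid[0]}, {e_grid[-1]}] for {material!r}"
        )
    out = np.exp(np.interp(np.log(e), np.log(e_grid), np.log(mu_grid)))
    return float(out) if np.isscalar(energy_kev) else out


def _basis_row(table: AttenuationTable, energy_kev: float) -> tuple[float, float]:
    mw = mass_atten(table, "water", energy_kev)
    return (
        mass_atten(table, "water", energy_kev) / mw,
        mass_atten(table, "bone", energy_kev) / mw,
    )


def synthesize_vmi(
    mbi: MBIPair, energy_kev: float, table: AttenuationTable | None = None
) -> CTImage:
    """Synthesize the VMI at ``energy_kev`` from water/bone basis images."""
    table = table or AttenuationTable.default()
    r1, r2 = _basis_row(table, energy_kev)
    hu = (1000.0 / table.rho_w) * (r1 * mbi.water + r2 * mbi.bone) - 1000.0
    return CTImage(hu, spacing=mbi.spacing, energy_kev=energy_kev, provenance="vmi")


def synthesize_series(
    mbi: MBIPair, energies: Sequence[float], table: AttenuationTable | None = None
) -> VMISeries:
    """Map :func:`synthesize_vmi` over an energy list."""
    table = table or AttenuationTable.default()
    return VMISeries([synthesize_vmi(mbi, float(e), table) for e in sorted(energies)])


def decompose_mbi(
    vmi_lo: CTImage, vmi_hi: CTImage, table: AttenuationTable | None = None
) -> MBIPair:
    """Two-point material decomposition of co-registered VMIs.

    Solves, per pixel, the exact 2x2 linear system relating HU at the
    two energies to water/bone basis densities.  No regularization: in
    particular, negative bone densities pass through untouched.
    """
    table = table or AttenuationTable.default()
    if vmi_lo.shape != vmi_hi.shape:
        raise ValueError(
            f"shape mismatch: {vmi_lo.shape} vs {vmi_hi.shape}"
        )
    e1, e2 = vmi_lo.energy_kev, vmi_hi.energy_kev
    if e1 is None or e2 is None:
        raise ValueError("both VMIs need energy labels for decomposition")
    a11, a12 = _basis_row(table, e1)
    a21, a22 = _basis_row(table, e2)
    det = a11 * a22 - a12 * a21
    norm = max(abs(a11), abs(a12), abs(a21), abs(a22))
    if abs(det) < COND_TOL * norm**2:
        raise ValueError(
            f"energy pair ({e1}, {e2}) keV is ill-conditioned for "
            f"decomposition (|det| = {abs(det):.3e})"
        )
    # right-hand side: rho_w * (HU + 1000) / 1000 at each energy
    b1 = table.rho_w * (vmi_lo.pixels + 1000.0) / 1000.0
    b2 = table.rho_w * (vmi_hi.pixels + 1000.0) / 1000.0
    water = (a22 * b1 - a12 * b2) / det
    bone = (a11 * b2 - a21 * b1) / det
    return MBIPair(water=water, bone=bone, spacing=vmi_lo.spacing)
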