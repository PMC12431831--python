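"""Regional quadratic mapping between VMI CT numbers and basis densities.

The core of rMAR: in artifact-free pixels of the optimal VMI, the
relationship between HU and each basis-material density is smooth and
well approximated by a quadratic polynomial.  That polynomial, fitted
only on clean pixels (bone and metal excluded), is then evaluated on
artifact-region pixels of the same VMI to replace the corrupted basis
values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import CTImage, MBIPair, MaskSet

__all__ = ["MappingModel", "fit_mapping", "apply_mapping", "correct_mbis"]

MIN_FIT_PIXELS = 100


@dataclass
class MappingModel:
    """basis = a0 + a1*HU + a2*HU^2, valid on the fitted HU domain.

    Evaluation outside ``hu_domain`` is clamped to the nearest domain
    endpoint: quadratics extrapolate violently and streak pixels can sit
    far outside the clean-region HU range.
    """

    coefficients: tuple[float, float, float]
    target: str  # "water" | "bone"
    hu_domain: tuple[float, float]
    n_fit: int
    residual_rms: float

    def __post_init__(self) -> None:
        if self.hu_domain[0] >= self.hu_domain[1]:
            raise ValueError(f"degenerate HU domain {self.hu_domain}")
        if self.n_fit < MIN_FIT_PIXELS:
            raise ValueError(f"model fitted on too few pixels ({self.n_fit})")

    def __call__(self, hu) -> np.ndarray:
        return apply_mapping(self, hu)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "MappingModel":
        d = json.loads(Path(path).read_text())
        d["coefficients"] = tuple(d["coefficients"])
        d["hu_domain"] = tuple(d["hu_domain"])
        return cls(**d)


def fit_mapping(
    vmi0: CTImage,
    basis: np.ndarray,
    masks: MaskSet,
    bone_exclude_hu: float = 150.0,
    target: str = "water",
) -> MappingModel:
    """Ordinary least-squares quadratic fit on artifact-free pixels.

    Pixel pairs ``(vmi0 HU, basis value)`` are taken from f_M0 minus
    pixels brighter than ``bone_exclude_hu`` (bone would bend the
    soft-tissue mapping).  Refuses to fit on fewer than 100 pixels or
    on a rank-deficient design (e.g. constant HU).
    """
    basis = np.asarray(basis, dtype=float)
    if basis.shape != vmi0.shape or masks.shape != vmi0.shape:
        raise ValueError("vmi0, basis and masks must share one grid")
    sel = masks.artifact_free & (vmi0.pixels <= bone_exclude_hu)
    x = vmi0.pixels[sel]
    y = basis[sel]
    n = x.size
    if n < MIN_FIT_PIXELS:
        raise ValueError(
            f"only {n} artifact-free pixels available; need >= {MIN_FIT_PIXELS}"
        )
    design = np.column_stack([np.ones_like(x), x, x * x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise ValueError(
            "rank-deficient design: HU values in the fitting region do not "
            "span a quadratic (constant or collinear input)"
        )
    resid = design @ coef - y
    return MappingModel(
        coefficients=(float(coef[0]), float(coef[1]), float(coef[2])),
        target=target,
        hu_domain=(float(x.min()), float(x.max())),
        n_fit=int(n),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def apply_mapping(model: MappingModel, hu) -> np.ndarray | float:
    """Evaluate the clamped quadratic on HU values."""
    h = np.clip(np.asarray(hu, dtype=float), *model.hu_domain)
    a0, a1, a2 = model.coefficients
    out = a0 + a1 * h + a2 * h * h
    return float(out) if np.isscalar(hu) else out


def correct_mbis(
    mbi: MBIPair,
    masks: MaskSet,
    model_w: MappingModel,
    model_b: MappingModel,
    vmi0: CTImage,
) -> MBIPair:
    """Assemble artifact-improved basis images.

    Artifact-region pixels (f_M1) get basis values mapped from the
    optimal VMI; every other pixel — artifact-free region, bone-excluded
    pixels, metal, outside-support — keeps its original basis value, so
    the correction is exactly local to f_M1.
    """
    if mbi.shape != vmi0.shape or masks.shape != vmi0.shape:
        raise ValueError("mbi, masks and vmi0 must share one grid")
    out = mbi.copy()
    idx = masks.artifact
    if idx.any():
        hu = vmi0.pixels[idx]
        out.water[idx] = apply_mapping(model_w, hu)
        out.bone[idx] = apply_mapping(model_b, hu)
    return out
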