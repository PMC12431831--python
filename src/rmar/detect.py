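"""Artifact localization: preliminary MAR, TV cost curves and STS masks.

The detection chain mirrors classic interpolation-based metal artifact
reduction: threshold the metal, forward-project image and metal mask,
bridge the metal trace in the sinogram by 1D linear interpolation, and
reconstruct by filtered back projection.  The reconstruction is
deliberately coarse — its only job is to expose the artifact content
as ``input - corrected`` ("artifact images") so that the total
variation (TV) cost can rank energies and the sorting-and-thresholding
segmentation (STS) can flag artifact pixels row by row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation, disk, erosion, remove_small_objects
from skimage.transform import iradon, radon

from .core import CTImage, MaskSet, VMISeries

__all__ = [
    "CostCurve",
    "segment_metal",
    "preliminary_mar",
    "artifact_image",
    "tv_cost",
    "cost_curve",
    "select_optimal",
    "select_worst",
    "sts_flags",
    "sts_mask",
    "build_masks",
    "analyze_artifacts",
    "ArtifactAnalysis",
]

#: energies the cost curve is evaluated on when the series provides them
DEFAULT_SELECTED_KEV = (70.0, 80.0, 100.0, 120.0, 140.0)


def segment_metal(
    ct: CTImage, threshold_hu: float = 2500.0, min_area: int = 9
) -> np.ndarray:
    """Threshold-based metal segmentation with small-component removal.

    Titanium and steel implants sit far above any tissue HU at every
    monochromatic energy, so a single global threshold separates metal
    from soft tissue and bone.  ``threshold_hu`` must exceed 1000 HU so
    dense cortical bone is never captured.
    """
    if threshold_hu <= 1000.0:
        raise ValueError(f"metal threshold must exceed 1000 HU, got {threshold_hu}")
    mask = ct.pixels >= threshold_hu
    if min_area > 1:
        mask = remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        warnings.warn("no metal found above threshold", stacklevel=2)
    return mask


def _radon_angles(n_angles: int) -> np.ndarray:
    return np.linspace(0.0, 180.0, n_angles, endpoint=False)


def preliminary_mar(ct: CTImage, metal: np.ndarray, n_angles: int = 180) -> CTImage:
    """Coarse sinogram-interpolation MAR used only to expose artifacts.

    Forward-projects the slice and the metal mask over ``n_angles`` in
    [0, 180), replaces metal-shadowed sinogram bins per angle by linear
    interpolation from the nearest clean bins, and reconstructs the
    correction by filtered back projection (ramp filter).  Because FBP
    is linear, only the sinogram *difference* — nonzero solely in the
    metal-trace bins — is reconstructed and subtracted from the input;
    this leaves pixels untouched by the metal shadow numerically exact
    instead of polluting them with forward/back-projection round-trip
    error.  Original metal pixels are re-inserted.  The output trades
    accuracy for speed on purpose.
    """
    metal = np.asarray(metal, dtype=bool)
    if not metal.any():
        raise ValueError("preliminary MAR requires a non-empty metal mask")
    n = ct.shape[0]
    if ct.shape[0] != ct.shape[1]:
        raise ValueError(f"input must be square, got {ct.shape}; pad first")
    theta = _radon_angles(n_angles)
    # separate metal from soft tissue first: metal pixels are replaced by
    # the median HU of their immediate surroundings so the sinogram
    # residual holds only artifact deviations, not the implant itself
    soft = ct.pixels.copy()
    shell = dilation(metal, disk(3)) & ~metal
    soft[metal] = np.median(ct.pixels[shell]) if shell.any() else 0.0
    # shift so air = 0: keeps the interpolation baseline physical
    sino = radon(soft + 1000.0, theta=theta, circle=False)
    trace = radon(metal.astype(float), theta=theta, circle=False) > 0.05
    bins = np.arange(sino.shape[0])
    resid = np.zeros_like(sino)
    for j in range(sino.shape[1]):
        bad = trace[:, j]
        if bad.any() and not bad.all():
            resid[bad, j] = sino[bad, j] - np.interp(
                bins[bad], bins[~bad], sino[~bad, j]
            )
    removed = iradon(resid, theta=theta, filter_name="ramp", circle=False,
                     output_size=n)
    recon = soft - removed
    recon[metal] = ct.pixels[metal]
    return ct.copy(pixels=recon, provenance="preliminary_mar")


def artifact_image(ct: CTImage, corrected: CTImage, metal: np.ndarray) -> CTImage:
    """Artifact content ``ct - corrected`` with metal pixels zeroed."""
    if ct.shape != corrected.shape:
        raise ValueError("image grids differ")
    diff = ct.pixels - corrected.pixels
    diff[np.asarray(metal, dtype=bool)] = 0.0
    return ct.copy(pixels=diff, provenance="artifact")


def tv_cost(img: CTImage | np.ndarray, exclude: np.ndarray | None = None) -> float:
    """Isotropic total-variation cost with forward differences.

    ``C = sum_xy sqrt((f[x+1,y]-f[x,y])^2 + (f[x,y+1]-f[x,y])^2)`` over
    pixels whose forward neighbours exist (last row/column omitted) and
    where, if ``exclude`` is given, the pixel and both forward
    neighbours all lie outside the excluded region.
    """
    f = img.pixels if isinstance(img, CTImage) else np.asarray(img, dtype=float)
    if f.ndim != 2 or f.shape[0] < 2 or f.shape[1] < 2:
        raise ValueError(f"need at least a 2x2 image, got shape {f.shape}")
    dr = f[1:, :-1] - f[:-1, :-1]
    dc = f[:-1, 1:] - f[:-1, :-1]
    g = np.sqrt(dr * dr + dc * dc)
    if exclude is not None:
        e = np.asarray(exclude, dtype=bool)
        ok = ~e[:-1, :-1] & ~e[1:, :-1] & ~e[:-1, 1:]
        g = g[ok]
    return float(g.sum())


@dataclass
class CostCurve:
    """TV costs per candidate energy, normalized by the maximum."""

    energies_kev: np.ndarray
    raw_costs: np.ndarray

    def __post_init__(self) -> None:
        self.energies_kev = np.asarray(self.energies_kev, dtype=float)
        self.raw_costs = np.asarray(self.raw_costs, dtype=float)
        if self.energies_kev.size != self.raw_costs.size:
            raise ValueError("energies and costs misaligned")
        if self.energies_kev.size < 2:
            raise ValueError("a cost curve needs at least two entries")

    @property
    def normalized_costs(self) -> np.ndarray:
        return self.raw_costs / self.raw_costs.max()


def cost_curve(
    artifact_images: Sequence[CTImage],
    energies: Sequence[float],
    exclude: np.ndarray | None = None,
) -> CostCurve:
    """Normalized TV cost C_norm(n) = C(n)/max C(n) over artifact images."""
    if len(artifact_images) < 2:
        raise ValueError("need at least two artifact images")
    raw = [tv_cost(im, exclude=exclude) for im in artifact_images]
    return CostCurve(np.asarray(energies, dtype=float), np.asarray(raw))


def select_optimal(curve: CostCurve) -> float:
    """Energy with the lowest normalized cost; ties go to the higher energy."""
    c = curve.normalized_costs
    idx = np.flatnonzero(c == c.min())[-1]
    return float(curve.energies_kev[idx])


def select_worst(curve: CostCurve) -> float:
    """Energy with the highest normalized cost; ties go to the lower energy."""
    c = curve.normalized_costs
    idx = np.flatnonzero(c == c.max())[0]
    return float(curve.energies_kev[idx])


def sts_flags(
    artifact: CTImage | np.ndarray,
    support: np.ndarray,
    delta_hu: float = 10.0,
    min_row_pixels: int = 3,
) -> np.ndarray:
    """Row-wise sorting-and-thresholding flags, before any morphology.

    For each image row the in-support pixels are sorted to find the
    median; bounds are ``median +/- delta_hu`` and pixels strictly
    outside them are flagged as artifact.  Rows with fewer than
    ``min_row_pixels`` support pixels are skipped (median ill-defined).
    """
    if delta_hu <= 0:
        raise ValueError("delta_hu must be positive")
    a = artifact.pixels if isinstance(artifact, CTImage) else np.asarray(artifact, float)
    support = np.asarray(support, dtype=bool)
    if a.shape != support.shape:
        raise ValueError("artifact and support grids differ")
    if not support.any():
        raise ValueError("empty support mask")
    vals = np.where(support, a, np.nan)
    counts = support.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(vals, axis=1)
    ok_rows = counts >= min_row_pixels
    med = np.where(ok_rows, med, 0.0)
    flags = support & ok_rows[:, None] & (np.abs(a - med[:, None]) > delta_hu)
    return flags


def sts_mask(
    artifact: CTImage | np.ndarray,
    support: np.ndarray,
    delta_hu: float = 10.0,
    erosion_px: int = 1,
    dilation_px: int = 2,
) -> np.ndarray:
    """STS artifact mask: row-wise median bounds plus dilation/erosion.

    Dilation (disc radius ``dilation_px``) bridges neighbouring streak
    pixels before the erosion (disc radius ``erosion_px``) prunes
    isolated flags; a larger erosion element makes the pass more
    conservative.
    """
    flags = sts_flags(artifact, support, delta_hu=delta_hu)
    if dilation_px > 0:
        flags = dilation(flags, disk(dilation_px))
    if erosion_px > 0:
        flags = erosion(flags, disk(erosion_px))
    return flags


@dataclass
class ArtifactAnalysis:
    """Everything the detection chain derives from one VMI series."""

    metal_found: bool
    metal: np.ndarray
    support: np.ndarray
    selected_energies: list[float]
    corrected: dict[float, CTImage] = field(default_factory=dict)
    artifacts: dict[float, CTImage] = field(default_factory=dict)
    curve: CostCurve | None = None
    optimal_kev: float | None = None
    worst_kev: float | None = None
    masks: MaskSet | None = None


def _support_mask(ct: CTImage, threshold_hu: float = -500.0) -> np.ndarray:
    body = ct.pixels > threshold_hu
    return ndimage.binary_fill_holes(body)


def analyze_artifacts(
    series: VMISeries,
    selected_energies: Sequence[float] | None = None,
    metal_threshold_hu: float = 2500.0,
    min_metal_area: int = 9,
    support_threshold_hu: float = -500.0,
    delta_hu: float = 10.0,
    sts1_erosion_px: int = 4,
    sts2_erosion_px: int = 1,
    dilation_px: int = 2,
    n_angles: int = 180,
) -> ArtifactAnalysis:
    """Run the full detection chain on a VMI series.

    Steps: bootstrap the metal mask on the highest-energy VMI (metal HU
    dwarfs the threshold at every energy, so the bootstrap energy is
    immaterial); preliminary MAR and artifact image per candidate
    energy; TV cost curve; optimal/worst energies; support mask; STS1
    (4 px erosion) on the worst-energy artifact image for the obvious
    artifact region, STS2 (1 px erosion) on the optimal-energy artifact
    image for a finer artifact-free split; union restricted to the body
    off metal yields f_M1, its complement f_M0.
    """
    if len(series) < 2:
        raise ValueError("need a series with at least two energies")
    energies = list(series.energies_kev)
    if selected_energies is None:
        selected = [e for e in DEFAULT_SELECTED_KEV if e in energies]
        if len(selected) < 2:
            selected = energies
    else:
        selected = sorted(float(e) for e in selected_energies)
        missing = [e for e in selected if e not in energies]
        if missing:
            raise ValueError(f"selected energies {missing} not in series {energies}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        metal = segment_metal(series.images[-1], metal_threshold_hu, min_metal_area)
    if not metal.any():
        support = _support_mask(series.images[-1], support_threshold_hu)
        return ArtifactAnalysis(
            metal_found=False, metal=metal, support=support,
            selected_energies=selected,
        )

    analysis = ArtifactAnalysis(
        metal_found=True, metal=metal,
        support=np.zeros(series.shape, dtype=bool),
        selected_energies=selected,
    )
    for e in selected:
        corr = preliminary_mar(series.at(e), metal, n_angles=n_angles)
        analysis.corrected[e] = corr
        analysis.artifacts[e] = artifact_image(series.at(e), corr, metal)
    analysis.curve = cost_curve(
        [analysis.artifacts[e] for e in selected], selected, exclude=metal
    )
    analysis.optimal_kev = select_optimal(analysis.curve)
    analysis.worst_kev = select_worst(analysis.curve)

    optimal_img = series.at(analysis.optimal_kev)
    metal = segment_metal(optimal_img, metal_threshold_hu, min_metal_area)
    analysis.metal = metal
    support = _support_mask(optimal_img, support_threshold_hu)
    analysis.support = support

    sts1 = sts_mask(analysis.artifacts[analysis.worst_kev], support,
                    delta_hu=delta_hu, erosion_px=sts1_erosion_px,
                    dilation_px=dilation_px)
    sts2 = sts_mask(analysis.artifacts[analysis.optimal_kev], support,
                    delta_hu=delta_hu, erosion_px=sts2_erosion_px,
                    dilation_px=dilation_px)
    f_m1 = (sts1 | sts2) & support & ~metal
    f_m0 = support & ~metal & ~f_m1
    analysis.masks = MaskSet(
        artifact=f_m1, artifact_free=f_m0, metal=metal, support=support
    )
    return analysis


def build_masks(series: VMISeries, **kwargs) -> MaskSet:
    """Convenience wrapper returning only the :class:`MaskSet`."""
    analysis = analyze_artifacts(series, **kwargs)
    if not analysis.metal_found:
        raise ValueError("no metal found; mask generation is undefined")
    assert analysis.masks is not None
    return analysis.masks
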