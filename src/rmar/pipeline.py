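"""End-to-end rMAR orchestration and evaluation instruments.

The correction runs entirely in the image domain:

1. decompose water/bone basis images from two VMIs of the series;
2. rank candidate energies by the TV cost of their artifact images and
   pick the optimal VMI;
3. build metal / support / artifact (f_M1) / artifact-free (f_M0) masks;
4. fit the quadratic HU-to-basis mapping on artifact-free pixels;
5. replace basis values inside f_M1 with mapped values;
6. re-synthesize VMIs from the improved basis images, splicing the
   synthesized values into the originals only inside f_M1 so the
   correction is exactly local.

Evaluation helpers compute ROI ``delta CT = mean(HU) - reference`` and
bilinear line profiles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import detect
from .core import CTImage, MBIPair, MaskSet, VMISeries
from .detect import ArtifactAnalysis, CostCurve, analyze_artifacts
from .model import MappingModel, correct_mbis, fit_mapping
from .phantom import CircleROI
from .spectral import AttenuationTable, decompose_mbi, synthesize_vmi

__all__ = [
    "PipelineConfig",
    "RMARResult",
    "ROIStats",
    "run_rmar",
    "delta_ct",
    "line_profile",
]


@dataclass
class PipelineConfig:
    """All tunable constants of the correction chain.

    ``decomposition_pair=None`` uses the series' lowest and highest
    energies.  ``selected_energies=None`` uses whichever of 70/80/100/
    120/140 keV the series provides.  ``output_energies=None`` corrects
    every energy present in the input series.
    """

    decomposition_pair: tuple[float, float] | None = None
    selected_energies: tuple[float, ...] | None = None
    output_energies: tuple[float, ...] | None = None
    metal_threshold_hu: float = 2500.0
    min_metal_area: int = 9
    support_threshold_hu: float = -500.0
    sts_delta_hu: float = 10.0
    sts1_erosion_px: int = 4
    sts2_erosion_px: int = 1
    dilation_px: int = 2
    bone_exclude_hu: float = 150.0
    n_angles: int = 180

    def __post_init__(self) -> None:
        for name in ("metal_threshold_hu", "sts_delta_hu", "n_angles"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sts1_erosion_px", "sts2_erosion_px", "dilation_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class RMARResult:
    """Outputs and diagnostics of one rMAR run."""

    corrected: VMISeries
    mbi: MBIPair | None = None
    improved_mbi: MBIPair | None = None
    masks: MaskSet | None = None
    curve: CostCurve | None = None
    models: dict[str, MappingModel] = field(default_factory=dict)
    no_metal: bool = False
    report: dict = field(default_factory=dict)

    def write_report(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.report, indent=2, sort_keys=True))
        return path


def _resolve_pair(
    series: VMISeries, pair: tuple[float, float] | None
) -> tuple[float, float]:
    e = series.energies_kev
    if pair is None:
        return float(e[0]), float(e[-1])
    lo, hi = sorted(float(x) for x in pair)
    for x in (lo, hi):
        if x not in e:
            raise ValueError(f"decomposition energy {x} keV not in series {list(e)}")
    return lo, hi


def run_rmar(
    series: VMISeries,
    cfg: PipelineConfig | None = None,
    table: AttenuationTable | None = None,
) -> RMARResult:
    """Run the full regional model-based metal artifact reduction.

    Returns the corrected series plus every intermediate needed to audit
    the run.  A series without detectable metal is returned unchanged
    with ``no_metal=True`` — a valid clinical input, not an error.
    Deterministic given the inputs and config.
    """
    cfg = cfg or PipelineConfig()
    table = table or AttenuationTable.default()
    report: dict = {"stages": []}

    e_lo, e_hi = _resolve_pair(series, cfg.decomposition_pair)
    report["decomposition_pair_kev"] = [e_lo, e_hi]
    mbi = decompose_mbi(series.at(e_lo), series.at(e_hi), table)
    report["stages"].append("decompose")

    analysis = analyze_artifacts(
        series,
        selected_energies=cfg.selected_energies,
        metal_threshold_hu=cfg.metal_threshold_hu,
        min_metal_area=cfg.min_metal_area,
        support_threshold_hu=cfg.support_threshold_hu,
        delta_hu=cfg.sts_delta_hu,
        sts1_erosion_px=cfg.sts1_erosion_px,
        sts2_erosion_px=cfg.sts2_erosion_px,
        dilation_px=cfg.dilation_px,
        n_angles=cfg.n_angles,
    )
    if not analysis.metal_found:
        report["no_metal"] = True
        corrected = VMISeries([im.copy() for im in series])
        return RMARResult(
            corrected=corrected, mbi=mbi, no_metal=True, report=report
        )
    assert analysis.masks is not None and analysis.curve is not None
    masks = analysis.masks
    report["stages"].append("detect")
    report["optimal_kev"] = analysis.optimal_kev
    report["worst_kev"] = analysis.worst_kev
    report["cost_curve"] = {
        "energies_kev": list(analysis.curve.energies_kev),
        "raw": list(analysis.curve.raw_costs),
        "normalized": list(analysis.curve.normalized_costs),
    }
    report["mask_areas_px"] = {
        "metal": int(masks.metal.sum()),
        "support": int(masks.support.sum()),
        "artifact": int(masks.artifact.sum()),
        "artifact_free": int(masks.artifact_free.sum()),
    }

    vmi0 = series.at(analysis.optimal_kev)
    model_w = fit_mapping(vmi0, mbi.water, masks, cfg.bone_exclude_hu, "water")
    model_b = fit_mapping(vmi0, mbi.bone, masks, cfg.bone_exclude_hu, "bone")
    report["stages"].append("fit")
    report["models"] = {
        m.target: {
            "coefficients": list(m.coefficients),
            "hu_domain": list(m.hu_domain),
            "n_fit": m.n_fit,
            "residual_rms": m.residual_rms,
        }
        for m in (model_w, model_b)
    }

    improved = correct_mbis(mbi, masks, model_w, model_b, vmi0)
    report["stages"].append("correct")

    out_energies = (
        list(series.energies_kev)
        if cfg.output_energies is None
        else sorted(float(e) for e in cfg.output_energies)
    )
    in_energies = list(series.energies_kev)
    corrected_images = []
    for e in out_energies:
        synth = synthesize_vmi(improved, e, table)
        if e in in_energies:
            # splice: only artifact-region pixels change, metal and all
            # clean pixels are copied from the measured VMI
            base = series.at(e).copy(provenance="corrected")
            base.pixels[masks.artifact] = synth.pixels[masks.artifact]
            corrected_images.append(base)
        else:
            synth.provenance = "corrected"
            nearest = series.at(
                min(in_energies, key=lambda x: abs(x - e))
            )
            synth.pixels[masks.metal] = nearest.pixels[masks.metal]
            corrected_images.append(synth)
    corrected = VMISeries(corrected_images)
    report["stages"].append("synthesize")
    report["output_energies_kev"] = out_energies

    return RMARResult(
        corrected=corrected,
        mbi=mbi,
        improved_mbi=improved,
        masks=masks,
        curve=analysis.curve,
        models={"water": model_w, "bone": model_b},
        report=report,
    )


@dataclass
class ROIStats:
    """Mean HU in a region of interest against a reference value."""

    roi: CircleROI
    mean_hu: float
    ref_hu: float

    @property
    def delta_ct(self) -> float:
        return self.mean_hu - self.ref_hu


def delta_ct(img: CTImage, roi: CircleROI, ref_hu: float) -> ROIStats:
    """ROI accuracy metric: mean HU minus the reference value."""
    m = roi.mask(img.shape)
    if not m.any():
        raise ValueError("ROI lies outside the image")
    return ROIStats(roi=roi, mean_hu=float(img.pixels[m].mean()), ref_hu=float(ref_hu))


def line_profile(
    img: CTImage,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int = 200,
) -> np.ndarray:
    """Bilinear profile along a segment; returns (distance_mm, HU) rows."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    for p in (p0, p1):
        if not (0 <= p[0] <= img.shape[0] - 1 and 0 <= p[1] <= img.shape[1] - 1):
            raise ValueError(f"endpoint {tuple(p)} outside image {img.shape}")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    hu = ndimage.map_coordinates(img.pixels, [rows, cols], order=1, mode="nearest")
    sr, sc = img.spacing
    length = np.hypot((p1[0] - p0[0]) * sr, (p1[1] - p0[1]) * sc)
    return np.column_stack([t * length, hu])
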