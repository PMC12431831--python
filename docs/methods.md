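# Methods

## The correction model

rMAR assumes that in spectral CT the VMI at energy `E` and the
water/bone basis images are linked pixelwise by

    HU(E) = (1000/ρ_w) · [ (m_w(E)/m_w(E))·f_w + (m_b(E)/m_w(E))·f_b ] − 1000

with ρ_w = 1 g/cm³ and m(E) the mass attenuation coefficients. The
factor 1000/ρ_w is the only reading consistent with the Hounsfield
definition: a pure-water pixel (f_w = ρ_w, f_b = 0) must read 0 HU at
every energy. Basis images carry density units (g/cm³); negative bone
values are physical for water-like materials that are not exactly
water (solid water decomposes to f_w ≈ 1.015, f_b slightly negative)
and are never clipped.

The correction itself rests on two assumptions:

1. a high-energy VMI with acceptable artifact content exists (the
   method cannot improve on it — corrected low-energy values converge
   to the optimal VMI's quality in the artifact region);
2. in artifact-free tissue, basis density is a smooth single-valued
   function of the optimal VMI's HU, well approximated by a quadratic.
   This holds when the scanned materials lie near a one-parameter
   family (soft tissue / water mixtures); it is the reason bone
   (> 150 HU on the optimal VMI by default) and metal are excluded
   from the fit.

## Pipeline stages and parameters

| parameter | default | role |
| --- | --- | --- |
| decomposition pair | series min/max keV | energies for the 2×2 basis solve |
| selected energies | 70/80/100/120/140 keV ∩ series | cost-curve candidates |
| metal threshold | 2500 HU | threshold segmentation (titanium ≫ 3000 HU in VMIs, bone < 2000 HU); components < 9 px discarded |
| support threshold | −500 HU | body mask (hole-filled) so row medians are not dominated by air |
| STS band | ±10 HU around the row median | artifact flagging |
| STS morphology | dilation r=2, then erosion r=4 (STS1) / r=1 (STS2) | bridge streaks, prune isolated flags |
| bone exclusion | 150 HU | fit-domain cut on the optimal VMI |
| projection angles | 180 over [0, 180) | preliminary MAR Radon grid |

STS1 runs on the worst-energy artifact image (obvious artifact
region), STS2 on the optimal-energy one (finer artifact-free split);
f_M1 is their union inside the body, off metal. Rows with fewer than
3 in-support pixels are skipped (median ill-defined). Tie-breaks in
energy selection: equal costs resolve to the higher energy for the
optimal VMI and the lower for the worst, matching the physical prior
that artifacts decline with energy.

## Preliminary MAR: numerical form

The coarse correction exists only to expose artifact content; its
output is never returned to the user. Metal is separated from soft
tissue *before* projection (metal pixels are filled with the median HU
of a 3-px surrounding shell); otherwise the implant's own ~8000-HU
projection dominates the interpolated residual and its ramp-filtered
sidelobes blanket the artifact image. Because filtered back projection
is linear, the corrected image is computed as `input − FBP(residual)`
where the residual sinogram is nonzero only in metal-trace bins; the
naive route — FBP of the full interpolated sinogram — adds the
forward/back-projection round-trip error (~28 HU RMS at 256 px with
metal present) to every pixel and destroys the STS row statistics.

A known limitation: the correction lowers the RMS error to ground
truth substantially (e.g. 140 → 80 HU at 70 keV on the two-rod
phantom) but *raises* the plain TV cost of the image, because it swaps
smooth low-TV artifact bands for low-amplitude high-frequency
interpolation residue. TV is a useful *ranking* statistic across
energies (the artifact-image cost curve is monotone in energy) but not
a before/after improvement metric for this operator.

## The regional fit

Ordinary least squares on the Vandermonde design `(1, HU, HU²)`;
rank < 3 (constant or collinear HU) and fits on fewer than 100 pixels
are refused. Evaluation is clamped to the fitted HU domain — streak
pixels can lie far outside it and an unclamped quadratic extrapolates
violently. Water and bone models are fitted independently on the same
pixel set. Corrected VMIs are assembled by splicing synthesized values
into the measured image only inside f_M1, so the correction is exactly
local and metal pixels are always the measured ones; output energies
absent from the input series are fully synthesized (metal copied from
the nearest measured energy).

## The simulator and what it does (not) emulate

`rmar.phantom` rasterizes disc phantoms with area-weighted
anti-aliased edges (painter's order). The default study is a 200 mm
solid-water cylinder (1.015 g/cm³, the industry-typical solid-water
density) with two 10 mm titanium rods (4.506 g/cm³) 40 mm either side
of center, 350 mm field of view, 256×256 grid (512 available).
Three 8 mm evaluation ROIs sit on the inter-rod axis at the center and
halfway toward each rod, where the dark-band artifact concentrates.
Ground truth is always the exact monochromatic synthesis from the true
basis images with metal replaced by the surrounding material — the
"all-water insertions" scan — through the same synthesis code path as
the pipeline.

Physics mode emulates a dual-layer acquisition at 140 kV: a
Kramers-shaped bremsstrahlung fluence hardened by 3 cm water-equivalent
filtration, split between detector layers by a logistic in energy
(split 68 keV, sharpness 5 → layer mean energies ≈ 45/81 keV);
polychromatic line integrals per layer from Radon transforms of the
per-material density maps; optional Poisson noise at 4×10⁵ photons/bin
(VMI noise ≈ 10 HU, a high-dose phantom protocol; a 0.1-photon floor
bounds photon starvation behind the rods); a water beam-hardening
calibration per layer (the standard single-material scanner
calibration — without it the pseudo-monochromatic treatment leaves a
global cupping bias and metal is no longer the sole artifact source);
ramp-filtered FBP per layer; image-domain decomposition of the two
layer images treated as monochromatic at their mean detected energies;
VMI synthesis. Titanium's beam hardening and starvation survive the
water calibration and propagate into streaks that strengthen toward
low keV.

The split and photon-count defaults were calibrated once so the
simulator reproduces the study conditions the method targets:
substantial low-energy artifacts (mean |ΔCT| ≈ 30 HU at 70 keV over
the inter-rod ROIs) with a comparatively clean optimal VMI. Fast mode
replaces physics with an analytic streak field scaled by
`(m_Ti(E)/m_Ti(140 keV))^γ` for cheap unit tests.

Not emulated: scatter, detector cross-talk, helical geometry, vendor
spectral-reconstruction algorithms (real dual-layer systems decompose
in the projection domain with statistical denoising), patient anatomy.
Passing tests therefore demonstrate the method's behavior under
beam hardening and photon starvation from titanium in a homogeneous
water background — not performance on clinical anatomy, irregular
implants, or vendor-specific VMI noise textures.

## Numerical choices

- Attenuation: standard reference values (water, ICRU-44 cortical
  bone, titanium; 20–200 keV) with log-log linear interpolation; exact
  at grid points; energies outside the span are errors, not
  extrapolations.
- Decomposition rejects energy pairs whose 2×2 matrix determinant is
  below 1e-8 of the squared matrix norm (e.g. equal energies).
- TV uses forward differences with the last row/column omitted; with
  an exclusion mask, a term is kept only if the pixel and both forward
  neighbours are outside the mask.
- The metal trace in the sinogram is any bin whose metal-mask
  projection exceeds 0.05 px of path length.
- Simulation problem sizes: 256×256 grid, 360 projection angles,
  1 keV spectral steps; the 20-trial robustness study randomizes rod
  offset (30–50 mm) and axis angle with three ROIs following the axis.
- Determinism: every stochastic step draws from one seeded generator;
  the correction pipeline itself is deterministic given its inputs.

## Known limitations

- The corrected low-energy VMI inherits whatever artifact the optimal
  VMI retains; severe photon starvation that corrupts every energy
  defeats the method.
- The quadratic mapping is global over the artifact-free region; a
  heterogeneous slice whose tissues fall off a single HU-to-density
  curve would need a spatially aware model (out of scope).
- Metal-adjacent partial-volume pixels are neither metal nor reliably
  artifact-flagged; blooming at rod boundaries is not corrected.
- The array container stores one 2D series per file; volumes are
  processed slice by slice.
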