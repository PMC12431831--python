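"""Digital dual-layer spectral-CT phantom simulator.

Generates artifact-bearing VMI series with matching artifact-free
ground truth from a 2D disc phantom: by default a 200 mm solid-water
cylinder holding two 10 mm titanium rods, imaged at 140 kV on a
dual-layer detector (the superficial layer captures the low-energy
photons, the deep layer the rest).

Physics mode runs the full pathway: polychromatic forward projection
per detector layer, optional Poisson photon noise (photon starvation
behind the rods), filtered back projection per layer, image-domain
two-point decomposition treating each layer reconstruction as a
pseudo-monochromatic image at its mean detected energy, then VMI
synthesis.  Beam hardening and starvation propagate into the
energy-dependent streaks the correction pipeline is built to remove —
worse at low keV, milder at high keV.

Ground truth is always the exact monochromatic synthesis from the true
basis images with all metal insertions replaced by the surrounding
material ("all water insertions"), sharing one code path with
:mod:`rmar.spectral`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.transform import iradon, radon

from .core import CTImage, MBIPair, VMISeries
from .spectral import AttenuationTable, decompose_mbi, mass_atten, synthesize_series

__all__ = [
    "Disc",
    "PhantomSpec",
    "Phantom",
    "SpectrumModel",
    "default_spectrum",
    "make_phantom",
    "simulate_series",
    "default_fixtures",
    "Fixture",
    "CircleROI",
]

#: attenuation material and default physical density (g/cm3) per phantom material
MATERIALS: dict[str, tuple[str | None, float]] = {
    "air": (None, 0.0),
    "water": ("water", 1.0),
    "solid_water": ("water", 1.015),  # industry-typical solid-water density
    "bone": ("bone", 1.92),
    "titanium": ("titanium", 4.506),
}
METAL_MATERIALS = frozenset({"titanium"})

PHOTON_FLOOR = 0.1  # photons per bin before the log (starvation guard)


@dataclass
class Disc:
    """Circular primitive; center is (x, y) in mm from the grid center."""

    center_mm: tuple[float, float]
    radius_mm: float
    material: str
    density: float | None = None  # g/cm3; default per MATERIALS

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValueError(
                f"unknown material {self.material!r}; have {sorted(MATERIALS)}"
            )
        if self.radius_mm <= 0:
            raise ValueError("disc radius must be positive")
        rho = MATERIALS[self.material][1] if self.density is None else self.density
        if self.material != "air" and rho <= 0:
            raise ValueError("density must be positive")
        self.density = rho


@dataclass
class PhantomSpec:
    """Geometry of a 2D disc phantom (painter's order: later discs win)."""

    fov_mm: float = 350.0
    grid: int = 256
    background: str = "air"
    primitives: list[Disc] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.background not in MATERIALS:
            raise ValueError(f"unknown background {self.background!r}")
        for p in self.primitives:
            r = float(np.hypot(*p.center_mm)) + p.radius_mm
            if r > self.fov_mm / 2:
                raise ValueError(
                    f"primitive {p.material} at {p.center_mm} extends outside FOV"
                )

    @property
    def spacing_mm(self) -> float:
        return self.fov_mm / self.grid


@dataclass
class Phantom:
    """Rasterized phantom: label/density maps and true basis images."""

    spec: PhantomSpec
    labels: np.ndarray            # index into .material_names
    material_names: list[str]
    density_by_channel: dict[str, np.ndarray]  # attenuation material -> g/cm3 map
    true_mbi: MBIPair
    metal: np.ndarray

    @property
    def spacing(self) -> tuple[float, float]:
        s = self.spec.spacing_mm
        return (s, s)


def _coverage(spec: PhantomSpec, disc: Disc) -> np.ndarray:
    """Anti-aliased disc coverage in [0, 1] (linear ramp over one pixel)."""
    n, px = spec.grid, spec.spacing_mm
    # pixel-center coordinates, x right / y up, origin at grid center
    c = (np.arange(n) - (n - 1) / 2.0) * px
    x = c[None, :]
    y = -c[:, None]
    d = np.hypot(x - disc.center_mm[0], y - disc.center_mm[1])
    return np.clip(0.5 + (disc.radius_mm - d) / px, 0.0, 1.0)


def _mbi_of(material: str, density: float) -> tuple[float, float]:
    channel, _ = MATERIALS[material]
    if channel == "water":
        return density, 0.0
    if channel == "bone":
        return 0.0, density
    return 0.0, 0.0  # air; metal never reaches here


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a spec with area-weighted (anti-aliased) disc edges.

    The true basis images encode the "all water insertions" ground
    truth: metal primitives paint the density channels used by the
    projector but leave the true MBIs showing whatever material lies
    beneath them.
    """
    n = spec.grid
    channels = {m: np.zeros((n, n)) for m in ("water", "bone", "titanium")}
    water_mbi = np.zeros((n, n))
    bone_mbi = np.zeros((n, n))
    labels = np.zeros((n, n), dtype=np.int32)
    names = [spec.background]

    bg_channel, bg_rho = MATERIALS[spec.background]
    if bg_channel is not None:
        channels[bg_channel][:] = bg_rho
    w0, b0 = _mbi_of(spec.background, bg_rho)
    water_mbi[:] = w0
    bone_mbi[:] = b0

    metal = np.zeros((n, n), dtype=bool)
    for disc in spec.primitives:
        cov = _coverage(spec, disc)
        inside = cov > 0.5
        if disc.material in names:
            lab = names.index(disc.material)
        else:
            names.append(disc.material)
            lab = len(names) - 1
        labels[inside] = lab
        keep = 1.0 - cov
        for ch in channels.values():
            ch *= keep
        channel, _ = MATERIALS[disc.material]
        if channel is not None:
            channels[channel] += cov * disc.density
        if disc.material in METAL_MATERIALS:
            metal |= inside
        else:
            w, b = _mbi_of(disc.material, disc.density)
            water_mbi = keep * water_mbi + cov * w
            bone_mbi = keep * bone_mbi + cov * b

    spacing = (spec.spacing_mm, spec.spacing_mm)
    return Phantom(
        spec=spec,
        labels=labels,
        material_names=names,
        density_by_channel=channels,
        true_mbi=MBIPair(water_mbi, bone_mbi, spacing),
        metal=metal,
    )


@dataclass
class SpectrumModel:
    """Detected photon-weight spectra for the two detector layers."""

    energies_kev: np.ndarray
    w_low: np.ndarray
    w_high: np.ndarray
    kvp: float = 140.0

    def __post_init__(self) -> None:
        self.energies_kev = np.asarray(self.energies_kev, dtype=float)
        self.w_low = np.asarray(self.w_low, dtype=float)
        self.w_high = np.asarray(self.w_high, dtype=float)
        if np.any(self.w_low < 0) or np.any(self.w_high < 0):
            raise ValueError("spectral weights must be non-negative")
        self.w_low = self.w_low / self.w_low.sum()
        self.w_high = self.w_high / self.w_high.sum()
        if self.mean_kev("low") >= self.mean_kev("high"):
            raise ValueError("low layer must detect the softer spectrum")

    def mean_kev(self, layer: Literal["low", "high"]) -> float:
        w = self.w_low if layer == "low" else self.w_high
        return float(np.sum(w * self.energies_kev))


def default_spectrum(
    kvp: float = 140.0,
    table: AttenuationTable | None = None,
    filtration_cm_water: float = 3.0,
    split_kev: float = 68.0,
    split_sharpness: float = 5.0,
) -> SpectrumModel:
    """Parametric 140 kV dual-layer spectrum.

    A Kramers-shaped bremsstrahlung fluence hardened by a water-equivalent
    inherent filtration, split between layers by a smooth logistic in
    energy: the superficial (low) layer preferentially absorbs photons
    below ``split_kev``.  Not a vendor spectrum — just enough physics to
    produce beam hardening with a realistic low/high energy separation.
    """
    table = table or AttenuationTable.default()
    e = np.arange(20.0, kvp + 0.5)
    fluence = np.maximum(kvp - e, 0.0) / e  # Kramers photon fluence
    mw = mass_atten(table, "water", e)
    fluence = fluence * np.exp(-mw * 1.0 * filtration_cm_water)
    p_low = 1.0 / (1.0 + (e / split_kev) ** split_sharpness)
    return SpectrumModel(e, fluence * p_low, fluence * (1 - p_low), kvp=kvp)


def _project_channels(
    phantom: Phantom, theta: np.ndarray
) -> dict[str, np.ndarray]:
    """Areal-density sinograms (g/cm^2) per attenuation channel."""
    px_cm = phantom.spec.spacing_mm / 10.0
    out = {}
    for name, rho in phantom.density_by_channel.items():
        if np.any(rho):
            out[name] = radon(rho, theta=theta, circle=False) * px_cm
    return out


def _layer_sinogram(
    proj: dict[str, np.ndarray],
    weights: np.ndarray,
    energies: np.ndarray,
    table: AttenuationTable,
    rng: np.random.Generator | None,
    photons: float,
) -> np.ndarray:
    """Polychromatic effective line integrals -ln(I/I0) for one layer."""
    shape = next(iter(proj.values())).shape
    intensity = np.zeros(shape)
    for w, e in zip(weights, energies):
        if w == 0.0:
            continue
        att = np.zeros(shape)
        for name, sino in proj.items():
            att += mass_atten(table, name, e) * sino
        intensity += w * np.exp(-att)
    if rng is not None and photons > 0:
        counts = rng.poisson(intensity * photons).astype(float)
        counts = np.maximum(counts, PHOTON_FLOOR)
        intensity = counts / photons
    return -np.log(intensity)


def _water_bhc(
    p: np.ndarray,
    weights: np.ndarray,
    energies: np.ndarray,
    e_mono: float,
    table: AttenuationTable,
) -> np.ndarray:
    """Water beam-hardening correction for one detector layer.

    Maps each polychromatic line integral to the monochromatic line
    integral at ``e_mono`` of the water thickness that would have
    produced it — the standard single-material calibration every
    scanner applies.  Pure-water objects therefore reconstruct without
    cupping; metal, which hardens the beam far more than water,
    survives as the artifact source.
    """
    mw = mass_atten(table, "water", energies)
    thickness = np.linspace(0.0, 150.0, 601)  # g/cm^2 of water
    p_poly = -np.log(np.exp(-np.outer(thickness, mw)) @ weights)
    mu_mono = mass_atten(table, "water", e_mono)
    # monotone curve: invert by interpolation, linear beyond the grid
    out = np.interp(p, p_poly, thickness * mu_mono)
    over = p > p_poly[-1]
    if np.any(over):
        slope = (thickness[-1] - thickness[-2]) * mu_mono / (p_poly[-1] - p_poly[-2])
        out[over] = thickness[-1] * mu_mono + (p[over] - p_poly[-1]) * slope
    return out


def simulate_series(
    phantom: Phantom,
    spectra: SpectrumModel | None = None,
    energies: Sequence[float] = (70.0, 80.0, 100.0, 120.0, 140.0),
    mode: Literal["physics", "fast"] = "physics",
    seed: int | None = None,
    photons: float = 4e5,
    n_angles: int = 360,
    streak_gamma: float = 1.0,
    streak_amp_hu: float = 60.0,
    table: AttenuationTable | None = None,
) -> tuple[VMISeries, VMISeries]:
    """Simulate an artifact-bearing VMI series plus its ground truth.

    Returns ``(artifact_series, truth_series)``.  ``photons`` is the
    unattenuated photon count per detector bin per layer; set it to 0
    (or ``seed=None`` in fast mode) for a noise-free run.  Deterministic
    given ``seed``.
    """
    table = table or AttenuationTable.default()
    truth = synthesize_series(phantom.true_mbi, energies, table)
    for im in truth.images:
        im.provenance = "truth"

    if mode == "fast":
        rng = np.random.default_rng(seed)
        streaks = _fast_streaks(phantom, rng) if phantom.metal.any() else None
        arts = []
        for im in truth.images:
            scale = (
                mass_atten(table, "titanium", im.energy_kev)
                / mass_atten(table, "titanium", 140.0)
            ) ** streak_gamma
            px = im.pixels.copy()
            if streaks is not None:
                px += streak_amp_hu * scale * streaks
            arts.append(CTImage(px, im.spacing, im.energy_kev, "simulated"))
        return VMISeries(arts), truth

    if mode != "physics":
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed) if (seed is not None and photons > 0) else None
    spectra = spectra or default_spectrum(table=table)
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    proj = _project_channels(phantom, theta)
    if not proj:  # empty phantom: truth is exact
        return VMISeries([im.copy(provenance="simulated") for im in truth]), truth
    px_cm = phantom.spec.spacing_mm / 10.0
    n = phantom.spec.grid
    pseudo = []
    for layer, weights in (("low", spectra.w_low), ("high", spectra.w_high)):
        p = _layer_sinogram(proj, weights, spectra.energies_kev, table, rng, photons)
        p = _water_bhc(p, weights, spectra.energies_kev, spectra.mean_kev(layer), table)
        mu = iradon(p, theta=theta, filter_name="ramp", circle=False,
                    output_size=n) / px_cm
        e_mean = spectra.mean_kev(layer)
        mu_w = mass_atten(table, "water", e_mean) * table.rho_w
        hu = 1000.0 * (mu - mu_w) / mu_w
        pseudo.append(CTImage(hu, phantom.spacing, e_mean, f"layer-{layer}"))
    mbi = decompose_mbi(pseudo[0], pseudo[1], table)
    series = synthesize_series(mbi, energies, table)
    for im in series.images:
        im.provenance = "simulated"
    return series, truth


def _fast_streaks(phantom: Phantom, rng: np.random.Generator) -> np.ndarray:
    """Cheap deterministic streak pattern radiating from each metal rod."""
    n = phantom.spec.grid
    c = np.arange(n) - (n - 1) / 2.0
    yy, xx = np.meshgrid(-c, c, indexing="ij")
    out = np.zeros((n, n))
    lab, num = _components(phantom.metal)
    for k in range(1, num + 1):
        rows, cols = np.nonzero(lab == k)
        cy, cx = rows.mean(), cols.mean()
        dy = yy - (-(cy - (n - 1) / 2.0))
        dx = xx - (cx - (n - 1) / 2.0)
        phi = np.arctan2(dy, dx)
        r = np.hypot(dx, dy) + 1.0
        phase = rng.uniform(0, 2 * np.pi)
        out += np.cos(10 * phi + phase) * np.exp(-r / (n / 4.0))
    out[phantom.metal] = 0.0
    return out


def _components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    from scipy import ndimage

    lab, num = ndimage.label(mask)
    return lab, num


@dataclass
class CircleROI:
    """Circular region of interest in pixel coordinates."""

    center_px: tuple[float, float]  # (row, col)
    radius_px: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        d2 = (rr - self.center_px[0]) ** 2 + (cc - self.center_px[1]) ** 2
        return d2 <= self.radius_px**2


@dataclass
class Fixture:
    """A named simulation scenario with evaluation geometry attached."""

    name: str
    spec: PhantomSpec
    rois: list[CircleROI]
    profile: tuple[tuple[float, float], tuple[float, float]]  # (p0, p1) in px
    reference_hu: dict[float, float]  # energy -> true background HU


def _mm_to_px(spec: PhantomSpec, x_mm: float, y_mm: float) -> tuple[float, float]:
    n, px = spec.grid, spec.spacing_mm
    col = x_mm / px + (n - 1) / 2.0
    row = -y_mm / px + (n - 1) / 2.0
    return (row, col)


def rod_phantom_spec(
    grid: int = 256,
    rod_offset_mm: float = 40.0,
    rod_angle_deg: float = 0.0,
    rod_radius_mm: float = 5.0,
) -> PhantomSpec:
    """200 mm solid-water cylinder with two symmetric 10 mm Ti rods."""
    a = np.deg2rad(rod_angle_deg)
    dx, dy = rod_offset_mm * np.cos(a), rod_offset_mm * np.sin(a)
    return PhantomSpec(
        fov_mm=350.0,
        grid=grid,
        primitives=[
            Disc((0.0, 0.0), 100.0, "solid_water"),
            Disc((dx, dy), rod_radius_mm, "titanium"),
            Disc((-dx, -dy), rod_radius_mm, "titanium"),
        ],
    )


def phantom_rois(
    spec: PhantomSpec,
    rod_offset_mm: float,
    rod_angle_deg: float = 0.0,
    roi_radius_mm: float = 8.0,
) -> list[CircleROI]:
    """Three ROIs on the inter-rod axis: center and halfway to each rod."""
    a = np.deg2rad(rod_angle_deg)
    r_px = roi_radius_mm / spec.spacing_mm
    out = []
    for f in (0.0, 0.5, -0.5):
        x, y = f * rod_offset_mm * np.cos(a), f * rod_offset_mm * np.sin(a)
        out.append(CircleROI(_mm_to_px(spec, x, y), r_px))
    return out


def random_rod_phantom(
    seed: int, grid: int = 256
) -> tuple[PhantomSpec, list[CircleROI]]:
    """Randomized variant of the two-rod phantom for robustness studies.

    Rod offset is drawn uniformly in 30-50 mm from center and the rod
    axis angle uniformly in [0, 180); the three evaluation ROIs follow
    the axis (center and halfway toward each rod).
    """
    rng = np.random.default_rng(seed)
    offset = float(rng.uniform(30.0, 50.0))
    angle = float(rng.uniform(0.0, 180.0))
    spec = rod_phantom_spec(grid=grid, rod_offset_mm=offset, rod_angle_deg=angle)
    return spec, phantom_rois(spec, offset, angle)


def default_fixtures(
    grid: int = 256, table: AttenuationTable | None = None
) -> dict[str, Fixture]:
    """Standard test scenarios: rod phantom, no-metal control, asymmetric."""
    table = table or AttenuationTable.default()
    rho_sw = MATERIALS["solid_water"][1]
    energies = (70.0, 80.0, 100.0, 120.0, 140.0)
    # solid water HU is energy-independent for a pure water-channel material
    ref = {e: 1000.0 * (rho_sw / table.rho_w) - 1000.0 for e in energies}

    rods = rod_phantom_spec(grid=grid)
    no_metal = PhantomSpec(
        fov_mm=350.0, grid=grid, primitives=[Disc((0.0, 0.0), 100.0, "solid_water")]
    )
    asym = PhantomSpec(
        fov_mm=350.0,
        grid=grid,
        primitives=[
            Disc((0.0, 0.0), 100.0, "solid_water"),
            Disc((45.0, 20.0), 6.0, "titanium"),
            Disc((-30.0, -35.0), 4.0, "titanium"),
        ],
    )
    profile = (_mm_to_px(rods, -90.0, 20.0), _mm_to_px(rods, 90.0, 20.0))
    center_roi = [CircleROI(_mm_to_px(no_metal, 0.0, 0.0), 8.0 / no_metal.spacing_mm)]
    return {
        "rods": Fixture("rods", rods, phantom_rois(rods, 40.0), profile, ref),
        "no_metal": Fixture("no_metal", no_metal, center_roi, profile, ref),
        "asymmetric": Fixture(
            "asymmetric", asym, phantom_rois(asym, 40.0, rod_angle_deg=30.0),
            profile, ref,
        ),
    }
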