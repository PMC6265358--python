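"""Synthetic ⁹⁰Y-PET phantom and patient-like case generation.

Stands in for physical phantom scans and patient data: piecewise-constant
ground-truth activity (warm liver, hot lesions, cold necrotic cores), a
Gaussian point-spread blur emulating reconstructed PET resolution, and
spatially correlated signal-dependent noise calibrated to a target
coefficient of variation in the warm liver background.

The phantom suite reproduces three bench configurations on the PET grid
(4.07 × 4.07 × 3 mm voxels): a 60 cm³ hot sphere in a cold background, the
same sphere in a warm 1200 cm³ liver at a 5:1 tumor-to-background ratio
(TBR), and an 8/16/29 cm³ lesion set at TBRs 5.1/6.2/5.5.  The patient-like
cohort draws lesion volumes log-uniformly over 2–818 cm³, assigns partial
perfusion or necrotic rims at random, and displaces the morphologic mask by
a small rigid translation emulating residual registration error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import GeometryError, Mask, VoxelImage

# PET reconstruction grid used throughout (mm)
PET_SPACING: tuple[float, float, float] = (4.07, 4.07, 3.0)
DEFAULT_GRID_SHAPE: tuple[int, int, int] = (57, 45, 42)
# Liver ellipsoid semi-axes (mm): volume 4/3·π·95·70·43 ≈ 1198 cm³
LIVER_SEMI_AXES: tuple[float, float, float] = (95.0, 70.0, 43.0)
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548


def sphere_radius_mm(volume_cm3: float) -> float:
    """Radius of a sphere of the given volume (cm³ → mm)."""
    return (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def ellipsoid_volume_cm3(semi_axes) -> float:
    a, b, c = semi_axes
    return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and uptake of one lesion.

    ``perfused_fraction`` < 1 removes a random half-space cut of the lesion
    from the uptake region (partial perfusion); ``core_fraction`` > 0 zeroes
    a concentric ellipsoid of that fractional radius (necrotic core, rim
    uptake).  The morphologic truth mask is always the full shape.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    tbr: float
    perfused_fraction: float = 1.0
    core_fraction: float = 0.0
    name: str = "lesion"

    def __post_init__(self) -> None:
        if self.tbr < 0:
            raise ValueError("tbr must be non-negative")
        if not (0.0 <= self.perfused_fraction <= 1.0):
            raise ValueError("perfused_fraction must be in [0, 1]")
        if not (0.0 <= self.core_fraction < 1.0):
            raise ValueError("core_fraction must be in [0, 1)")

    @property
    def target_volume_cm3(self) -> float:
        return ellipsoid_volume_cm3(self.semi_axes)

    @staticmethod
    def sphere(center, volume_cm3: float, tbr: float, **kw) -> "LesionSpec":
        r = sphere_radius_mm(volume_cm3)
        return LesionSpec(center=tuple(center), semi_axes=(r, r, r), tbr=tbr, **kw)


@dataclass(frozen=True)
class NoiseSpec:
    """Spatially correlated, signal-dependent Gaussian noise model.

    ``background_cov`` is the target coefficient of variation realized in
    the warm liver background; ``correlation_sigma`` (voxels) sets the
    spatial correlation length of the noise texture.  ``floor_fraction``
    keeps a small noise floor in cold regions (fraction of the reference
    background level added under the square root).
    """

    model: str = "gaussian_correlated"
    background_cov: float = 0.25
    correlation_sigma: float = 1.0
    floor_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.background_cov < 0:
            raise ValueError("background_cov must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic case."""

    lesions: tuple[LesionSpec, ...]
    total_activity_gbq: float = 3.0
    liver_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    liver_semi_axes: tuple[float, float, float] = LIVER_SEMI_AXES
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing: tuple[float, float, float] = PET_SPACING
    psf_fwhm_mm: float = 5.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    cold_background: bool = False
    seed: int = 0
    name: str = "phantom"


@dataclass
class Case:
    """A simulated case: truth activity, degraded PET, and masks."""

    case_id: str
    patient_id: str
    spec: PhantomSpec
    truth_activity: VoxelImage
    pet: VoxelImage
    truth_masks: list[Mask]
    ms_masks: list[Mask]
    liver_mask: Mask
    lesion_ids: list[str]


def _blank_grid(spec: PhantomSpec) -> VoxelImage:
    shape = tuple(spec.grid_shape)
    spacing = tuple(spec.spacing)
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return VoxelImage(values=np.zeros(shape), spacing=spacing, origin=origin, unit="Bq/mL")


def ellipsoid_mask(grid: VoxelImage, center, semi_axes) -> Mask:
    """Rasterize an axis-aligned ellipsoid by voxel-center inclusion."""
    coords = [np.asarray(grid.origin)[d] + np.arange(grid.shape[d]) * grid.spacing[d]
              for d in range(3)]
    xs, ys, zs = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center
    a, b, c = semi_axes
    inside = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 + ((zs - cz) / c) ** 2 <= 1.0
    return Mask(values=inside, grid=grid)


def _perfused_region(grid: VoxelImage, lesion: LesionSpec, mask: Mask,
                     rng: np.random.Generator) -> np.ndarray:
    """Boolean uptake region for a lesion (core removal + half-space cut)."""
    region = mask.values.copy()
    if lesion.core_fraction > 0.0:
        core = ellipsoid_mask(grid, lesion.center,
                              tuple(s * lesion.core_fraction for s in lesion.semi_axes))
        region &= ~core.values
    if lesion.perfused_fraction < 1.0 and region.any():
        normal = rng.standard_normal(3)
        normal /= np.linalg.norm(normal)
        pts = grid.voxel_centers_mm(np.argwhere(region)) - np.asarray(lesion.center)
        proj = pts @ normal
        cut = np.quantile(proj, 1.0 - lesion.perfused_fraction)
        keep = proj >= cut
        sub = np.zeros_like(region)
        sub[tuple(np.argwhere(region).T)] = keep
        region = sub
    return region


def build_truth(spec: PhantomSpec) -> tuple[VoxelImage, list[Mask], Mask]:
    """Rasterize the piecewise-constant ground-truth activity map.

    Returns the activity image (Bq/mL), the per-lesion truth masks (full
    morphologic shapes) and the liver mask.  The background concentration is
    solved so that the total liver activity equals ``total_activity_gbq``
    and every lesion's perfused region sits at its specified TBR; with
    ``cold_background`` the background is zero and the total activity is
    apportioned to the lesions in proportion to tbr × perfused volume.
    """
    grid = _blank_grid(spec)
    liver = ellipsoid_mask(grid, spec.liver_center, spec.liver_semi_axes)
    rng = np.random.default_rng([spec.seed, 0xC0FFEE])

    masks: list[Mask] = []
    perfused: list[np.ndarray] = []
    occupied = np.zeros(grid.shape, dtype=bool)
    for les in spec.lesions:
        m = ellipsoid_mask(grid, les.center, les.semi_axes)
        if m.n_voxels == 0 or np.any(m.values & ~liver.values):
            raise GeometryError(f"lesion {les.name} extends outside the liver")
        if np.any(m.values & occupied):
            raise GeometryError(f"lesion {les.name} overlaps another lesion")
        occupied |= m.values
        masks.append(m)
        perfused.append(_perfused_region(grid, les, m, rng))

    v_mL = grid.voxel_volume_cm3  # 1 cm³ = 1 mL
    a_total = spec.total_activity_gbq * 1e9
    bg_region = liver.values & ~occupied
    values = np.zeros(grid.shape)
    if spec.cold_background:
        weight = sum(les.tbr * p.sum() * v_mL for les, p in zip(spec.lesions, perfused))
        if weight <= 0:
            raise GeometryError("cold background requires at least one perfused lesion")
        for les, p in zip(spec.lesions, perfused):
            values[p] = a_total * les.tbr / weight
    else:
        denom = bg_region.sum() * v_mL + sum(
            les.tbr * p.sum() * v_mL for les, p in zip(spec.lesions, perfused))
        c_b = a_total / denom
        values[bg_region] = c_b
        for les, p in zip(spec.lesions, perfused):
            values[p] = c_b * les.tbr
    return grid.with_values(values, unit="Bq/mL"), masks, liver


def apply_psf(img: VoxelImage, fwhm_mm: float) -> VoxelImage:
    """Gaussian blur with the given isotropic FWHM in mm (zero-padded)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return img.with_values(img.values.copy())
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / s for s in img.spacing]
    return img.with_values(ndimage.gaussian_filter(img.values, sigma=sigma_vox,
                                                   mode="constant", cval=0.0))


def add_noise(img: VoxelImage, noise: NoiseSpec, seed,
              background_mask: Mask | None = None,
              reference_level: float | None = None) -> VoxelImage:
    """Add correlated, signal-dependent Gaussian noise; negatives clip to 0.

    The per-voxel standard deviation is proportional to
    ``sqrt(signal + floor)`` and scaled so that the coefficient of variation
    at the reference background level equals ``noise.background_cov``.  The
    reference level defaults to the mean over ``background_mask`` (or the
    median positive voxel when no mask is given).
    """
    if noise.background_cov == 0:
        return img.with_values(img.values.copy())
    if reference_level is None:
        if background_mask is not None and background_mask.n_voxels > 0:
            reference_level = float(img.values[background_mask.values].mean())
        else:
            positive = img.values[img.values > 0]
            if positive.size == 0:
                return img.with_values(img.values.copy())
            reference_level = float(np.median(positive))
    rng = np.random.default_rng(seed)
    fieldv = rng.standard_normal(img.shape)
    if noise.correlation_sigma > 0:
        fieldv = ndimage.gaussian_filter(fieldv, sigma=noise.correlation_sigma,
                                         mode="constant", cval=0.0)
    fieldv /= fieldv.std()
    floor = noise.floor_fraction * reference_level
    sigma_ref = noise.background_cov * reference_level
    sigma_map = sigma_ref * np.sqrt((img.values + floor) / (reference_level + floor))
    out = np.clip(img.values + sigma_map * fieldv, 0.0, None)
    return img.with_values(out)


def degrade(activity: VoxelImage, spec: PhantomSpec, seed,
            background_mask: Mask | None = None,
            reference_level: float | None = None) -> VoxelImage:
    """PSF blur followed by noise: the simulated reconstructed PET image."""
    blurred = apply_psf(activity, spec.psf_fwhm_mm)
    return add_noise(blurred, spec.noise, seed, background_mask=background_mask,
                     reference_level=reference_level)


# ---------------------------------------------------------------------------
# Phantom suite
# ---------------------------------------------------------------------------

def phantom_suite_specs(seed: int = 0, noise: NoiseSpec | None = None) -> list[PhantomSpec]:
    """Specs for the three bench phantoms (cold sphere / warm sphere / lesion set)."""
    noise = noise if noise is not None else NoiseSpec()
    # warm-case background concentration for 3.0 GBq in a ~1200 cm³ liver
    # sets the cold sphere's activity so its concentration matches the warm one
    cold_activity = 3.0 * (5.0 * 60.0) / (1140.0 + 5.0 * 60.0)
    specs = [
        PhantomSpec(
            name="sphere60_cold",
            lesions=(LesionSpec.sphere((0, 0, 0), 60.0, tbr=5.0, name="sphere60"),),
            total_activity_gbq=cold_activity,
            cold_background=True,
            noise=noise, seed=seed,
        ),
        PhantomSpec(
            name="sphere60_warm",
            lesions=(LesionSpec.sphere((0, 0, 0), 60.0, tbr=5.0, name="sphere60"),),
            noise=noise, seed=seed,
        ),
        PhantomSpec(
            name="multilesion",
            lesions=(
                LesionSpec.sphere((-45.0, 0.0, 0.0), 8.0, tbr=5.1, name="sphere8"),
                LesionSpec.sphere((0.0, 0.0, 0.0), 16.0, tbr=6.2, name="sphere16"),
                LesionSpec(center=(50.0, 0.0, 0.0),
                           semi_axes=(24.0, 17.0, 29.0e3 * 3 / (4 * math.pi * 24.0 * 17.0)),
                           tbr=5.5, name="ovoid29"),
            ),
            noise=noise, seed=seed,
        ),
    ]
    return specs


def realize_case(spec: PhantomSpec, case_id: str, patient_id: str,
                 ms_masks: list[Mask] | None = None) -> Case:
    """Build truth and the degraded PET image for one spec."""
    activity, truth_masks, liver = build_truth(spec)
    occupied = np.zeros(activity.shape, dtype=bool)
    for m in truth_masks:
        occupied |= m.values
    bg = Mask(values=liver.values & ~occupied, grid=activity)
    ref = None
    if spec.cold_background:
        # no warm background: calibrate noise as if lesions sat at their TBR
        # over a warm background (same count level as the warm experiments)
        lesion_mean = float(activity.values[occupied].mean())
        mean_tbr = float(np.mean([l.tbr for l in spec.lesions]))
        ref = lesion_mean / mean_tbr
    pet = degrade(activity, spec, seed=[spec.seed, 0x9E7],
                  background_mask=bg, reference_level=ref)
    if ms_masks is None:
        ms_masks = truth_masks
    return Case(case_id=case_id, patient_id=patient_id, spec=spec,
                truth_activity=activity, pet=pet, truth_masks=truth_masks,
                ms_masks=ms_masks, liver_mask=liver,
                lesion_ids=[l.name for l in spec.lesions])


def make_phantom_suite(seed: int = 0, noise: NoiseSpec | None = None) -> list[Case]:
    """The three bench phantoms, degraded with the given seed."""
    return [realize_case(s, case_id=s.name, patient_id=s.name)
            for s in phantom_suite_specs(seed=seed, noise=noise)]


# ---------------------------------------------------------------------------
# Patient-like cohort
# ---------------------------------------------------------------------------

def _sample_lesion_geometry(rng: np.random.Generator, volume_cm3: float,
                            liver_semi_axes) -> tuple[np.ndarray, np.ndarray]:
    """Sample semi-axes and a center for a lesion inside the liver."""
    la = np.asarray(liver_semi_axes, dtype=float)
    r = sphere_radius_mm(volume_cm3)
    if r <= 0.75 * la.min():
        # near-spherical, mildly anisotropic
        p = rng.uniform(0.8, 1.25, size=3)
        p /= p.prod() ** (1 / 3)
        semi = r * p
    else:
        # large lesion: liver-proportional ellipsoid, centered
        s = (volume_cm3 * 1000.0 * 3 / (4 * math.pi * la.prod())) ** (1 / 3)
        return s * la, np.zeros(3)
    slack = la - semi - 4.0  # keep ≥ ~1 voxel off the capsule
    if np.any(slack <= 0):
        return semi, np.zeros(3)
    while True:
        u = rng.uniform(-1, 1, size=3)
        if (u ** 2).sum() <= 1.0:
            return semi, u * slack


def make_patient_cohort(n_patients: int, seed,
                        lesions_per_patient_range: tuple[int, int] = (1, 9),
                        registration_sigma_mm: float = 2.0,
                        noise: NoiseSpec | None = None,
                        volume_range_cm3: tuple[float, float] = (2.0, 818.0),
                        tbr_range: tuple[float, float] = (1.5, 8.0),
                        activity_range_gbq: tuple[float, float] = (0.6, 5.8),
                        ) -> list[Case]:
    """Simulate a patient-like cohort on the PET grid.

    Per patient: 1–9 lesions with log-uniform volumes, randomly assigned
    full/partial/rim perfusion, a patient-level administered activity, and
    morphologic (MS) masks displaced by a per-lesion rigid translation of
    per-axis Gaussian σ = ``registration_sigma_mm`` emulating residual
    registration error.  Deterministic given ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    noise = noise if noise is not None else NoiseSpec()
    lo, hi = lesions_per_patient_range
    cases: list[Case] = []
    for p in range(n_patients):
        rng = np.random.default_rng([seed, p, 0xFACADE])
        n_lesions = int(rng.integers(lo, hi + 1))
        volumes = np.exp(rng.uniform(np.log(volume_range_cm3[0]),
                                     np.log(volume_range_cm3[1]), size=n_lesions))
        volumes = np.sort(volumes)[::-1]  # place the big ones first
        activity = float(rng.uniform(*activity_range_gbq))

        probe = _blank_grid(PhantomSpec(lesions=(), seed=0))
        liver = ellipsoid_mask(probe, (0, 0, 0), LIVER_SEMI_AXES)
        occupied = np.zeros(probe.shape, dtype=bool)
        lesions: list[LesionSpec] = []
        for j, vol in enumerate(volumes):
            placed = False
            for _ in range(60):
                semi, center = _sample_lesion_geometry(rng, vol, LIVER_SEMI_AXES)
                cand = ellipsoid_mask(probe, tuple(center), tuple(semi))
                if cand.n_voxels == 0 or np.any(cand.values & ~liver.values):
                    continue
                grown = ndimage.binary_dilation(cand.values)
                if np.any(grown & occupied):
                    continue
                u = rng.uniform()
                if u < 0.5:
                    pf, cf = 1.0, 0.0
                elif u < 0.8:
                    pf, cf = float(rng.uniform(0.3, 1.0)), 0.0
                else:
                    pf, cf = 1.0, float(rng.uniform(0.3, 0.7))
                lesions.append(LesionSpec(center=tuple(center), semi_axes=tuple(semi),
                                          tbr=float(rng.uniform(*tbr_range)),
                                          perfused_fraction=pf, core_fraction=cf,
                                          name=f"p{p:02d}_l{j}"))
                occupied |= grown
                placed = True
                break
            if not placed:
                continue  # crowded liver: drop the lesion
        if not lesions:
            lesions = [LesionSpec.sphere((0, 0, 0), volumes[0] if len(volumes) else 10.0,
                                         tbr=5.0, name=f"p{p:02d}_l0")]

        spec = PhantomSpec(name=f"patient{p:02d}", lesions=tuple(lesions),
                           total_activity_gbq=activity, noise=noise, seed=int(
                               np.random.default_rng([seed, p, 7]).integers(2 ** 31)))
        activity_img, truth_masks, liver_mask = build_truth(spec)
        ms_masks = []
        for les, tm in zip(spec.lesions, truth_masks):
            shift = rng.normal(0.0, registration_sigma_mm, size=3) \
                if registration_sigma_mm > 0 else np.zeros(3)
            ms = ellipsoid_mask(activity_img,
                                tuple(np.asarray(les.center) + shift), les.semi_axes)
            if ms.n_voxels == 0:
                ms = tm
            ms_masks.append(ms)
        occupied = np.zeros(activity_img.shape, dtype=bool)
        for m in truth_masks:
            occupied |= m.values
        bg = Mask(values=liver_mask.values & ~occupied, grid=activity_img)
        pet = degrade(activity_img, spec, seed=[spec.seed, 0x9E7], background_mask=bg)
        cases.append(Case(case_id=spec.name, patient_id=f"p{p:02d}", spec=spec,
                          truth_activity=activity_img, pet=pet,
                          truth_masks=truth_masks, ms_masks=ms_masks,
                          liver_mask=liver_mask,
                          lesion_ids=[l.name for l in spec.lesions]))
    return cases
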