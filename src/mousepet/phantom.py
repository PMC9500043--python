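"""Seeded synthetic mouse-head phantom.

Generates CT/MR/PET triplets of a simplified mouse head — an ellipsoidal
brain partitioned into mirror-symmetric internal regions (Voronoi cells of
named seed points), wrapped in a bright skull shell and extra-cerebral soft
tissue — together with exact ground-truth rigid poses and low-frequency
elastic deformations, and paired baseline/follow-up cohorts with injected
regional uptake effects.  Everything is deterministic under a fixed seed
(numpy Generator, fixed draw order).

Geometry emulates the acquisition setting the toolbox targets: CT at
0.2 mm isotropic with the skull as the brightest class, MR at 0.15 mm with
soft-tissue contrast and dark skull, PET at 0.4 mm blurred by a < 1 mm
FWHM point-spread function with intensity-proportional Gaussian noise
(a post-reconstruction surrogate for count statistics).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import LabelAtlas, VOISpec, build_label_atlas
from .errors import ValidationError
from .grids import (AnnotatedVolume, BoundingBox, EXTENDED_EXTENT, Grid,
                    resample, write_volume)
from .registration import (BasisDomain, DeformationField, RigidTransform,
                           invert_mapping, synthesize_displacement)

# class-map codes (annotation ids for internal regions start at 1001)
BG, SOFT, SKULL, BRAIN = 0, 1, 2, 3
FIRST_REGION_ID = 1001


@dataclass(frozen=True)
class PhantomRegion:
    """One internal brain region: a Voronoi seed in normalized brain coords.

    ``seed_frac`` is (AP, DV, ML) as fractions of the brain semi-axes;
    bilateral regions mirror the ML component.  Intensities are MR signal
    and relative PET uptake.
    """

    name: str
    laterality: str           # bilateral | central
    seed_frac: tuple[float, float, float]
    mr_intensity: float
    uptake: float


DEFAULT_REGIONS = (
    PhantomRegion("CTX", "bilateral", (-0.10, -0.55, 0.45), 85.0, 1.00),
    PhantomRegion("STRd", "bilateral", (-0.45, 0.05, 0.35), 95.0, 1.10),
    PhantomRegion("TH", "bilateral", (0.05, 0.15, 0.25), 90.0, 1.05),
    PhantomRegion("HY", "bilateral", (0.10, 0.60, 0.20), 80.0, 0.95),
    PhantomRegion("MB", "central", (0.45, 0.00, 0.0), 88.0, 1.00),
    PhantomRegion("HB", "central", (0.80, 0.20, 0.0), 70.0, 0.90),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for the synthetic cohort."""

    spacing: float = 0.2                                  # anatomy/CT grid, mm
    box_extent: tuple[float, float, float] = EXTENDED_EXTENT
    brain_semiaxes: tuple[float, float, float] = (4.8, 2.6, 4.2)  # mm, AP/DV/ML
    skull_scale: tuple[float, float] = (1.06, 1.18)       # shell radii, brain units
    # head sized so extra-cerebral tissue stays inside the extended box
    # even at the pose bounds (the box's design intent)
    soft_scale: float = 1.25
    # bony landmarks (center mm, semi-axes mm) that break the shell's
    # tangential symmetry, as real skull anatomy does: snout ridge,
    # occipital ridge, and a mirrored pair of tympanic bullae
    skull_features: tuple = (
        ((-5.3, 0.5, 0.0), (1.8, 0.6, 0.8)),
        ((4.5, -1.5, 0.0), (1.0, 0.8, 1.5)),
        ((2.5, 1.5, -4.4), (0.9, 0.9, 0.7)),
        ((2.5, 1.5, 4.4), (0.9, 0.9, 0.7)),
    )
    regions: tuple[PhantomRegion, ...] = DEFAULT_REGIONS
    seed_jitter_frac: float = 0.03
    ct_intensities: tuple[float, float, float, float] = (0.0, 60.0, 800.0, 40.0)
    ct_noise_sigma: float = 3.0
    mr_grid_spacing: float = 0.15
    mr_soft: float = 40.0
    mr_skull: float = 8.0
    mr_noise_sigma: float = 2.0
    pet_grid_spacing: float = 0.4
    pet_psf_fwhm: float = 0.8                             # mm
    pet_noise_scale: float = 0.05                         # sigma = scale*sqrt(v)
    pet_soft_uptake: float = 0.30
    seed: int = 0

    @property
    def n_internal_regions(self) -> int:
        return len(self.regions)


@dataclass
class PhantomAnatomy:
    """Reference anatomy: continuous head model plus its voxelized maps.

    The model is analytic — concentric ellipsoid shells for brain, skull
    and soft tissue, and Voronoi seeds in normalized brain coordinates for
    the internal regions — so deformed subjects can be classified exactly
    at arbitrary points, without accumulating resampling error.
    """

    spec: PhantomSpec
    grid: Grid
    class_map: AnnotatedVolume       # 0 bg, 1 soft, 2 skull, 3 brain
    annotation: AnnotatedVolume      # internal region ids inside the brain, else 0
    region_ids: dict[str, int]       # region name -> annotation id
    seeds: np.ndarray = None         # (S, 3) Voronoi seeds, normalized coords
    seed_ids: np.ndarray = None      # (S,) annotation id per seed
    #: dense inverse displacement u on ``grid`` (src = y + u(y)) for warped
    #: subjects; None for the reference anatomy
    inverse_disp: np.ndarray = None

    def classify_points(self, points: np.ndarray):
        """Analytic (class, region id) at world points (N, 3)."""
        spec = self.spec
        u = np.asarray(points, dtype=float) / np.asarray(spec.brain_semiaxes)
        r2 = (u ** 2).sum(axis=1)
        cls = np.zeros(len(u), dtype=np.int32)
        cls[(r2 > spec.skull_scale[1] ** 2) & (r2 <= spec.soft_scale ** 2)] = SOFT
        cls[(r2 > spec.skull_scale[0] ** 2) & (r2 <= spec.skull_scale[1] ** 2)] = SKULL
        brain = r2 <= 1.0
        pts = np.asarray(points, dtype=float)
        for center, semi in spec.skull_features:
            f2 = (((pts - np.asarray(center)) / np.asarray(semi)) ** 2).sum(axis=1)
            cls[(f2 <= 1.0) & ~brain] = SKULL
        cls[brain] = BRAIN
        ann = np.zeros(len(u), dtype=np.int32)
        if brain.any():
            d2 = ((u[brain, None, :] - self.seeds[None, :, :]) ** 2).sum(axis=2)
            ann[brain] = self.seed_ids[np.argmin(d2, axis=1)]
        return cls, ann

    def fraction_maps(self) -> dict:
        """Partial-volume fraction of each tissue class / internal region
        per voxel, from one pass of supersampled analytic classification.

        Cached: repeated renders of the same anatomy (e.g. both conditions
        of a paired study) reuse it.
        """
        if getattr(self, "_fractions", None) is None:
            pts = self.source_points(_fine_points(self.grid))
            cls, ann = self.classify_points(pts)
            fine_shape = tuple(s * _SUPERSAMPLE for s in self.grid.shape)
            fractions = {}
            for key, sel in (("soft", cls == SOFT), ("skull", cls == SKULL),
                             ("brain", cls == BRAIN)):
                fractions[key] = _block_mean(sel.astype(float).reshape(fine_shape))
            for name, rid in self.region_ids.items():
                fractions[name] = _block_mean(
                    (ann == rid).astype(float).reshape(fine_shape))
            self._fractions = fractions
        return self._fractions

    def source_points(self, points: np.ndarray) -> np.ndarray:
        """Reference-space source of world points (interpolating the stored
        inverse mapping for warped subjects)."""
        if self.inverse_disp is None:
            return np.asarray(points, dtype=float)
        pts = np.asarray(points, dtype=float)
        idx = self.grid.world_to_index(pts).T
        u = np.stack([ndimage.map_coordinates(self.inverse_disp[c], idx, order=1,
                                              mode="nearest") for c in range(3)],
                     axis=1)
        return pts + u

    def brain_mask(self) -> np.ndarray:
        return self.annotation.values > 0

    def voi_specs(self) -> list[VOISpec]:
        return [VOISpec(name=r.name, abbreviation=r.name, laterality=r.laterality,
                        root_ids=(self.region_ids[r.name],))
                for r in self.spec.regions]

    def atlas(self, erosion_iters: int = 1, min_volume_mm3: float = 1.5) -> LabelAtlas:
        return build_label_atlas(self.annotation, self.voi_specs(),
                                 erosion_iters=erosion_iters,
                                 min_volume_mm3=min_volume_mm3)


@dataclass
class PhantomSubject:
    """One synthetic animal with its exact generative ground truth."""

    subject_id: str
    true_rigid: RigidTransform
    true_field: DeformationField          # template-space pull-back field
    ct: AnnotatedVolume
    mr: AnnotatedVolume
    pet: AnnotatedVolume
    annotation: AnnotatedVolume           # subject-space region ids

    def true_total_displacement(self, grid: Grid) -> DeformationField:
        """Dense template->subject field R(x' + d(x')) - x' on ``grid``."""
        pts = grid.world_points()
        mapped = self.true_rigid.apply(self.true_field.map_points(pts))
        disp = (mapped - pts).T.reshape((3,) + grid.shape)
        return DeformationField(grid=grid, displacement=disp)


# ---------------------------------------------------------------------------
# Reference anatomy

def make_reference_anatomy(spec: PhantomSpec | None = None) -> PhantomAnatomy:
    """Build the deterministic, mirror-symmetric reference head.

    The brain ellipsoid is partitioned by nearest-seed (Voronoi) assignment
    in normalized coordinates; bilateral seeds are mirrored exactly across
    the ML midplane, central seeds sit on it, so left/right region volumes
    are equal by construction.
    """
    spec = spec or PhantomSpec()
    for s, e in zip(spec.brain_semiaxes, spec.box_extent):
        if 2 * s * spec.soft_scale > e:
            raise ValidationError("head does not fit inside the bounding box")
    rng = np.random.default_rng(spec.seed)
    grid = Grid.centered(spec.box_extent, spec.spacing)

    # seeds: jitter shared within a bilateral pair, ML component mirrored
    seeds, ids = [], []
    region_ids: dict[str, int] = {}
    next_id = FIRST_REGION_ID
    for reg in spec.regions:
        jitter = rng.normal(0.0, spec.seed_jitter_frac, size=3)
        f = np.asarray(reg.seed_frac) + jitter
        region_ids[reg.name] = next_id
        if reg.laterality == "bilateral":
            ml = max(abs(f[2]), 0.05)  # keep off the midline
            seeds += [[f[0], f[1], -ml], [f[0], f[1], ml]]
            ids += [next_id, next_id]
        else:
            seeds.append([f[0], f[1], 0.0])
            ids.append(next_id)
        next_id += 1
    anatomy = PhantomAnatomy(
        spec=spec, grid=grid, class_map=None, annotation=None,
        region_ids=region_ids, seeds=np.asarray(seeds),
        seed_ids=np.asarray(ids, dtype=np.int32))
    cls, ann = anatomy.classify_points(grid.world_points())
    anatomy.class_map = AnnotatedVolume(grid=grid, values=cls.reshape(grid.shape),
                                        modality="annotation")
    anatomy.annotation = AnnotatedVolume(grid=grid, values=ann.reshape(grid.shape),
                                         modality="annotation")
    return anatomy


# ---------------------------------------------------------------------------
# Modality rendering

def _fwhm_sigma_vox(fwhm_mm: float, spacing) -> list[float]:
    return [fwhm_mm / 2.3548 / s for s in spacing]


_SUPERSAMPLE = 2  # subvoxels per axis for partial-volume rendering


def _fine_points(grid: Grid, f: int = _SUPERSAMPLE) -> np.ndarray:
    """Centers of the f^3 subdivision of every voxel, C order, (N*f^3, 3)."""
    axes = []
    for i in range(3):
        s = grid.spacing[i]
        axes.append(grid.origin[i] - s / 2 + (np.arange(grid.shape[i] * f) + 0.5) * s / f)
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


def _block_mean(arr: np.ndarray, f: int = _SUPERSAMPLE) -> np.ndarray:
    n1, n2, n3 = (s // f for s in arr.shape)
    return arr.reshape(n1, f, n2, f, n3, f).mean(axis=(1, 3, 5))


def render_modalities(anatomy: PhantomAnatomy, spec: PhantomSpec | None = None,
                      rng: np.random.Generator | None = None,
                      uptake_overrides: dict | None = None,
                      suv_scale: float = 185.0,
                      modalities: tuple = ("ct", "mr", "pet")):
    """Render (ct, mr, pet) volumes; noiseless and seed-independent if ``rng`` is None.

    Intensities are partial-volume mixtures: each voxel combines the
    analytically classified sub-voxel fractions of its tissues, emulating
    the scanner's integration over the voxel.  ``suv_scale`` sets the PET
    concentration (kBq/mL) of a region with unit relative uptake —
    numerically equal to injected activity (kBq) per body weight (g), so
    that SUV conversion recovers the relative uptake.  Omitted
    ``modalities`` are returned as None.
    """
    spec = spec or anatomy.spec
    frac = anatomy.fraction_maps()
    _, soft_i, skull_i, brain_i = spec.ct_intensities
    ct = mr = pet = None

    if "ct" in modalities:
        ct_img = frac["soft"] * soft_i + frac["skull"] * skull_i + frac["brain"] * brain_i
        ct_img = ndimage.gaussian_filter(ct_img, _fwhm_sigma_vox(0.3, anatomy.grid.spacing))
        if rng is not None:
            ct_img = ct_img + rng.normal(0.0, spec.ct_noise_sigma, ct_img.shape)
        ct = AnnotatedVolume(grid=anatomy.grid, values=ct_img, modality="CT",
                             units="HU-like")

    if "mr" in modalities:
        mr_img = frac["soft"] * spec.mr_soft + frac["skull"] * spec.mr_skull
        for reg in spec.regions:
            mr_img = mr_img + frac[reg.name] * reg.mr_intensity
        mr_hi = AnnotatedVolume(grid=anatomy.grid, values=mr_img, modality="MR")
        mr_grid = Grid.centered(spec.box_extent, spec.mr_grid_spacing)
        mr = resample(mr_hi, mr_grid, interpolation="trilinear")
        mr_v = ndimage.gaussian_filter(mr.values, _fwhm_sigma_vox(0.2, mr_grid.spacing))
        if rng is not None:
            mr_v = mr_v + rng.normal(0.0, spec.mr_noise_sigma, mr_v.shape)
        mr = AnnotatedVolume(grid=mr_grid, values=mr_v, modality="MR", units="a.u.")

    if "pet" in modalities:
        overrides = uptake_overrides or {}
        up = frac["soft"] * spec.pet_soft_uptake
        for reg in spec.regions:
            u = reg.uptake * (1.0 + overrides.get(reg.name, 0.0))
            up = up + frac[reg.name] * u
        up = up * suv_scale
        up = ndimage.gaussian_filter(up, _fwhm_sigma_vox(spec.pet_psf_fwhm,
                                                         anatomy.grid.spacing))
        pet_grid = Grid.centered(spec.box_extent, spec.pet_grid_spacing)
        pet = resample(AnnotatedVolume(grid=anatomy.grid, values=up, modality="PET"),
                       pet_grid, interpolation="trilinear")
        pet_v = pet.values
        if rng is not None:
            pet_v = pet_v + rng.normal(0.0, 1.0, pet_v.shape) * \
                spec.pet_noise_scale * np.sqrt(np.clip(pet_v, 0, None))
        pet = AnnotatedVolume(grid=pet_grid, values=pet_v, modality="PET",
                              units="kBq/mL")
    return ct, mr, pet


# ---------------------------------------------------------------------------
# Deformed subjects

def draw_random_field(grid: Grid, amplitude_mm: float,
                      rng: np.random.Generator,
                      orders: tuple[int, int, int] = (3, 3, 3)) -> DeformationField:
    """Random smooth field with max |d| equal to ``amplitude_mm``.

    Coefficients are i.i.d. normal, tapered with total frequency so low
    orders dominate, then rescaled to hit the requested peak exactly.
    """
    domain = BasisDomain.from_grid(grid)
    coef = rng.standard_normal((3, *orders))
    k1, k2, k3 = np.meshgrid(*(np.arange(o) for o in orders), indexing="ij")
    coef = coef / (1.0 + k1 + k2 + k3)
    if amplitude_mm == 0:
        coef[:] = 0.0
        return DeformationField.from_coefficients(coef, grid, domain)
    disp = synthesize_displacement(coef, grid, domain)
    peak = np.sqrt((disp ** 2).sum(axis=0)).max()
    coef *= amplitude_mm / peak
    return DeformationField.from_coefficients(coef, grid, domain)


def _warp_anatomy(anatomy: PhantomAnatomy, rigid: RigidTransform,
                  field: DeformationField) -> PhantomAnatomy:
    """Subject-space anatomy A_s(y) = A_ref(T^{-1}(y)) for T = rigid o (id + d).

    Each voxel center is pulled back through the exact inverse mapping and
    classified analytically, so the subject is the continuous reference
    model seen through the recorded ground-truth deformation.  An identity
    mapping returns the reference anatomy itself (sharing its caches).
    """
    if rigid.is_identity() and (field.coefficients is None
                                or not np.any(field.coefficients)):
        return anatomy
    pts = anatomy.grid.world_points()
    src = invert_mapping(pts, rigid if not rigid.is_identity() else None,
                         field if field.coefficients is not None
                         and np.any(field.coefficients) else None)
    cls, ann = anatomy.classify_points(src)
    grid = anatomy.grid
    return PhantomAnatomy(
        spec=anatomy.spec, grid=grid,
        class_map=AnnotatedVolume(grid=grid, values=cls.reshape(grid.shape),
                                  modality="annotation"),
        annotation=AnnotatedVolume(grid=grid, values=ann.reshape(grid.shape),
                                   modality="annotation"),
        region_ids=dict(anatomy.region_ids),
        seeds=anatomy.seeds, seed_ids=anatomy.seed_ids,
        inverse_disp=(src - pts).T.reshape((3,) + grid.shape))


def make_subject(anatomy: PhantomAnatomy, spec: PhantomSpec | None = None,
                 deformation_amplitude: float = 0.5, seed: int = 0,
                 pose_amplitude_mm: float = 0.8, pose_amplitude_deg: float = 4.0,
                 subject_id: str | None = None,
                 uptake_overrides: dict | None = None,
                 noise: bool = True, suv_scale: float = 185.0) -> PhantomSubject:
    """Draw a posed, elastically deformed subject with recorded ground truth.

    The recorded (rigid, field) pair is exactly the template->subject
    pull-back mapping that a perfect registration of this subject to the
    reference would return.
    """
    spec = spec or anatomy.spec
    if deformation_amplitude < 0:
        raise ValidationError("deformation amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    t = rng.uniform(-pose_amplitude_mm, pose_amplitude_mm, 3)
    r = np.deg2rad(rng.uniform(-pose_amplitude_deg, pose_amplitude_deg, 3))
    rigid = RigidTransform(translation=tuple(t), rotation=tuple(r),
                           center=(0.0, 0.0, 0.0))
    field = draw_random_field(anatomy.grid, deformation_amplitude, rng)
    warped = _warp_anatomy(anatomy, rigid, field)
    ct, mr, pet = render_modalities(warped, spec, rng=rng if noise else None,
                                    uptake_overrides=uptake_overrides,
                                    suv_scale=suv_scale)
    return PhantomSubject(subject_id=subject_id or f"sub{seed:03d}",
                          true_rigid=rigid, true_field=field,
                          ct=ct, mr=mr, pet=pet, annotation=warped.annotation)


# ---------------------------------------------------------------------------
# Paired cohorts

@dataclass
class PairedCohort:
    """In-memory paired cohort plus its study manifest."""

    manifest: pd.DataFrame
    pets: dict
    cts: dict
    doses: dict
    conditions: tuple[str, str] = ("d0", "d7")


def make_paired_cohort(anatomy: PhantomAnatomy, spec: PhantomSpec | None = None,
                       n_subjects: int = 6, effect: dict | None = None,
                       seed: int = 0, deformation_amplitude: float = 0.0,
                       pose_amplitude_mm: float = 0.0,
                       biological_cv: float = 0.05,
                       include_ct: bool = True,
                       out_dir=None) -> PairedCohort:
    """Paired d0/d7 cohort with optional fractional uptake effects at d7.

    Each subject's anatomical deformation is drawn once and shared by both
    conditions; imaging noise and per-region biological variability are
    independent per condition.  ``effect`` maps region names to fractional
    d7 uptake changes (e.g. ``{"STRd": 0.2}``).  With ``out_dir`` set, the
    images are written as NIfTI and the manifest carries their paths.
    """
    spec = spec or anatomy.spec
    if n_subjects < 2:
        raise ValidationError("need at least 2 subjects")
    effect = effect or {}
    known = {r.name for r in spec.regions}
    unknown = set(effect) - known
    if unknown:
        raise ValidationError(f"effect regions not in the phantom atlas: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows, pets, cts, doses = [], {}, {}, {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(n_subjects):
        sid = f"m{i + 1:02d}"
        sub_seed = int(rng.integers(2 ** 31))
        sub_rng = np.random.default_rng(sub_seed)
        t = sub_rng.uniform(-pose_amplitude_mm, pose_amplitude_mm, 3)
        rot = (np.deg2rad(sub_rng.uniform(-2.0, 2.0, 3))
               if pose_amplitude_mm > 0 else np.zeros(3))
        rigid = RigidTransform(translation=tuple(t), rotation=tuple(rot))
        fld = draw_random_field(anatomy.grid, deformation_amplitude, sub_rng)
        warped = _warp_anatomy(anatomy, rigid, fld)
        for cond in ("d0", "d7"):
            activity = float(np.clip(sub_rng.normal(4.7, 0.3), 3.5, 6.0))   # MBq
            weight = float(np.clip(sub_rng.normal(27.0, 2.0), 20.0, 35.0))  # g
            overrides = {r.name: float(sub_rng.normal(0.0, biological_cv))
                         for r in spec.regions}
            if cond == "d7":
                for name, frac in effect.items():
                    overrides[name] = (1 + overrides[name]) * (1 + frac) - 1
            suv_scale = activity * 1000.0 / weight
            mods = ("ct", "pet") if include_ct else ("pet",)
            ct, _, pet = render_modalities(warped, spec, rng=sub_rng,
                                           uptake_overrides=overrides,
                                           suv_scale=suv_scale, modalities=mods)
            key = (sid, cond)
            pets[key], cts[key] = pet, ct
            doses[key] = (activity, weight)
            row = {"subject": sid, "condition": cond, "pet": "", "ct": "",
                   "injected_activity_mbq": activity, "body_weight_g": weight}
            if out_dir is not None:
                pet_path = out_dir / f"{sid}_{cond}_pet.nii.gz"
                ct_path = out_dir / f"{sid}_{cond}_ct.nii.gz"
                write_volume(pet, pet_path)
                write_volume(ct, ct_path)
                row["pet"], row["ct"] = str(pet_path), str(ct_path)
            rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return PairedCohort(manifest=manifest, pets=pets, cts=cts, doses=doses)
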