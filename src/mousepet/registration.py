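"""Rigid and low-frequency elastic registration engines.

The elastic model parameterizes each displacement component by a separable
3-D cosine (DCT-II) basis over the fixed volume's physical box — the classic
low-frequency spatial-normalization family.  Fitting minimizes

    E(c) = mean_v [ s * M(x_v + d_c(x_v)) - F(x_v) ]^2  +  lambda * c' L c

by Gauss–Newton with Levenberg damping and backtracking, coarse to fine over
a smoothing/resolution pyramid.  ``L`` is a diagonal membrane-energy
penalty in coefficient space; ``s`` an optional global intensity scale.

Fields store *pull-back* displacements on the template (fixed) grid: a
template-space point ``x'`` corresponds to the subject-space point
``x = x' + d(x')`` (optionally followed by a rigid map).  All optimizers are
deterministic: identical inputs and settings give bit-identical transforms.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.transform import Rotation

from .errors import RegistrationFailure, ValidationError
from .grids import AnnotatedVolume, Grid, resample, sample_at_points

__all__ = [
    "RigidTransform", "BasisDomain", "DeformationField", "RegistrationSettings",
    "register_rigid", "register_elastic", "apply_transform", "compose_fields",
    "invert_mapping", "invert_field", "synthesize_displacement",
]


# ---------------------------------------------------------------------------
# Rigid transforms

@dataclass(frozen=True)
class RigidTransform:
    """Rigid map y = R (x - c) + c + t with fixed intrinsic-XYZ Euler angles."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # radians
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("XYZ", self.rotation).as_matrix()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        c = np.asarray(self.center)
        return (pts - c) @ self.matrix.T + c + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        r_inv = self.matrix.T
        t_inv = -r_inv @ np.asarray(self.translation)
        angles = Rotation.from_matrix(r_inv).as_euler("XYZ")
        return RigidTransform(translation=tuple(t_inv), rotation=tuple(angles),
                              center=self.center)

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return the map x -> self(inner(x))."""
        r = self.matrix @ inner.matrix
        c = np.asarray(self.center)
        # self(inner(x)) = R_s (R_i (x - c_i) + c_i + t_i - c_s) + c_s + t_s
        ci, ti = np.asarray(inner.center), np.asarray(inner.translation)
        offset = self.matrix @ (inner.matrix @ (-ci) + ci + ti - c) + c + np.asarray(self.translation)
        # express as rotation about origin-centered form with center 0
        angles = Rotation.from_matrix(r).as_euler("XYZ")
        return RigidTransform(translation=tuple(offset), rotation=tuple(angles),
                              center=(0.0, 0.0, 0.0))

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center=tuple(center))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (max(abs(v) for v in self.translation) < tol
                and max(abs(v) for v in self.rotation) < tol)

    def to_dict(self) -> dict:
        return {"translation": list(self.translation), "rotation": list(self.rotation),
                "center": list(self.center)}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(translation=tuple(d["translation"]), rotation=tuple(d["rotation"]),
                   center=tuple(d.get("center", (0, 0, 0))))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Cosine basis machinery

@dataclass(frozen=True)
class BasisDomain:
    """Physical box over which the cosine basis is defined."""

    origin: tuple[float, float, float]
    extent: tuple[float, float, float]

    @classmethod
    def from_grid(cls, grid: Grid) -> "BasisDomain":
        origin = tuple(o - s / 2.0 for o, s in zip(grid.origin, grid.spacing))
        return cls(origin=origin, extent=grid.extent)


def _basis_1d(coords_mm: np.ndarray, order: int, origin: float, length: float) -> np.ndarray:
    """DCT-II style basis functions cos(pi k u), u in [0, 1]; shape (n, order)."""
    u = (np.asarray(coords_mm, dtype=float) - origin) / length
    k = np.arange(order)
    return np.cos(np.pi * np.outer(u, k))


def synthesize_displacement(coefficients: np.ndarray, grid: Grid,
                            domain: BasisDomain) -> np.ndarray:
    """Dense (3, n1, n2, n3) displacement in mm from coefficient blocks (3,K1,K2,K3)."""
    coefficients = np.asarray(coefficients, dtype=float)
    _, k1, k2, k3 = coefficients.shape
    mats = [_basis_1d(grid.axis_coords(i), k, domain.origin[i], domain.extent[i])
            for i, k in enumerate((k1, k2, k3))]
    out = np.empty((3,) + grid.shape)
    for c in range(3):
        t = np.tensordot(mats[0], coefficients[c], axes=(1, 0))   # (n1, K2, K3)
        t = np.tensordot(t, mats[1], axes=(1, 1))                 # (n1, K3, n2)
        t = np.tensordot(t, mats[2], axes=(1, 1))                 # (n1, n2, n3)
        out[c] = t
    return out


def evaluate_displacement_at(coefficients: np.ndarray, points: np.ndarray,
                             domain: BasisDomain) -> np.ndarray:
    """Displacement (N, 3) at arbitrary world points, evaluated analytically."""
    coefficients = np.asarray(coefficients, dtype=float)
    pts = np.asarray(points, dtype=float)
    _, k1, k2, k3 = coefficients.shape
    b1 = _basis_1d(pts[:, 0], k1, domain.origin[0], domain.extent[0])
    b2 = _basis_1d(pts[:, 1], k2, domain.origin[1], domain.extent[1])
    b3 = _basis_1d(pts[:, 2], k3, domain.origin[2], domain.extent[2])
    out = np.empty((pts.shape[0], 3))
    for c in range(3):
        t = np.einsum("nk,klm->nlm", b1, coefficients[c], optimize=True)
        t = np.einsum("nlm,nl->nm", t, b2, optimize=True)
        out[:, c] = np.einsum("nm,nm->n", t, b3)
    return out


def _membrane_weights(orders, extent) -> np.ndarray:
    """Diagonal membrane-energy weights per coefficient, shape (K1,K2,K3)."""
    k1, k2, k3 = (np.arange(o) for o in orders)
    w = ((np.pi * k1[:, None, None] / extent[0]) ** 2
         + (np.pi * k2[None, :, None] / extent[1]) ** 2
         + (np.pi * k3[None, None, :] / extent[2]) ** 2)
    return w


@dataclass
class DeformationField:
    """Dense per-voxel pull-back displacement in mm on a template grid.

    When ``coefficients`` (3, K1, K2, K3) and ``domain`` are present the
    dense field is their cosine synthesis; the field then extends smoothly
    to arbitrary points.
    """

    grid: Grid
    displacement: np.ndarray  # (3, n1, n2, n3) mm
    coefficients: np.ndarray | None = None
    domain: BasisDomain | None = None
    converged: bool = True
    final_ssd: float | None = None

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.shape != (3,) + self.grid.shape:
            raise ValidationError("displacement shape must be (3,) + grid shape")
        if not np.all(np.isfinite(self.displacement)):
            raise ValidationError("displacement field contains non-finite values")

    @classmethod
    def from_coefficients(cls, coefficients, grid: Grid, domain: BasisDomain,
                          **kw) -> "DeformationField":
        disp = synthesize_displacement(coefficients, grid, domain)
        return cls(grid=grid, displacement=disp, coefficients=np.asarray(coefficients),
                   domain=domain, **kw)

    @classmethod
    def identity(cls, grid: Grid) -> "DeformationField":
        return cls(grid=grid, displacement=np.zeros((3,) + grid.shape))

    def map_points(self, points: np.ndarray) -> np.ndarray:
        """x' -> x' + d(x'), interpolating the dense field (analytic if coefficients)."""
        pts = np.asarray(points, dtype=float)
        if self.coefficients is not None and self.domain is not None:
            return pts + evaluate_displacement_at(self.coefficients, pts, self.domain)
        idx = self.grid.world_to_index(pts).T
        d = np.stack([ndimage.map_coordinates(self.displacement[c], idx, order=1,
                                              mode="nearest") for c in range(3)], axis=1)
        return pts + d

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.displacement ** 2).sum(axis=0))


# ---------------------------------------------------------------------------
# Settings

@dataclass
class RegistrationSettings:
    """Shared knobs for the rigid and elastic stages.

    ``pyramid`` lists (grid spacing mm, smoothing FWHM mm) pairs, coarse to
    fine.  ``basis_orders`` are cosine frequencies per axis; with the default
    working box they give basis wavelengths of roughly 2-4 mm.  ``metric`` is
    used by the rigid stage only; the elastic stage is always SSD (with
    optional global intensity scaling), which is why inter-modality elastic
    registration requires comparable contrast.
    """

    metric: str = "SSD"                      # SSD or MI (rigid stage)
    basis_orders: tuple[int, int, int] = (5, 4, 4)
    regularization_weight: float = 0.05      # lambda, membrane penalty
    pyramid: tuple = ((0.8, 1.2), (0.4, 0.6))
    rigid_pyramid: tuple = ((0.8, 1.2), (0.4, 0.6), (0.2, 0.3))
    max_iterations: int = 30
    convergence_tol: float = 1e-6
    intensity_scaling: bool = True
    com_init: bool = True                    # centre-of-mass rigid initialization
    mi_bins: int = 32

    def __post_init__(self):
        if self.metric not in ("SSD", "MI"):
            raise ValidationError("metric must be SSD or MI")
        if self.regularization_weight < 0:
            raise ValidationError("regularization_weight must be >= 0")


def _smooth(vol: AnnotatedVolume, fwhm_mm: float) -> AnnotatedVolume:
    if fwhm_mm <= 0:
        return vol
    sigma = [fwhm_mm / 2.3548 / s for s in vol.grid.spacing]
    return vol.copy_with(values=ndimage.gaussian_filter(vol.values.astype(float), sigma))


def _pyramid_level(vol: AnnotatedVolume, spacing: float, fwhm: float,
                   box_grid: Grid | None = None) -> AnnotatedVolume:
    """Smooth then resample to an isotropic level grid covering the volume."""
    sm = _smooth(vol, fwhm)
    target = box_grid
    if target is None:
        shape = tuple(max(2, int(np.ceil(e / spacing))) for e in vol.grid.extent)
        origin = tuple(o - s / 2.0 + spacing / 2.0
                       for o, s in zip(vol.grid.origin, vol.grid.spacing))
        target = Grid(shape=shape, spacing=(spacing,) * 3, origin=origin)
    if target.same_geometry(sm.grid):
        return sm
    return resample(sm, target, interpolation="trilinear")


def _intensity_com(vol: AnnotatedVolume) -> np.ndarray:
    """Intensity-weighted centre of mass (world mm) of the above-background signal."""
    v = vol.values.astype(float)
    thr = v.min() + 0.1 * (v.max() - v.min())
    w = np.clip(v - thr, 0, None)
    total = w.sum()
    if total <= 0:
        raise RegistrationFailure("volume has no signal above background")
    idx = np.array(ndimage.center_of_mass(w))
    return vol.grid.index_to_world(idx)


# ---------------------------------------------------------------------------
# Rigid registration

def _mi_metric(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    """Negative mutual information of two equal-length samples (Parzen-smoothed)."""
    h, _, _ = np.histogram2d(a, b, bins=bins)
    h = ndimage.gaussian_filter(h, 1.0)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())
    return -mi


_ROT_SCALE = 0.05  # rad per parameter unit, so 1 unit ~ effect of 1 mm at r ~ 20 mm


def register_rigid(moving: AnnotatedVolume, fixed: AnnotatedVolume,
                   settings: RegistrationSettings | None = None) -> RigidTransform:
    """Estimate the rigid map from fixed-space points to moving-space points.

    Deterministic Powell descent over a smoothing pyramid, SSD or mutual
    information.  The returned transform is the pull-back map: sampling
    ``moving`` at ``T(x')`` aligns it with ``fixed``.
    """
    settings = settings or RegistrationSettings()
    if moving.values.max() == moving.values.min():
        raise RegistrationFailure("moving volume is constant (no signal)")
    if fixed.values.max() == fixed.values.min():
        raise RegistrationFailure("fixed volume is constant (no signal)")
    center = tuple(fixed.grid.center())
    t0 = np.zeros(3)
    if settings.com_init:
        t0 = _intensity_com(moving) - _intensity_com(fixed)
    params = np.concatenate([t0, np.zeros(3)])
    for spacing, fwhm in settings.rigid_pyramid:
        fx = _pyramid_level(fixed, spacing, fwhm)
        mv = _smooth(moving, fwhm)
        pts = fx.grid.world_points()
        fvals = fx.values.ravel().astype(float)
        if pts.shape[0] > 60000:  # deterministic subsampling at fine levels
            stride = int(np.ceil(pts.shape[0] / 60000))
            pts, fvals = pts[::stride], fvals[::stride]
        inside_f = fvals != 0

        def objective(p):
            t = RigidTransform(translation=tuple(p[:3]),
                               rotation=tuple(p[3:] * _ROT_SCALE), center=center)
            mvals = sample_at_points(mv, t.apply(pts))
            if settings.metric == "MI":
                sel = inside_f | (mvals != 0)
                if sel.sum() < 100:
                    return 0.0
                return _mi_metric(fvals[sel], mvals[sel], settings.mi_bins)
            diff = mvals - fvals
            return float(diff @ diff) / diff.size

        res = optimize.minimize(objective, params, method="Powell",
                                options={"xtol": 1e-4, "ftol": 1e-9, "maxiter": 40})
        params = res.x
    transform = RigidTransform(translation=tuple(params[:3]),
                               rotation=tuple(params[3:] * _ROT_SCALE), center=center)
    # sanity: the optimum must keep some overlap
    mvals = sample_at_points(_smooth(moving, 0.0), transform.apply(fixed.grid.world_points()[::7]))
    if np.count_nonzero(mvals) == 0 and np.count_nonzero(moving.values) > 0:
        raise RegistrationFailure("no overlap between volumes at the rigid optimum")
    return transform


# ---------------------------------------------------------------------------
# Elastic registration

def register_elastic(moving: AnnotatedVolume, fixed: AnnotatedVolume,
                     settings: RegistrationSettings | None = None,
                     initial_coefficients: np.ndarray | None = None) -> DeformationField:
    """Estimate a low-frequency pull-back field warping ``moving`` onto ``fixed``.

    Volumes must be rigidly pre-aligned.  Gauss–Newton with Levenberg
    damping over the cosine coefficients; the objective (mean SSD plus
    membrane penalty) never increases across accepted iterations.  If no
    step can be accepted the best-so-far field is returned flagged
    ``converged=False``.
    """
    settings = settings or RegistrationSettings()
    domain = BasisDomain.from_grid(fixed.grid)
    orders = settings.basis_orders
    n_coef = int(np.prod(orders))
    coef = np.zeros((3, *orders)) if initial_coefficients is None \
        else np.asarray(initial_coefficients, dtype=float).copy()
    if coef.shape != (3, *orders):
        raise ValidationError(f"initial coefficients shape {coef.shape} != (3, {orders})")
    lam = settings.regularization_weight
    weights = _membrane_weights(orders, domain.extent).ravel()  # (K,)
    converged = True
    final_ssd = None

    for spacing, fwhm in settings.pyramid:
        fx = _pyramid_level(fixed, spacing, fwhm)
        mv = _smooth(moving, fwhm)
        grad = np.stack(np.gradient(mv.values.astype(float), *mv.grid.spacing))
        pts = fx.grid.world_points()                       # (N, 3)
        fvals = fx.values.ravel().astype(float)
        n = fvals.size
        mats = [_basis_1d(fx.grid.axis_coords(i), orders[i], domain.origin[i],
                          domain.extent[i]) for i in range(3)]
        # voxel-by-coefficient basis product matrix (N, K)
        p_mat = np.einsum("ia,jb,kc->ijkabc", *mats, optimize=True).reshape(n, n_coef)

        def sample_and_grad(c):
            warped = pts + evaluate_displacement_at(c, pts, domain)
            idx = mv.grid.world_to_index(warped).T
            m = ndimage.map_coordinates(mv.values.astype(float), idx, order=1,
                                        mode="constant", cval=0.0)
            g = [ndimage.map_coordinates(grad[a], idx, order=1, mode="constant",
                                         cval=0.0) for a in range(3)]
            return m, g

        def penalty(c):
            return float(sum(weights @ (c[a].ravel() ** 2) for a in range(3)))

        def objective(c):
            m, _ = sample_and_grad(c)
            s = 1.0
            if settings.intensity_scaling:
                denom = float(m @ m)
                s = float(m @ fvals) / denom if denom > 0 else 1.0
            r = s * m - fvals
            return float(r @ r) / n + lam * penalty(c), s

        energy, s = objective(coef)
        mu = 1e-3
        for _ in range(settings.max_iterations):
            m, g = sample_and_grad(coef)
            if settings.intensity_scaling:
                denom = float(m @ m)
                s = float(m @ fvals) / denom if denom > 0 else 1.0
            r = s * m - fvals
            # Gauss-Newton normal equations in (3K) blocks
            jtj = np.empty((3 * n_coef, 3 * n_coef))
            jtr = np.empty(3 * n_coef)
            for a in range(3):
                ga = s * g[a]
                jtr[a * n_coef:(a + 1) * n_coef] = (2.0 / n) * (p_mat.T @ (ga * r))
                for b in range(a, 3):
                    block = (2.0 / n) * (p_mat.T * (ga * s * g[b])) @ p_mat
                    jtj[a * n_coef:(a + 1) * n_coef, b * n_coef:(b + 1) * n_coef] = block
                    if b != a:
                        jtj[b * n_coef:(b + 1) * n_coef, a * n_coef:(a + 1) * n_coef] = block.T
            reg = 2.0 * lam * np.tile(weights, 3)
            jtj[np.diag_indices_from(jtj)] += reg
            jtr += reg * coef.reshape(3, -1).ravel()
            accepted = False
            step = None
            for _try in range(8):
                damped = jtj.copy()
                damped[np.diag_indices_from(damped)] += mu * np.abs(np.diag(jtj)) + 1e-12
                try:
                    step = cho_solve(cho_factor(damped), -jtr)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                trial = coef + step.reshape(3, *orders)
                e_trial, _ = objective(trial)
                if e_trial <= energy:
                    rel = (energy - e_trial) / max(energy, 1e-30)
                    coef, energy = trial, e_trial
                    mu = max(mu * 0.3, 1e-8)
                    accepted = True
                    break
                mu *= 10.0
            if not accepted:
                # a vanishing proposed step means we are at the optimum,
                # not diverging
                if step is not None and np.abs(step).max() < 1e-3:
                    break
                converged = False
                break
            if rel < settings.convergence_tol:
                break
        final_ssd = energy - lam * penalty(coef)
    return DeformationField.from_coefficients(coef, fixed.grid, domain,
                                              converged=converged, final_ssd=final_ssd)


# ---------------------------------------------------------------------------
# Applying, composing, inverting

def apply_transform(vol: AnnotatedVolume, rigid: RigidTransform | None = None,
                    field: DeformationField | None = None,
                    interpolation: str = "trilinear",
                    out_grid: Grid | None = None) -> AnnotatedVolume:
    """Pull a volume back through ``rigid`` and/or ``field``.

    The output lives on ``field.grid`` (or ``out_grid``); its value at x' is
    ``vol(rigid(x' + d(x')))``.
    """
    if rigid is None and field is None:
        raise ValidationError("apply_transform needs a rigid transform and/or a field")
    if vol.is_label and interpolation != "nearest":
        raise ValidationError(f"{vol.modality} volumes require nearest interpolation")
    grid = out_grid or (field.grid if field is not None else vol.grid)
    pts = grid.world_points()
    if field is not None:
        pts = field.map_points(pts)
    if rigid is not None:
        pts = rigid.apply(pts)
    vals = sample_at_points(vol, pts, interpolation=interpolation)
    return AnnotatedVolume(grid=grid, values=vals.reshape(grid.shape),
                           modality=vol.modality, units=vol.units)


def compose_fields(outer: DeformationField,
                   inner: "RigidTransform | DeformationField") -> DeformationField:
    """Total field for the map x' -> inner(outer(x')) on the outer grid."""
    pts = outer.grid.world_points()
    mid = pts + outer.displacement.reshape(3, -1).T
    if isinstance(inner, RigidTransform):
        final = inner.apply(mid)
    else:
        final = inner.map_points(mid)
    disp = (final - pts).T.reshape((3,) + outer.grid.shape)
    return DeformationField(grid=outer.grid, displacement=disp,
                            converged=outer.converged)


def invert_mapping(points: np.ndarray, rigid: RigidTransform | None,
                   field: DeformationField | None,
                   iterations: int = 25, tol: float = 1e-7) -> np.ndarray:
    """Solve T(x) = y for x where T(x) = rigid(x + d(x)), by fixed-point iteration.

    Converges for the smooth, small-amplitude fields this toolbox produces
    (requires the displacement gradient to be a contraction).
    """
    y = np.asarray(points, dtype=float)
    z = rigid.inverse().apply(y) if rigid is not None else y
    if field is None:
        return z
    x = z.copy()
    for _ in range(iterations):
        x_new = z - (field.map_points(x) - x)
        if np.abs(x_new - x).max() < tol:
            x = x_new
            break
        x = x_new
    return x


def invert_field(field: DeformationField, grid: Grid | None = None) -> DeformationField:
    """Numeric inverse of a deformation field on ``grid`` (default: its own)."""
    grid = grid or field.grid
    pts = grid.world_points()
    x = invert_mapping(pts, None, field)
    disp = (x - pts).T.reshape((3,) + grid.shape)
    return DeformationField(grid=grid, displacement=disp)
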