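"""Rigid/elastic registration engines: recovery of known transforms,
objective behaviour, field application, composition and inversion."""
import numpy as np
import pytest

from mousepet.errors import RegistrationFailure, ValidationError
from mousepet.grids import AnnotatedVolume, Grid, resample, sample_at_points
from mousepet.phantom import draw_random_field, make_subject
from mousepet.registration import (BasisDomain, DeformationField,
                                   RegistrationSettings, RigidTransform,
                                   apply_transform, compose_fields, invert_field,
                                   invert_mapping, register_elastic,
                                   register_rigid, synthesize_displacement)


@pytest.fixture(scope="module")
def ct_template(reference_modalities):
    return reference_modalities[0]


class TestRigidTransform:
    def test_inverse_roundtrip(self, rng):
        t = RigidTransform(translation=(0.4, -0.6, 0.2),
                           rotation=(0.05, -0.03, 0.08), center=(1.0, 2.0, 3.0))
        pts = rng.normal(size=(50, 3)) * 5
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_compose_matches_sequential(self, rng):
        a = RigidTransform(translation=(0.2, 0.1, -0.3), rotation=(0.02, 0.04, -0.01),
                           center=(0.5, -0.5, 0.0))
        b = RigidTransform(translation=(-0.1, 0.3, 0.2), rotation=(-0.03, 0.01, 0.02),
                           center=(1.0, 0.0, -1.0))
        pts = rng.normal(size=(20, 3)) * 4
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-10)

    def test_json_roundtrip(self, tmp_path):
        t = RigidTransform(translation=(0.1, 0.2, 0.3), rotation=(0.01, 0.02, 0.03))
        t.save(tmp_path / "t.json")
        assert RigidTransform.load(tmp_path / "t.json") == t


class TestBasis:
    def test_synthesis_linearity(self, rng):
        grid = Grid(shape=(10, 10, 10), spacing=(0.4,) * 3)
        dom = BasisDomain.from_grid(grid)
        c1 = rng.normal(size=(3, 3, 3, 3))
        c2 = rng.normal(size=(3, 3, 3, 3))
        d1 = synthesize_displacement(c1, grid, dom)
        d2 = synthesize_displacement(c2, grid, dom)
        d12 = synthesize_displacement(c1 + c2, grid, dom)
        assert np.allclose(d12, d1 + d2, atol=1e-12)

    def test_dense_matches_analytic_evaluation(self, rng):
        grid = Grid(shape=(8, 9, 10), spacing=(0.3,) * 3, origin=(-1, 0, 1))
        dom = BasisDomain.from_grid(grid)
        coef = rng.normal(size=(3, 4, 3, 2))
        f = DeformationField.from_coefficients(coef, grid, dom)
        pts = grid.world_points()
        mapped = f.map_points(pts)
        assert np.allclose((mapped - pts).T.reshape((3,) + grid.shape),
                           f.displacement, atol=1e-6)


class TestRigidRegistration:
    def test_self_registration_is_identity(self, ct_template):
        t = register_rigid(ct_template, ct_template)
        assert max(abs(v) for v in t.translation) < 1e-3
        assert max(abs(v) for v in t.rotation) < 1e-3

    def test_known_shift_recovered(self, ct_template):
        """Template shifted by (0.4, -0.6, 0.2) mm -> translation recovered
        within 0.1 mm."""
        shift = np.array([0.4, -0.6, 0.2])
        moved = AnnotatedVolume(
            grid=Grid(shape=ct_template.grid.shape, spacing=ct_template.grid.spacing,
                      origin=tuple(np.asarray(ct_template.grid.origin) + shift)),
            values=ct_template.values.copy(), modality="CT")
        t = register_rigid(moved, ct_template)
        assert np.allclose(t.translation, shift, atol=0.1)
        assert max(abs(v) for v in t.rotation) < 0.01

    def test_known_pose_recovery_median(self, anatomy, phantom_spec, ct_template):
        """Random rigid poses within +-0.8 mm / +-4 deg recovered with median
        point error < 0.25 voxel (0.05 mm at the 0.2 mm working grid)."""
        errs = []
        for seed in range(5):
            sub = make_subject(anatomy, phantom_spec, deformation_amplitude=0.0,
                               seed=200 + seed)
            est = register_rigid(sub.ct, ct_template)
            pts = ct_template.grid.world_points()[::17]
            d = est.apply(pts) - sub.true_rigid.apply(pts)
            errs.append(np.sqrt((d ** 2).sum(axis=1)).mean())
        assert np.median(errs) < 0.25 * 0.2

    def test_cross_modality_mi_pose(self, anatomy, phantom_spec, reference_modalities):
        """Subject MR registered to the CT template with mutual information:
        pose within 0.2 mm / 0.5 deg."""
        _, mr_template, _ = reference_modalities
        sub = make_subject(anatomy, phantom_spec, deformation_amplitude=0.0, seed=42)
        est = register_rigid(sub.mr, reference_modalities[0],
                             RegistrationSettings(metric="MI"))
        assert np.allclose(est.translation, sub.true_rigid.translation, atol=0.2)
        pts = reference_modalities[0].grid.world_points()[::29]
        d = est.apply(pts) - sub.true_rigid.apply(pts)
        assert np.sqrt((d ** 2).sum(axis=1)).mean() < 0.2

    def test_constant_volume_fails(self, ct_template):
        flat = ct_template.copy_with(values=np.zeros(ct_template.grid.shape))
        with pytest.raises(RegistrationFailure):
            register_rigid(flat, ct_template)


class TestElasticRegistration:
    def test_self_registration_near_zero(self, ct_template):
        f = register_elastic(ct_template, ct_template)
        assert f.magnitude().mean() < 0.05

    def test_inspan_field_recovery(self, ct_template, reference_modalities):
        """A synthetic field inside the basis span, applied to the MR
        template, is recovered with RMS error < 0.2 mm over the head."""
        _, mr_t, _ = reference_modalities
        mr = resample(mr_t, ct_template.grid)
        mr.modality = "MR"
        rng = np.random.default_rng(5)
        truth = draw_random_field(ct_template.grid, 0.5, rng)
        pts = ct_template.grid.world_points()
        src = invert_mapping(pts, None, truth)
        moving = AnnotatedVolume(grid=ct_template.grid,
                                 values=sample_at_points(mr, src).reshape(
                                     ct_template.grid.shape), modality="MR")
        est = register_elastic(moving, mr)
        head = ct_template.values > 20  # soft tissue and denser
        e = np.sqrt(((est.displacement - truth.displacement) ** 2).sum(axis=0))
        assert np.sqrt((e[head] ** 2).mean()) < 0.2

    def test_large_regularization_shrinks_field(self, ct_template, reference_modalities):
        _, mr_t, _ = reference_modalities
        mr = resample(mr_t, ct_template.grid)
        mr.modality = "MR"
        rng = np.random.default_rng(9)
        truth = draw_random_field(ct_template.grid, 0.4, rng)
        pts = ct_template.grid.world_points()
        src = invert_mapping(pts, None, truth)
        moving = AnnotatedVolume(grid=ct_template.grid,
                                 values=sample_at_points(mr, src).reshape(
                                     ct_template.grid.shape), modality="MR")
        norms, wiggles = [], []
        for lam in (0.05, 10.0, 1e5):
            f = register_elastic(moving, mr,
                                 RegistrationSettings(regularization_weight=lam,
                                                      max_iterations=10))
            norms.append(f.magnitude().mean())
            # non-constant part: the membrane penalty's range (its null
            # space is a bulk translation, which stays data-driven)
            c = f.coefficients.copy()
            c[:, 0, 0, 0] = 0.0
            wiggles.append(np.abs(c).max())
        assert norms[0] > norms[1] > norms[2]
        assert wiggles[2] < 0.02

    def test_objective_decreases_and_deterministic(self, ct_template,
                                                   reference_modalities):
        _, mr_t, _ = reference_modalities
        mr = resample(mr_t, ct_template.grid)
        mr.modality = "MR"
        rng = np.random.default_rng(3)
        truth = draw_random_field(ct_template.grid, 0.3, rng)
        pts = ct_template.grid.world_points()
        src = invert_mapping(pts, None, truth)
        moving = AnnotatedVolume(grid=ct_template.grid,
                                 values=sample_at_points(mr, src).reshape(
                                     ct_template.grid.shape), modality="MR")
        f1 = register_elastic(moving, mr)
        f2 = register_elastic(moving, mr)
        assert np.array_equal(f1.coefficients, f2.coefficients)
        # final SSD no worse than the zero-field SSD
        zero = register_elastic(moving, mr, RegistrationSettings(max_iterations=0))
        assert f1.final_ssd <= zero.final_ssd


class TestApplyCompose:
    def test_identity_field_unchanged(self, ct_template):
        f = DeformationField.identity(ct_template.grid)
        out = apply_transform(ct_template, field=f)
        assert np.allclose(out.values, ct_template.values, atol=1e-9)

    def test_shift_and_back(self):
        """+s then -s returns the original within interpolation tolerance
        on a smooth volume (max abs diff < 1% of the range)."""
        grid = Grid(shape=(24, 24, 24), spacing=(0.2,) * 3, origin=(-2.3,) * 3)
        g = np.meshgrid(*[grid.axis_coords(i) for i in range(3)], indexing="ij")
        vals = 100 * np.exp(-(g[0] ** 2 + 1.3 * g[1] ** 2 + 0.7 * g[2] ** 2) / 4.0)
        vol = AnnotatedVolume(grid=grid, values=vals, modality="CT")
        s = (0.35, -0.2, 0.15)
        once = apply_transform(vol, rigid=RigidTransform(translation=s),
                               out_grid=grid)
        twice = apply_transform(once,
                                rigid=RigidTransform(translation=tuple(-np.array(s))),
                                out_grid=grid)
        interior = tuple(slice(4, -4) for _ in range(3))
        diff = np.abs(twice.values - vol.values)[interior]
        assert diff.max() < 0.01 * vals.max()

    def test_label_warp_preserves_label_set(self, anatomy):
        rng = np.random.default_rng(8)
        f = draw_random_field(anatomy.grid, 0.5, rng)
        warped = apply_transform(anatomy.annotation, field=f, interpolation="nearest")
        assert set(np.unique(warped.values)) <= set(np.unique(anatomy.annotation.values))

    def test_label_trilinear_rejected(self, anatomy):
        f = DeformationField.identity(anatomy.grid)
        with pytest.raises(ValidationError):
            apply_transform(anatomy.annotation, field=f, interpolation="trilinear")

    def test_compose_with_identity(self, rng):
        grid = Grid(shape=(8, 8, 8), spacing=(0.4,) * 3)
        f = draw_random_field(grid, 0.3, rng)
        out = compose_fields(f, RigidTransform.identity())
        assert np.allclose(out.displacement, f.displacement, atol=1e-12)

    def test_compose_shifts_add(self):
        grid = Grid(shape=(6, 6, 6), spacing=(0.4,) * 3)
        a = np.zeros((3,) + grid.shape)
        a[0] += 0.2
        fa = DeformationField(grid=grid, displacement=a)
        fb = RigidTransform(translation=(0.1, 0.3, -0.2))
        out = compose_fields(fa, fb)
        assert np.allclose(out.displacement[0], 0.3, atol=1e-12)
        assert np.allclose(out.displacement[1], 0.3, atol=1e-12)
        assert np.allclose(out.displacement[2], -0.2, atol=1e-12)

    def test_compose_with_numeric_inverse(self, rng):
        grid = Grid(shape=(16, 16, 16), spacing=(0.4,) * 3)
        f = draw_random_field(grid, 0.4, rng)
        finv = invert_field(f)
        out = compose_fields(f, finv)
        # residual below 0.1 voxel in the interior (edges extrapolate)
        interior = (slice(None), slice(2, -2), slice(2, -2), slice(2, -2))
        assert np.abs(out.displacement[interior]).mean() < 0.1 * 0.4

    def test_apply_requires_some_transform(self, ct_template):
        with pytest.raises(ValidationError):
            apply_transform(ct_template)
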