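"""SUV conversion, scaling, regional extraction, paired t and BH FDR."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from mousepet.atlas import LabelAtlas
from mousepet.errors import ValidationError
from mousepet.grids import AnnotatedVolume, Grid
from mousepet.stats import (analyze_cohort, analyze_paired_volumes,
                            extract_regional_means, fdr_bh, paired_t_test,
                            scale_to_global_mean, to_suv)


def _pet(values, spacing=0.4):
    grid = Grid(shape=values.shape, spacing=(spacing,) * 3)
    return AnnotatedVolume(grid=grid, values=values, modality="PET", units="kBq/mL")


def _two_region_atlas(shape=(6, 6, 6)):
    grid = Grid(shape=shape, spacing=(0.4,) * 3)
    labels = np.zeros(shape, dtype=np.int32)
    labels[:3] = 1
    labels[3:] = 2
    vol = AnnotatedVolume(grid=grid, values=labels, modality="label")
    regions = pd.DataFrame([
        {"label": 1, "name": "one", "abbreviation": "R1", "side": "C", "volume_mm3": 0},
        {"label": 2, "name": "two", "abbreviation": "R2", "side": "C", "volume_mm3": 0}])
    return LabelAtlas(volume=vol, regions=regions)


class TestSUV:
    def test_hand_arithmetic(self):
        pet = _pet(np.full((4, 4, 4), 200.0))
        suv = to_suv(pet, injected_activity_mbq=5.0, body_weight_g=25.0)
        assert np.allclose(suv.values, 1.0)  # 200 / (5000/25)

    def test_zero_concentration(self):
        suv = to_suv(_pet(np.zeros((4, 4, 4))), 4.7, 27.0)
        assert np.all(suv.values == 0)

    def test_ratio_invariance(self, rng):
        pet = _pet(np.abs(rng.normal(size=(4, 4, 4))))
        a = to_suv(pet, 5.0, 25.0)
        b = to_suv(pet, 10.0, 50.0)
        assert np.allclose(a.values, b.values)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            to_suv(_pet(np.ones((2, 2, 2))), 0.0, 25.0)
        with pytest.raises(ValidationError):
            to_suv(_pet(np.ones((2, 2, 2))), 5.0, -1.0)


class TestGlobalScaling:
    def test_masked_mean_exactly_one(self, rng):
        vol = _pet(np.abs(rng.normal(size=(6, 6, 6))) + 0.5)
        mask = AnnotatedVolume(grid=vol.grid,
                               values=(rng.random((6, 6, 6)) > 0.4).astype(np.uint8),
                               modality="mask")
        out = scale_to_global_mean(vol, mask)
        assert abs(out.values[mask.values.astype(bool)].mean() - 1.0) < 1e-12

    def test_calibration_invariance(self, rng):
        vol = _pet(np.abs(rng.normal(size=(5, 5, 5))) + 0.5)
        mask = AnnotatedVolume(grid=vol.grid, values=np.ones((5, 5, 5), np.uint8),
                               modality="mask")
        a = scale_to_global_mean(vol, mask)
        b = scale_to_global_mean(vol.copy_with(values=vol.values * 7.3), mask)
        assert np.allclose(a.values, b.values)

    def test_suv_then_scale_equals_raw_scale(self, rng):
        """SUV conversion is a positive constant, so it cancels under
        global-mean scaling (density/dose assumptions are irrelevant
        downstream)."""
        vol = _pet(np.abs(rng.normal(size=(5, 5, 5))) + 0.5)
        mask = AnnotatedVolume(grid=vol.grid, values=np.ones((5, 5, 5), np.uint8),
                               modality="mask")
        via_suv = scale_to_global_mean(to_suv(vol, 4.2, 26.0), mask)
        raw = scale_to_global_mean(vol, mask)
        assert np.allclose(via_suv.values, raw.values)

    def test_empty_mask_rejected(self):
        vol = _pet(np.ones((3, 3, 3)))
        mask = AnnotatedVolume(grid=vol.grid, values=np.zeros((3, 3, 3), np.uint8),
                               modality="mask")
        with pytest.raises(ValidationError):
            scale_to_global_mean(vol, mask)


class TestExtraction:
    def test_piecewise_constant(self):
        atlas = _two_region_atlas()
        values = np.zeros((6, 6, 6))
        values[:3] = 2.0
        values[3:] = 5.0
        vol = AnnotatedVolume(grid=atlas.grid, values=values, modality="PET")
        means = extract_regional_means(vol, atlas).set_index("region")["mean"]
        assert means["R1"] == 2.0 and means["R2"] == 5.0

    def test_hand_computed_means(self, rng):
        atlas = _two_region_atlas()
        vol = AnnotatedVolume(grid=atlas.grid, values=rng.normal(size=(6, 6, 6)),
                              modality="PET")
        means = extract_regional_means(vol, atlas).set_index("region")["mean"]
        assert np.isclose(means["R1"], vol.values[:3].mean())
        assert np.isclose(means["R2"], vol.values[3:].mean())


class TestPairedT:
    def test_identical_conditions(self):
        t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_textbook_closed_form(self):
        """diffs (1,-1,0,2,1,3): t = mean/(sd/sqrt(6)) against the closed form."""
        d = np.array([1.0, -1.0, 0.0, 2.0, 1.0, 3.0])
        x0 = np.zeros(6)
        t, p = paired_t_test(x0, d)
        expect_t = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        assert abs(t - expect_t) < 1e-12
        from scipy.stats import t as tdist
        assert abs(p - 2 * tdist.sf(abs(expect_t), 5)) < 1e-12

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=(2, 8))
        t1, p1 = paired_t_test(a, b)
        t2, p2 = paired_t_test(b, a)
        assert np.isclose(t1, -t2) and np.isclose(p1, p2)

    def test_matches_closed_form_many_cases(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            t, p = paired_t_test(a, b)
            d = b - a
            expect = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            assert abs(t - expect) < 1e-10

    def test_degenerate_variance(self):
        t, p = paired_t_test([1.0, 2.0], [2.0, 3.0])  # constant nonzero diff
        assert p == 0.0


def _bh_bruteforce(p, q):
    """Step-up by definition: largest i with p_(i) <= i q / m."""
    p = np.asarray(p)
    order = np.argsort(p, kind="stable")
    m = len(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestFDR:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    @hyp_settings(max_examples=200, deadline=None)
    def test_matches_stepup_definition(self, p, q):
        _, reject = fdr_bh(p, q=q)
        assert np.array_equal(reject, _bh_bruteforce(p, q))

    def test_adjusted_monotone(self, rng):
        p = rng.random(25)
        adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p - 1e-15)

    def test_all_at_half_q_rejected(self):
        _, reject = fdr_bh([0.025] * 7, q=0.05)
        assert reject.all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh([0.5, 1.5])


class TestCohortAnalysis:
    def test_three_conditions_rejected(self):
        manifest = pd.DataFrame({
            "subject": ["a", "a", "a"], "condition": ["d0", "d7", "d14"],
            "pet": [""] * 3, "injected_activity_mbq": [4.7] * 3,
            "body_weight_g": [25.0] * 3})
        with pytest.raises(ValidationError):
            analyze_cohort(manifest, atlas=None)

    def test_in_memory_paired_analysis(self, rng):
        atlas = _two_region_atlas()
        pets, doses = {}, {}
        for i in range(5):
            s = f"m{i}"
            base = np.abs(rng.normal(size=(6, 6, 6))) + 1.0
            for cond, boost in (("d0", 1.0), ("d7", 1.0)):
                v = base * boost * (1 + rng.normal(0, 0.01, size=base.shape))
                pets[(s, cond)] = AnnotatedVolume(grid=atlas.grid, values=v,
                                                  modality="PET")
                doses[(s, cond)] = (4.7, 27.0)
        out = analyze_paired_volumes(pets, doses, atlas, ("d0", "d7"))
        assert set(out["region"]) == {"R1", "R2"}
        assert (out["p_adjusted"] >= out["p_value"] - 1e-15).all()
        assert out["significant_unadjusted"].equals(out["p_value"] < 0.05)
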