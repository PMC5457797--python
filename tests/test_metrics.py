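"""Loss metrics: regional means, fractional/pattern deviation, GLV, FLV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gsdi.metrics import (compute_all_metrics, compute_flv, compute_glv,
                          fractional_deviation_map, pattern_deviation_map,
                          regional_mean)
from gsdi.simulate import SUPERIOR, INFERIOR, ThicknessMap

from conftest import constant_map, full_square_region, make_eye


def _map(values, modality="GCC"):
    values = np.asarray(values, dtype=float)
    return ThicknessMap(values, full_square_region(values.shape), modality)


class TestRegionalMean:
    def test_constant_map_any_region(self):
        m = constant_map(100.0)
        for region in ("overall", "superior", "inferior"):
            assert regional_mean(m, region) == pytest.approx(100.0)

    def test_hemifield_means_average_to_overall(self):
        values = np.vstack([np.full((5, 10), 80.0), np.full((5, 10), 120.0)])
        m = _map(values)
        assert regional_mean(m, "superior") == pytest.approx(80.0)
        assert regional_mean(m, "inferior") == pytest.approx(120.0)
        assert regional_mean(m, "overall") == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_location_loop(self, seed):
        rng = np.random.default_rng(seed)
        m = _map(rng.uniform(40, 140, (8, 8)))
        for region in ("overall", "superior", "inferior"):
            mask = m.region_mask(region)
            loop = sum(m.values[i, j] for i in range(8) for j in range(8)
                       if mask[i, j]) / mask.sum()
            assert regional_mean(m, region) == pytest.approx(loop)


class TestFractionalDeviation:
    def test_map_at_reference_mean_is_zero(self, exact_ref):
        fd = fractional_deviation_map(constant_map(100.0), exact_ref)
        assert np.allclose(fd, 0.0)

    def test_uniform_thinning_gives_constant_fd(self, exact_ref):
        fd = fractional_deviation_map(constant_map(90.0), exact_ref)
        assert np.allclose(fd, -0.10)

    def test_agrees_with_location_loop(self, exact_ref):
        rng = np.random.default_rng(1)
        m = _map(rng.uniform(60, 130, (10, 10)))
        fd = fractional_deviation_map(m, exact_ref)
        for i, j in [(0, 0), (3, 7), (9, 9)]:
            assert fd[i, j] == pytest.approx((m.values[i, j] - 100.0) / 100.0)

    def test_shape_mismatch_rejected(self, exact_ref):
        with pytest.raises(ValueError, match="shape"):
            fractional_deviation_map(constant_map(100.0, shape=(6, 6)),
                                     exact_ref)


class TestGLV:
    def test_map_at_mean_gives_zero(self, exact_ref):
        assert compute_glv(constant_map(100.0), exact_ref) == pytest.approx(0.0)

    def test_uniform_ten_percent_thinning(self, exact_ref):
        assert compute_glv(constant_map(90.0), exact_ref) == pytest.approx(10.0)

    def test_half_map_twenty_percent_thinner(self, exact_ref):
        values = np.full((10, 10), 100.0)
        values[:5] = 80.0  # half the map 20% thinner
        # brute-force sum over the grid of negative fractional deviations
        brute = 100 * sum(max(0.0, (100 - v) / 100) for v in values.ravel()) / 100
        assert compute_glv(_map(values), exact_ref) == pytest.approx(brute)
        assert brute == pytest.approx(10.0)

    def test_thickening_does_not_count(self, exact_ref):
        assert compute_glv(constant_map(120.0), exact_ref) == pytest.approx(0.0)

    def test_monotone_under_thinning(self, exact_ref):
        rng = np.random.default_rng(2)
        values = rng.uniform(80, 120, (10, 10))
        base = compute_glv(_map(values), exact_ref)
        for _ in range(10):
            i, j = rng.integers(0, 10, 2)
            values2 = values.copy()
            values2[i, j] *= 0.7
            assert compute_glv(_map(values2), exact_ref) >= base


class TestPatternDeviation:
    def test_uniform_thinning_is_removed(self, exact_ref):
        for frac in (0.05, 0.2, 0.5):
            pdm = pattern_deviation_map(constant_map(100 * (1 - frac)),
                                        exact_ref)
            assert np.allclose(pdm, 0.0, atol=1e-12)

    def test_focal_defect_after_rescaling(self, exact_ref):
        # 50% defect over 10% of the map: rescale factor 1/0.95, so the
        # defect's pattern deviation is 0.5/0.95 - 1 = -0.4737
        values = np.full((10, 10), 100.0)
        values[0] = 50.0
        pdm = pattern_deviation_map(_map(values), exact_ref)
        assert np.allclose(pdm[0], 0.5 / 0.95 - 1.0)
        assert np.allclose(pdm[1:], 1.0 / 0.95 - 1.0)
        # loop oracle
        factor = 100.0 / values.mean()
        for i, j in [(0, 0), (5, 5)]:
            assert pdm[i, j] == pytest.approx(
                (values[i, j] * factor - 100.0) / 100.0)

    def test_non_positive_mean_rejected(self, exact_ref):
        with pytest.raises(ValueError, match="positive"):
            pattern_deviation_map(constant_map(0.0), exact_ref)


class TestFLV:
    def test_map_at_mean_gives_zero(self, exact_ref):
        assert compute_flv(constant_map(100.0), exact_ref) == pytest.approx(0.0)

    def test_pure_diffuse_thinning_gives_zero(self, exact_ref):
        for frac in (0.1, 0.3):
            assert compute_flv(constant_map(100 * (1 - frac)),
                               exact_ref) == pytest.approx(0.0)

    def test_focal_defect_contributes_full_fractional_loss(self, exact_ref):
        # 50% defect over 10% of area -> FLV = 100 * 0.10 * 0.50 = 5%
        values = np.full((10, 10), 100.0)
        values[0] = 50.0
        assert compute_flv(_map(values), exact_ref) == pytest.approx(5.0)

    def test_pattern_flv_is_scale_invariant_but_glv_is_not(self, exact_ref):
        # the significant-location set and the pattern contribution ignore
        # uniform rescaling; GLV picks up the extra diffuse deficit
        values = np.full((10, 10), 100.0)
        values[0] = 50.0
        m1, m2 = _map(values), _map(values * 0.8)
        assert compute_flv(m2, exact_ref, sum_pattern=True) == pytest.approx(
            compute_flv(m1, exact_ref, sum_pattern=True), abs=1e-9)
        assert compute_glv(m2, exact_ref) > compute_glv(m1, exact_ref)

    def test_sum_pattern_variant_uses_pattern_deviation(self, exact_ref):
        values = np.full((10, 10), 100.0)
        values[0] = 50.0
        flv_pattern = compute_flv(_map(values), exact_ref, sum_pattern=True)
        assert flv_pattern == pytest.approx(100 * 10 * (1 - 0.5 / 0.95) / 100)


class TestComputeAllMetrics:
    def test_eye_at_reference_mean(self, exact_ref):
        eye = make_eye(np.full((10, 10), 100.0), np.full((1, 20), 100.0),
                       vcdr=0.4)
        lm = compute_all_metrics(eye, exact_ref)
        for mod in (lm.gcc, lm.nfl):
            assert mod.overall_um == pytest.approx(100.0)
            assert mod.glv_pct == pytest.approx(0.0)
            assert mod.flv_pct == pytest.approx(0.0)
        assert lm.vcdr == 0.4

    def test_orientation_flip_preserving_masks_is_invariant(self, exact_ref):
        rng = np.random.default_rng(4)
        values = rng.uniform(70, 120, (10, 10))
        eye = make_eye(values, np.full((1, 20), 100.0))
        flipped = make_eye(values[:, ::-1], np.full((1, 20), 100.0))
        a = compute_all_metrics(eye, exact_ref).to_series()
        b = compute_all_metrics(flipped, exact_ref).to_series()
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_matches_recomputation_from_primitives(self, exact_ref):
        rng = np.random.default_rng(5)
        eye = make_eye(rng.uniform(70, 120, (10, 10)),
                       rng.uniform(70, 120, (1, 20)), vcdr=0.55)
        lm = compute_all_metrics(eye, exact_ref)
        assert lm.gcc.overall_um == pytest.approx(
            regional_mean(eye.gcc_map, "overall"))
        assert lm.nfl.glv_pct == pytest.approx(
            compute_glv(eye.nfl_map, exact_ref))
        assert lm.gcc.flv_pct == pytest.approx(
            compute_flv(eye.gcc_map, exact_ref))
        s = lm.to_series()
        assert set(s.index) >= {"gcc_overall_um", "nfl_flv_pct", "vcdr"}
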