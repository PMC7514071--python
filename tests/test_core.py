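"""Unit and property tests for the effect-size formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import impactsize as im
from impactsize.synthetic import make_dataset2

TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


def gmd_bruteforce(x):
    """Independent O(n^2) oracle: literal double loop over ordered pairs."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    return sum(abs(a - b) for a in x for b in x) / n ** 2


class TestGMD:
    def test_constant_vector_is_zero(self):
        assert im.gmd(np.full(17, 3.5)) == 0.0
        assert im.gmd([42.0]) == 0.0

    def test_small_example(self):
        assert im.gmd([1, 2, 3]) == pytest.approx(8 / 9, abs=1e-15)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            im.gmd([])

    def test_normal_closed_form(self, rng):
        # E|X - Y| = 2 sigma / sqrt(pi) for iid normals
        x = rng.normal(0.0, 1.0, 10_000)
        assert im.gmd(x) == pytest.approx(TWO_OVER_SQRT_PI, rel=0.02)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_matches_bruteforce_oracle(self, values):
        expected = gmd_bruteforce(values)
        assert im.gmd(values) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_matches_bruteforce_oracle_n200(self, rng):
        x = rng.normal(0.0, 10.0, 200)
        assert im.gmd(x) == pytest.approx(gmd_bruteforce(x), rel=1e-12)


class TestPooledGMD:
    def test_both_groups_constant_falls_to_epsilon(self):
        assert im.pooled_gmd(np.ones(100), np.ones(100), epsilon=1e-7) == 1e-7

    def test_one_group_constant_uses_pooled_vector(self):
        # pooled {1}x100 + {2}x100: 2*100*100*1 / 200^2 = 0.5
        assert im.pooled_gmd(np.ones(100), 2 * np.ones(100)) == pytest.approx(0.5)

    def test_rms_pooling_preserves_common_gmd(self, rng):
        x1 = rng.normal(0.0, 1.0, 20_000)
        x2 = rng.normal(5.0, 1.0, 20_000)
        assert im.pooled_gmd(x1, x2) == pytest.approx(TWO_OVER_SQRT_PI, rel=0.02)

    def test_always_positive_and_finite(self, rng):
        for x1, x2 in [(np.zeros(5), np.zeros(5)), (np.zeros(5), rng.normal(size=5)),
                       (rng.normal(size=5), rng.normal(size=5))]:
            g = im.pooled_gmd(x1, x2)
            assert np.isfinite(g) and g > 0


class TestComponents:
    def test_ct_diff_identical_groups(self, rng):
        x = rng.normal(size=50)
        assert im.ct_diff(x, x, im.pooled_gmd(x, x)) == 0.0

    def test_ct_diff_degenerate_worked_example(self):
        x1, x2 = np.ones(100), 2 * np.ones(100)
        assert im.ct_diff(x1, x2, im.pooled_gmd(x1, x2)) == pytest.approx(2.0)

    def test_ct_diff_gaussian_closed_form(self, rng):
        x1 = rng.normal(0.0, 1.0, 100_000)
        x2 = rng.normal(3.0, 1.0, 100_000)
        expected = 3.0 / TWO_OVER_SQRT_PI  # ~2.659
        assert im.ct_diff(x1, x2, im.pooled_gmd(x1, x2)) == pytest.approx(expected, rel=0.02)

    def test_dir_ct(self):
        assert im.dir_ct([1, 2, 3], [1, 2, 3]) == 1  # tie -> +1
        assert im.dir_ct([1.0], [2.0]) == 1
        assert im.dir_ct([-2.258], [-3.645]) == -1

    @pytest.mark.parametrize("ct, expected", [(0.0, 0.0), (1.0, 0.5), (2.0, 1.0),
                                              (2.66, 1.0), (100.0, 1.0)])
    def test_ct_weight_clamp(self, ct, expected):
        assert im.ct_weight(ct) == expected

    def test_ct_weight_rejects_negative(self):
        with pytest.raises(ValueError):
            im.ct_weight(-0.1)

    def test_log_modulus(self):
        e = np.e
        np.testing.assert_allclose(im.log_modulus([0.0, e - 1, -(e - 1)]),
                                   [0.0, 1.0, -1.0], atol=1e-15)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_log_modulus_odd_and_monotone(self, values):
        x = np.sort(np.asarray(values))
        lx = im.log_modulus(x)
        np.testing.assert_allclose(im.log_modulus(-x), -lx, atol=1e-12)
        assert np.all(np.diff(lx) >= 0)

    def test_momentum(self):
        e = np.e
        assert im.momentum([0, 0, 0]) == 0.0
        assert im.momentum([e - 1, -(e - 1)]) == pytest.approx(0.0, abs=1e-15)
        assert im.momentum([e - 1, e ** 2 - 1]) == pytest.approx(1.5)

    def test_dir_morph(self, rng):
        x = np.abs(rng.normal(size=200)) + 0.1
        assert im.dir_morph(x, x) == 1          # tie -> +1
        assert im.dir_morph(x, x + 1.0) == 1    # shifted right
        assert im.dir_morph(x, -x) == -1        # negated flips momentum sign


class TestKSGate:
    def test_identical_samples_gate(self, rng):
        x = rng.normal(size=40)
        p, gated = im.ks_gate(x, x)
        assert gated and p == 1.0

    def test_identical_discrete_sequences_gate(self):
        seq = np.tile(np.arange(1.0, 6.0), 20)
        _, gated = im.ks_gate(seq, seq.copy())
        assert gated

    def test_separated_normals_not_gated(self, rng):
        _, gated = im.ks_gate(rng.normal(0, 1, 1000), rng.normal(3, 1, 1000))
        assert not gated


class TestComputeImpact:
    def test_identical_groups_zero(self, rng):
        x = rng.normal(size=100)
        res = im.compute_impact(im.LabeledSample.from_groups(x, x.copy()))
        assert res.impact == 0.0 and res.gated_zero

    def test_degenerate_groups_give_two(self):
        res = im.impact(np.r_[np.ones(100), 2 * np.ones(100)],
                        np.r_[np.zeros(100), np.ones(100)])
        assert res.impact == pytest.approx(2.0)
        assert res.ct_weight == 1.0 and res.ct_diff == pytest.approx(2.0)

    def test_components_recompose(self, rng):
        sample = im.LabeledSample.from_groups(rng.normal(0, 1, 300),
                                              rng.normal(0.6, 2, 300))
        r = im.compute_impact(sample)
        if not r.gated_zero:
            expected = (r.ct_weight * r.dir_ct * r.ct_diff
                        + (1 - r.ct_weight) * r.dir_morph * r.morph_diff)
            assert r.impact == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= r.ct_weight <= 1.0
        assert 0.0 <= r.morph_diff <= 2.0 + 1e-9

    def test_absolute_value_option(self, rng):
        x1, x2 = rng.normal(2, 1, 300), rng.normal(0, 1, 300)
        signed = im.impact(np.r_[x1, x2], np.r_[np.ones(300), 2 * np.ones(300)])
        absval = im.impact(np.r_[x1, x2], np.r_[np.ones(300), 2 * np.ones(300)],
                           absolute_value=True)
        assert signed.impact < 0 and absval.impact == pytest.approx(-signed.impact)

    def test_rejects_bad_labels(self, rng):
        with pytest.raises(ValueError):
            im.impact(rng.normal(size=9), np.repeat([0, 1, 2], 3))
        with pytest.raises(ValueError):
            im.impact(rng.normal(size=4), np.zeros(4))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_antisymmetry_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        sample = im.LabeledSample.from_groups(rng.normal(0, 1, 200),
                                              rng.normal(1.0, 1.5, 200))
        fwd = im.compute_impact(sample)
        bwd = im.compute_impact(sample.swapped())
        assert bwd.impact == pytest.approx(-fwd.impact, abs=1e-9)
        assert bwd.ct_diff == pytest.approx(fwd.ct_diff)
        assert bwd.morph_diff == pytest.approx(fwd.morph_diff, abs=1e-9)

    @pytest.mark.parametrize("scale", [10.0, 0.1])
    def test_scale_invariance(self, scale, rng):
        x1, x2 = rng.normal(0, 1, 400), rng.normal(0, 3, 400)
        base = im.compute_impact(im.LabeledSample.from_groups(x1, x2))
        scaled = im.compute_impact(im.LabeledSample.from_groups(scale * x1, scale * x2))
        assert abs(scaled.impact - base.impact) < 0.05

    def test_no_nan_on_zero_variance_scenarios(self):
        for subset in make_dataset2(seed=5):
            res = im.compute_impact(subset.sample)
            for value in (res.impact, res.ct_diff, res.morph_diff,
                          res.gmd_pooled, res.ct_weight, res.gate_pvalue):
                assert np.isfinite(value), subset.name


class TestCohensD:
    def test_identical_groups_zero(self, rng):
        x = rng.normal(size=60)
        assert im.cohens_d(x, x) == 0.0

    def test_zero_variance_raises(self):
        with pytest.raises(im.UndefinedEffectSizeError):
            im.cohens_d(np.ones(100), 2 * np.ones(100))

    def test_poolings_agree_for_equal_group_sizes(self, rng):
        x1, x2 = rng.normal(0, 1, 500), rng.normal(1, 2, 500)
        assert im.cohens_d(x1, x2, "rms") == pytest.approx(
            im.cohens_d(x1, x2, "n_weighted"))

    def test_separated_normals(self, rng):
        d = im.cohens_d(rng.normal(0, 1, 1000), rng.normal(3, 1, 1000))
        assert d == pytest.approx(3.0, abs=0.2)
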