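"""Cyclic-shift surrogates, empirical p-values and BH-FDR masking."""

import numpy as np
import pytest

import ewcomm as e
from ewcomm import surrogate as sur
from ewcomm import tensors as tns


class TestCyclicSurrogate:
    def test_zero_shift_is_identity(self, rng):
        x = rng.standard_normal((4, 100))
        np.testing.assert_array_equal(sur.cyclic_surrogate(x, 0, rng, shift=0), x)

    def test_shift_group_property(self, rng):
        x = rng.standard_normal((4, 100))
        y = sur.cyclic_surrogate(x, 1, rng, shift=37)
        z = sur.cyclic_surrogate(y, 1, rng, shift=100 - 37)
        np.testing.assert_array_equal(z, x)

    def test_source_untouched_targets_shifted(self, rng):
        x = rng.standard_normal((4, 100))
        y = sur.cyclic_surrogate(x, 2, rng, shift=11)
        np.testing.assert_array_equal(y[2], x[2])
        np.testing.assert_array_equal(y[0], np.roll(x[0], 11))

    def test_circular_autocorrelation_preserved(self, rng):
        x = rng.standard_normal((2, 256))
        y = sur.cyclic_surrogate(x, 0, rng, shift=77)

        def circ_acf(v):
            f = np.fft.fft(v - v.mean())
            return np.real(np.fft.ifft(f * np.conj(f)))

        np.testing.assert_allclose(circ_acf(y[1]), circ_acf(x[1]), atol=1e-9)

    def test_marginal_distribution_preserved(self, rng):
        x = rng.standard_normal((3, 64))
        y = sur.cyclic_surrogate(x, 0, rng, shift=5)
        np.testing.assert_allclose(np.sort(y[1]), np.sort(x[1]))


class TestSurrogatePvalues:
    def test_extreme_observed_hits_floor(self, rng):
        surr = rng.standard_normal((100, 3, 10)) * 0.1
        obs = np.full((3, 10), 5.0)
        p = sur.surrogate_pvalues(obs, surr)
        np.testing.assert_allclose(p, 1.0 / 100)

    def test_zero_observed_gives_one(self, rng):
        surr = rng.standard_normal((50, 2, 10))
        p = sur.surrogate_pvalues(np.zeros((2, 10)), surr)
        np.testing.assert_allclose(p, 1.0)

    def test_null_calibration_uniform(self, rng):
        # observed drawn from the surrogate distribution itself
        pool = rng.standard_normal(5000)
        ps = []
        for _ in range(400):
            surr = rng.choice(pool, size=(200, 1, 1))
            obs = rng.choice(pool, size=(1, 1))
            ps.append(sur.surrogate_pvalues(obs, surr)[0, 0])
        from scipy import stats

        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_missing_observed_propagates(self, rng):
        surr = rng.standard_normal((50, 1, 2))
        obs = np.array([[np.nan, 0.5]])
        p = sur.surrogate_pvalues(obs, surr)
        assert np.isnan(p[0, 0]) and np.isfinite(p[0, 1])


def _brute_bh(p, q=0.05):
    """Independent BH step-up oracle: sort, find largest k with
    p_(k) <= k q / m, reject all smaller."""
    m = len(p)
    order = np.argsort(p)
    thresh = q * (np.arange(1, m + 1)) / m
    passed = np.flatnonzero(p[order] <= thresh)
    mask = np.zeros(m, dtype=int)
    if passed.size:
        mask[order[: passed.max() + 1]] = 1
    return mask


class TestFdrMask:
    def test_all_small_all_in(self):
        p = np.full((100, 1), 0.001)
        assert sur.fdr_mask(p).all()

    def test_all_large_all_out(self):
        p = np.full((100, 1), 0.5)
        assert not sur.fdr_mask(p).any()

    def test_matches_brute_force_bh(self, rng):
        for _ in range(50):
            p = rng.random(40)
            got = sur.fdr_mask(p[:, None])[:, 0]
            np.testing.assert_array_equal(got, _brute_bh(p))

    def test_columns_independent(self, rng):
        p = np.column_stack([np.full(20, 0.001), np.full(20, 0.9)])
        mask = sur.fdr_mask(p)
        assert mask[:, 0].all() and not mask[:, 1].any()

    def test_missing_p_masked_out(self):
        p = np.array([[0.001], [np.nan], [0.002]])
        mask = sur.fdr_mask(p)
        assert mask[1, 0] == 0 and mask[0, 0] == 1


class TestSurrogatePipeline:
    def test_surrogate_branch_uses_shared_engine(self):
        # the null must be produced by the same code path as the observed pass
        assert sur._ENGINE is tns.compute_tensors

    def test_reproducible_given_seed(self, small_epochs, small_connectome):
        params = e.EwcParams()
        cat = tns.build_event_catalog(small_epochs, small_connectome, params, 250.0)
        kw = dict(n_surrogates=3, seed=42)
        a = sur.surrogate_principles(
            small_epochs, cat, small_connectome, params, 250.0, **kw
        )
        b = sur.surrogate_principles(
            small_epochs, cat, small_connectome, params, 250.0, **kw
        )
        np.testing.assert_array_equal(a, b)

    def test_mask_principles_zeroes_nonsignificant(self):
        vals = np.array([[0.5, -0.4], [np.nan, 0.2]])
        mask = np.array([[1, 0], [0, 1]])
        out = sur.mask_principles(vals, mask)
        assert out[0, 0] == 0.5 and out[0, 1] == 0.0
        assert np.isnan(out[1, 0]) and out[1, 1] == 0.2
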