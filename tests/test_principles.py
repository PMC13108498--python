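"""Principle-matrix construction and top-band ANOVA/Tukey statistics."""

import numpy as np
import pytest
from scipy import stats

import ewcomm as e
from ewcomm.principles import _family_report, principle_rows, top_band_report


def _fake_tensors(rng, N=6, M=8, B=5, density=0.6):
    adj = (rng.random((N, N)) < density).astype(int)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    comm = rng.standard_normal((N, N, M)) * (adj[:, :, None] > 0)
    power = rng.random((N, N, M, B)) * 0.15
    ispc = rng.random((N, N, M, B))
    return adj, comm, power, ispc


class TestPrincipleRows:
    def test_self_correlation_near_one(self, rng):
        adj, comm, power, ispc = _fake_tensors(rng)
        # spectral measure equal to communication plus tiny noise
        for b in range(5):
            power[..., b] = comm + 1e-4 * rng.standard_normal(comm.shape)
            ispc[..., b] = comm + 1e-4 * rng.standard_normal(comm.shape)
        rows, _ = principle_rows(comm, power, ispc, adj)
        valid = np.isfinite(rows)
        assert valid.any()
        assert (rows[valid] >= 0.99).all()

    def test_shuffled_measures_have_null_mean(self, rng):
        means = []
        for _ in range(100):
            adj, comm, power, ispc = _fake_tensors(rng)
            rows, _ = principle_rows(comm, power, ispc, adj)
            means.append(np.nanmean(rows))
        means = np.asarray(means)
        assert abs(means.mean()) < 3 * means.std() / np.sqrt(len(means))

    def test_too_few_samples_flagged_missing(self, rng):
        adj = np.array([[0, 1], [1, 0]])
        comm = rng.standard_normal((2, 2, 3))  # 3 cells < MIN_VALID
        power = rng.random((2, 2, 3, 5))
        ispc = rng.random((2, 2, 3, 5))
        rows, nval = principle_rows(comm, power, ispc, adj)
        assert np.isnan(rows).all()
        assert (nval == 3).all()

    def test_restricted_to_connected_targets(self, rng):
        adj, comm, power, ispc = _fake_tensors(rng)
        rows, _ = principle_rows(comm, power, ispc, adj)
        # corrupting disconnected cells must not change anything
        comm2 = comm.copy()
        comm2[adj == 0] = 1e6
        rows2, _ = principle_rows(comm2, power, ispc, adj)
        np.testing.assert_allclose(np.nan_to_num(rows), np.nan_to_num(rows2))

    def test_scale_shift_invariance(self, rng):
        adj, comm, power, ispc = _fake_tensors(rng)
        r1, _ = principle_rows(comm, power, ispc, adj)
        r2, _ = principle_rows(3.0 * comm + 1.0, power, ispc, adj)
        np.testing.assert_allclose(np.nan_to_num(r1), np.nan_to_num(r2), atol=1e-12)


def _brute_anova_tukey(data):
    """Independent oracle: one-way ANOVA F/p and Tukey-Kramer p for the top
    two groups, from first principles (studentized range distribution)."""
    k = data.shape[1]
    n = data.shape[0]
    grand = data.mean()
    ssb = n * ((data.mean(0) - grand) ** 2).sum()
    ssw = ((data - data.mean(0)) ** 2).sum()
    dfb, dfw = k - 1, k * n - k
    F = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(F, dfb, dfw)
    mse = ssw / dfw
    order = np.argsort(data.mean(0))[::-1]
    diff = abs(data.mean(0)[order[0]] - data.mean(0)[order[1]])
    q = diff / np.sqrt(mse / n)
    p_tukey = stats.studentized_range.sf(q, k, dfw)
    return F, p, p_tukey


class TestTopBandReport:
    def test_matches_brute_force_oracle(self, rng):
        data = rng.standard_normal((8, 5)) * 0.3
        data[:, 2] += 1.0
        data[:, 4] += 0.6
        rec = _family_report(data, list(e.BAND_NAMES), alpha=0.05)
        F, p, p_tukey = _brute_anova_tukey(data)
        assert abs(rec["f_stat"] - F) < 1e-8
        assert abs(rec["anova_p"] - p) < 1e-8
        assert abs(rec["tukey_p_top2"] - p_tukey) < 1e-8

    def test_constructed_effect_single_dominant(self, rng):
        mats = []
        for _ in range(8):
            m = rng.standard_normal((4, 10)) * 0.05
            m[:, 1] += 0.5  # alpha power column shifted
            mats.append(m)
        rep = top_band_report(mats)
        pw = rep[rep.family == "power"]
        assert (pw.top_band == "alpha").all()
        assert pw.single_dominant.all()

    def test_null_false_dominance_rate(self, rng):
        false_hits = 0
        trials = 200
        for _ in range(trials):
            data = rng.standard_normal((6, 5))
            rec = _family_report(data, list(e.BAND_NAMES), alpha=0.05)
            if rec["single_dominant"]:
                false_hits += 1
        assert false_hits / trials <= 0.05 + 0.03

    def test_identical_groups_no_top_band(self):
        mats = [np.ones((3, 10)) * 0.2 for _ in range(5)]
        rep = top_band_report(mats)
        assert (rep.f_stat == 0).all()
        assert rep.top_band.isna().all()

    def test_requires_three_recordings(self, rng):
        with pytest.raises(ValueError):
            top_band_report([rng.standard_normal((3, 10))] * 2)
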