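"""The synthetic oscillator-network generator."""

import numpy as np
import pytest

import ewcomm as e
from ewcomm.spectral import welch_band_power


class TestGenerateConnectome:
    def test_two_regions_full_density(self):
        conn = e.generate_connectome(2, 1.0, seed=0)
        np.testing.assert_array_equal(conn.adjacency, [[0, 1], [1, 0]])

    def test_edge_count_matches_density(self):
        conn = e.generate_connectome(12, 0.15, seed=1)
        assert conn.adjacency.sum() // 2 == round(0.15 * 66)

    def test_determinism(self):
        a = e.generate_connectome(9, 0.3, seed=4)
        b = e.generate_connectome(9, 0.3, seed=4)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_centroids_distinct_and_on_sphere(self):
        conn = e.generate_connectome(20, 0.2, seed=2)
        d = conn.distances_mm
        assert (d[np.triu_indices(20, 1)] > 0).all()
        np.testing.assert_allclose(np.linalg.norm(conn.centroids, axis=1), 70.0)

    def test_too_sparse_errors(self):
        with pytest.raises(ValueError):
            e.generate_connectome(3, 0.01, seed=0)


def _lagged_xcorr(x, y, lag):
    # correlation of x(t) with y(t + lag)
    if lag > 0:
        return np.corrcoef(x[:-lag], y[lag:])[0, 1]
    return np.corrcoef(x, y)[0, 1]


class TestSimulateRecording:
    def test_zero_coupling_gives_independent_regions(self):
        vals = []
        for seed in range(50):
            conn = e.generate_connectome(4, 0.5, seed=seed)
            cfg = e.SimulationConfig(
                n_regions=4, duration_s=12.0, coupling_gain=0.0,
                event_rate_hz=0.0, seed=seed,
            )
            rec, _ = e.simulate_recording(conn, cfg)
            vals.append(_lagged_xcorr(rec.data[0], rec.data[1], 2))
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(len(vals))

    def test_coupling_gain_monotone_in_lagged_xcorr(self):
        adj = np.array([[0, 1], [1, 0]])
        cent = np.array([[0.0, 0, 0], [80.0, 0, 0]])  # 8 ms -> 2 samples
        conn = e.Connectome(adjacency=adj, centroids=cent)
        coup_dir = np.array([[0.0, 1.0], [0.0, 0.0]])
        xcs = []
        for g in (0.0, 0.2, 0.5):
            cfg = e.SimulationConfig(
                n_regions=2, duration_s=20.0, event_rate_hz=0.0, seed=21
            )
            rec, _ = e.simulate_recording(conn, cfg, coupling=g * coup_dir)
            xcs.append(_lagged_xcorr(rec.data[0], rec.data[1], 2))
        assert xcs[0] < xcs[1] < xcs[2]

    def test_zero_event_rate_gives_empty_catalogs(self, small_connectome):
        cfg = e.SimulationConfig(
            n_regions=6, duration_s=12.0, connection_density=0.5,
            event_rate_hz=0.0, seed=3,
        )
        _, truth = e.simulate_recording(small_connectome, cfg)
        assert all(t.size == 0 for t in truth.event_times)

    def test_event_times_strictly_increasing(self, small_recording):
        _, truth = small_recording
        for t in truth.event_times:
            assert (np.diff(t) > 0).all()

    def test_determinism(self, small_connectome):
        cfg = e.SimulationConfig(n_regions=6, duration_s=12.0, seed=8)
        r1, _ = e.simulate_recording(small_connectome, cfg)
        r2, _ = e.simulate_recording(small_connectome, cfg)
        np.testing.assert_array_equal(r1.data, r2.data)

    def test_alpha_dominant_profile_peaks_in_alpha(self, small_connectome):
        prof = [{"alpha": 2.0}] * 6
        cfg = e.SimulationConfig(
            n_regions=6, duration_s=20.0, event_rate_hz=0.0,
            coupling_gain=0.0, noise_sd=0.0, seed=9,
        )
        rec, _ = e.simulate_recording(small_connectome, cfg, band_profile=prof)
        p = welch_band_power(rec.data[0][: int(10 * 250)], 250.0)
        assert np.argmax(p) == 1

    def test_unknown_gating_band_errors(self, small_connectome):
        cfg = e.SimulationConfig(n_regions=6, duration_s=12.0, seed=1)
        with pytest.raises(KeyError):
            e.simulate_recording(small_connectome, cfg, gating="target_power", gated_band="mu")

    def test_coupling_off_structure_errors(self, small_connectome):
        cfg = e.SimulationConfig(n_regions=6, duration_s=12.0, seed=1)
        bad = 1.0 - small_connectome.adjacency  # complement: off-edge gains
        with pytest.raises(ValueError):
            e.simulate_recording(small_connectome, cfg, coupling=bad)

    def test_causality_of_coupled_copy(self):
        # altering the source after time t must not change the target before t + delay
        adj = np.array([[0, 1], [1, 0]])
        cent = np.array([[0.0, 0, 0], [100.0, 0, 0]])  # 10 ms -> 2-3 samples
        conn = e.Connectome(adjacency=adj, centroids=cent)
        from ewcomm.synth import _delayed

        x = np.arange(10.0)
        d = 3
        out = _delayed(x, d)
        assert (out[:d] == 0).all()
        np.testing.assert_array_equal(out[d:], x[:-d])


class TestGradientFixture:
    def test_block_structure_and_unit_diagonal(self):
        fc, coords, labels = e.make_gradient_fixture(20, 2, seed=0)
        np.testing.assert_allclose(np.diag(fc), 1.0)
        np.testing.assert_allclose(fc, fc.T)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(20, dtype=bool)
        assert fc[same & off].mean() > fc[~same].mean() + 0.2

    def test_leading_eigenvector_separates_modules(self):
        fc, _, labels = e.make_gradient_fixture(30, 2, seed=1)
        w, v = np.linalg.eigh(fc)
        # second-largest eigenvector carries the module contrast
        vec = v[:, -2]
        signs = np.sign(vec)
        agree = max((signs == np.where(labels == 0, 1, -1)).mean(),
                    (signs == np.where(labels == 0, -1, 1)).mean())
        assert agree >= 0.95

    def test_determinism_and_errors(self):
        a = e.make_gradient_fixture(12, 3, seed=5)[0]
        b = e.make_gradient_fixture(12, 3, seed=5)[0]
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            e.make_gradient_fixture(4, 5)
        with pytest.raises(ValueError):
            e.make_gradient_fixture(4, 1)
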