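import numpy as np
import pytest

from critresp.connectome import (
    OCCIPITAL_SEED_LABEL,
    Connectome,
    delay_matrix,
    generate_synthetic_connectome,
    load_connectome,
    sample_natural_frequencies,
    save_connectome,
    select_local_targets,
)


class TestGenerator:
    def test_default_82(self, conn82):
        assert conn82.n_nodes == 82
        assert "lh.cuneus" in conn82.labels and "rh.thalamus" in conn82.labels
        assert len(set(conn82.labels)) == 82
        conn82.validate()  # symmetric, binary, connected, Euclidean-consistent

    def test_density_near_target(self, conn82):
        assert abs(conn82.edge_density - 0.27) < 0.05

    def test_occipital_set(self, conn82):
        seed_idx = conn82.labels.index(OCCIPITAL_SEED_LABEL)
        assert seed_idx in conn82.occipital_set
        assert 2 <= len(conn82.occipital_set) < 82
        assert np.all(conn82.distances[seed_idx, conn82.occipital_set] <= 50.0)

    def test_spatial_scale(self, conn82):
        assert np.isclose(conn82.distances.max(), 170.0)

    def test_deterministic(self):
        a = generate_synthetic_connectome(rng_seed=5)
        b = generate_synthetic_connectome(rng_seed=5)
        c = generate_synthetic_connectome(rng_seed=6)
        assert np.array_equal(a.adjacency, b.adjacency)
        assert np.allclose(a.coords, b.coords)
        assert not np.array_equal(a.adjacency, c.adjacency)

    def test_generic_sizes(self):
        conn = generate_synthetic_connectome(n_nodes=20, edge_density=0.4, rng_seed=1)
        assert conn.n_nodes == 20
        conn.validate()
        # The most posterior node doubles as the occipital seed.
        seed_idx = conn.labels.index(OCCIPITAL_SEED_LABEL)
        assert seed_idx == int(np.argmin(conn.coords[:, 1]))

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_synthetic_connectome(n_nodes=1)
        with pytest.raises(ValueError):
            generate_synthetic_connectome(edge_density=0.0)
        with pytest.raises(ValueError):
            generate_synthetic_connectome(edge_density=1.5)
        with pytest.raises(ValueError):
            # too sparse to ever be connected
            generate_synthetic_connectome(n_nodes=50, edge_density=0.01)


class TestValidate:
    def _base(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0]])
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(coords))
        a = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        return a, d, coords

    def test_asymmetric_rejected(self):
        a, d, coords = self._base()
        a[0, 1] = 0
        with pytest.raises(ValueError, match="asymmetric"):
            Connectome(a, d, ["a", "b", "c"], coords).validate()

    def test_nonbinary_rejected(self):
        a, d, coords = self._base()
        a[0, 1] = a[1, 0] = 2
        with pytest.raises(ValueError, match="not binary"):
            Connectome(a, d, ["a", "b", "c"], coords).validate()

    def test_disconnected_rejected(self):
        a, d, coords = self._base()
        a[:] = 0
        a[0, 1] = a[1, 0] = 1
        with pytest.raises(ValueError, match="disconnected"):
            Connectome(a, d, ["a", "b", "c"], coords).validate()

    def test_distance_mismatch_rejected(self):
        a, d, coords = self._base()
        d = d * 2.0
        with pytest.raises(ValueError, match="Euclidean"):
            Connectome(a, d, ["a", "b", "c"], coords).validate()


class TestIO:
    def test_round_trip(self, tmp_path, conn82):
        adj, coo = tmp_path / "adj.txt", tmp_path / "coords.tsv"
        save_connectome(conn82, adj, coo)
        loaded = load_connectome(adj, coords_path=coo)
        assert np.array_equal(loaded.adjacency, conn82.adjacency)
        assert np.allclose(loaded.distances, conn82.distances)
        assert loaded.labels == conn82.labels
        assert np.array_equal(loaded.occipital_set, conn82.occipital_set)

    def test_distances_override(self, tmp_path, conn82):
        adj, coo, dst = tmp_path / "adj.txt", tmp_path / "c.tsv", tmp_path / "d.txt"
        save_connectome(conn82, adj, coo)
        np.savetxt(dst, conn82.distances * 1.5)
        loaded = load_connectome(adj, coords_path=coo, distances_path=dst)
        assert np.allclose(loaded.distances, conn82.distances * 1.5)
        assert loaded.coords is None  # fiber lengths need not match Euclidean coords

    def test_requires_geometry(self, tmp_path, conn82):
        adj = tmp_path / "adj.txt"
        save_connectome(conn82, adj)
        with pytest.raises(ValueError, match="coords_path or distances_path"):
            load_connectome(adj)

    def test_rejects_nonsquare(self, tmp_path):
        p = tmp_path / "adj.txt"
        np.savetxt(p, np.zeros((2, 3)))
        with pytest.raises(ValueError, match="not square"):
            load_connectome(p, distances_path=p)


class TestDelays:
    def test_known_values(self):
        coords = np.array([[0.0, 0, 0], [7.0, 0, 0], [0, 21.0, 0]])
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(coords))
        a = np.ones((3, 3), dtype=np.int8) - np.eye(3, dtype=np.int8)
        conn = Connectome(a, d, ["a", "b", "c"], coords)
        tau = delay_matrix(conn, conduction_speed=7.0, dt=1e-3)
        assert tau[0, 1] == 1  # 7 mm / 7 m/s = 1 ms
        assert tau[0, 2] == 3  # 21 mm -> 3 ms
        assert np.all(np.diag(tau) == 0)
        assert np.array_equal(tau, tau.T)

    def test_half_step_ties_round_down(self):
        d = np.array([[0.0, 10.5], [10.5, 0.0]])
        a = np.array([[0, 1], [1, 0]], dtype=np.int8)
        conn = Connectome(a, d, ["a", "b"])
        tau = delay_matrix(conn, conduction_speed=7.0, dt=1e-3)
        assert tau[0, 1] == 1  # 1.5 ms ties toward zero

    def test_invalid(self, conn82):
        with pytest.raises(ValueError):
            delay_matrix(conn82, conduction_speed=0.0)
        with pytest.raises(ValueError):
            delay_matrix(conn82, dt=0.0)


class TestFrequencies:
    def test_distribution(self):
        w = sample_natural_frequencies(20000, mean_hz=10.0, sd_hz=0.5, rng_seed=0)
        f = w / (2 * np.pi)
        assert abs(f.mean() - 10.0) < 0.02
        assert abs(f.std() - 0.5) < 0.02

    def test_deterministic(self):
        assert np.array_equal(
            sample_natural_frequencies(10, rng_seed=4), sample_natural_frequencies(10, rng_seed=4)
        )

    def test_invalid(self):
        with pytest.raises(ValueError):
            sample_natural_frequencies(0)
        with pytest.raises(ValueError):
            sample_natural_frequencies(5, sd_hz=-1.0)


class TestLocalTargets:
    def test_matches_occipital_set(self, conn82):
        targets = select_local_targets(conn82, OCCIPITAL_SEED_LABEL, 50.0)
        assert np.array_equal(targets, conn82.occipital_set)

    def test_radius_zero_is_center_only(self, conn82):
        targets = select_local_targets(conn82, OCCIPITAL_SEED_LABEL, 0.0)
        assert np.array_equal(targets, [conn82.labels.index(OCCIPITAL_SEED_LABEL)])

    def test_unknown_label(self, conn82):
        with pytest.raises(KeyError):
            select_local_targets(conn82, "nonexistent", 50.0)
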