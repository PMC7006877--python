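import numpy as np
import pytest

from critresp.connectome import Connectome
from critresp.model import Trajectory
from critresp.response import (
    BaselineStats,
    PRMatrix,
    amplitude_response,
    baseline_stats,
    binarize_response,
    lz76,
    lzc_spatial,
    lzc_temporal,
    node_phase_sync,
    responsivity,
)


def _path3():
    # 3-node path graph a-b-c with simple geometry.
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)
    coords = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
    from scipy.spatial.distance import pdist, squareform

    return Connectome(a, squareform(pdist(coords)), ["a", "b", "c"], coords)


class TestNodeSync:
    def test_hand_computed(self):
        conn = _path3()
        theta = np.array([[0.0, np.pi / 2, np.pi]])
        traj = Trajectory(states=np.exp(1j * theta), dt=1e-3)
        sync = node_phase_sync(traj, conn)
        # node a: one neighbor (b) -> modulus 1; node b: neighbors a and c in
        # antiphase -> 0; node c: one neighbor -> 1.
        assert np.allclose(sync.values[0], [1.0, 0.0, 1.0], atol=1e-12)
        assert np.array_equal(sync.neighbor_counts, [1, 2, 1])

    def test_amplitude_invariance(self):
        # |S_j| depends only on phases, not on node amplitudes.
        conn = _path3()
        theta = np.random.default_rng(0).uniform(0, 2 * np.pi, (50, 3))
        amps = np.random.default_rng(1).uniform(0.2, 2.0, (50, 3))
        s1 = node_phase_sync(Trajectory(np.exp(1j * theta), 1e-3), conn)
        s2 = node_phase_sync(Trajectory(amps * np.exp(1j * theta), 1e-3), conn)
        assert np.allclose(s1.values, s2.values)

    def test_isolated_node_nan(self):
        a = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.int8)
        conn = Connectome(a, np.zeros((3, 3)), ["a", "b", "c"])
        traj = Trajectory(np.exp(1j * np.zeros((10, 3))), 1e-3)
        with pytest.warns(UserWarning, match="isolated"):
            sync = node_phase_sync(traj, conn)
        assert np.isnan(sync.values[:, 2]).all()
        assert np.isfinite(sync.values[:, :2]).all()


class TestBaseline:
    def test_gaussian_threshold(self):
        rng = np.random.default_rng(7)
        segments = [rng.normal(2.0, 0.5, (1000, 4)) for _ in range(10)]
        base = baseline_stats(segments, alpha=0.05)
        assert np.allclose(base.mean, 2.0, atol=0.05)
        assert np.allclose(base.sd, 0.5, atol=0.05)
        # Empirical 95% quantile of z-scores close to the Gaussian 1.645.
        assert np.allclose(base.threshold, 1.645, atol=0.1)
        assert base.n_samples == 10_000
        assert not base.degenerate.any()

    def test_gaussian_method(self):
        rng = np.random.default_rng(7)
        base = baseline_stats([rng.normal(0, 1, (200, 2))], alpha=0.05, method="gaussian")
        from scipy.stats import norm

        assert np.allclose(base.threshold, norm.ppf(0.95))

    def test_degenerate_column(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(0, 1, (200, 3))
        seg[:, 1] = 4.2
        base = baseline_stats([seg])
        assert base.degenerate[1] and not base.degenerate[0]
        pr = binarize_response(np.full((50, 3), 100.0), base)
        assert np.all(pr.values[1] == 0)  # degenerate node never responds
        assert np.all(pr.values[0] == 1)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 100"):
            baseline_stats([np.zeros((50, 2))])

    def test_invalid_alpha_and_method(self):
        seg = np.zeros((200, 2))
        with pytest.raises(ValueError):
            baseline_stats([seg], alpha=1.5)
        with pytest.raises(ValueError):
            baseline_stats([np.random.default_rng(0).normal(size=(200, 2))], method="bogus")


class TestBinarize:
    def _base(self):
        return BaselineStats(
            mean=np.zeros(2), sd=np.ones(2), threshold=np.full(2, 1.645),
            alpha=0.05, n_samples=1000, degenerate=np.zeros(2, dtype=bool),
        )

    def test_thresholding(self):
        vals = np.array([[0.0, 2.0], [1.7, 1.6], [-3.0, 5.0]])
        pr = binarize_response(vals, self._base())
        assert pr.values.shape == (2, 3)  # nodes x time
        assert np.array_equal(pr.values, [[0, 1, 0], [1, 0, 1]])

    def test_window_truncation(self):
        vals = np.zeros((100, 2))
        pr = binarize_response(vals, self._base(), window=0.05)
        assert pr.values.shape == (2, 50)
        with pytest.raises(ValueError, match="window"):
            binarize_response(vals, self._base(), window=0.2)

    def test_responsivity(self):
        pr = PRMatrix(values=np.array([[1, 1, 0, 0], [0, 0, 0, 0]], dtype=np.uint8))
        r_j, r_mean = responsivity(pr)
        assert np.allclose(r_j, [0.5, 0.0])
        assert r_mean == pytest.approx(0.25)
        with pytest.raises(ValueError):
            responsivity(PRMatrix(values=np.zeros((2, 0), dtype=np.uint8)))

    def test_amplitude_response_same_contract(self):
        vals = np.array([[0.0, 2.0], [1.7, 1.6]])
        assert np.array_equal(
            amplitude_response(vals, self._base()).values,
            binarize_response(vals, self._base()).values,
        )


class TestLZ76:
    def test_known_values(self):
        assert lz76("0") == 1
        assert lz76("1") == 1
        assert lz76("01") == 2
        assert lz76("0000") == 2  # "0" + reproducible tail
        assert lz76([0, 0, 0, 0]) == 2
        assert lz76("0001101001000101") == 6  # classic worked example

    def test_string_array_equivalence(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            bits = rng.integers(0, 2, rng.integers(1, 40))
            s = "".join(map(str, bits))
            assert lz76(s) == lz76(bits)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="non-binary"):
            lz76([0, 1, 2])
        with pytest.raises(ValueError):
            lz76("")

    def test_random_is_more_complex_than_periodic(self):
        rng = np.random.default_rng(0)
        rand = rng.integers(0, 2, 512)
        periodic = np.tile([0, 1], 256)
        assert lz76(rand) > lz76(periodic)


class TestLZc:
    def test_temporal_normalization(self):
        row = np.zeros(500, dtype=np.uint8)
        assert lzc_temporal(row) == pytest.approx(2 * np.log2(500) / 500)
        with pytest.raises(ValueError):
            lzc_temporal([0])

    def test_spatial_all_zero(self):
        pr = PRMatrix(values=np.zeros((82, 500), dtype=np.uint8))
        series, mean = lzc_spatial(pr)
        expected = 2 * np.log2(82) / 82
        assert series.shape == (500,)
        assert np.allclose(series, expected)
        assert mean == pytest.approx(expected)

    def test_spatial_random_near_one(self):
        rng = np.random.default_rng(5)
        pr = PRMatrix(values=rng.integers(0, 2, (82, 200)).astype(np.uint8))
        _, mean = lzc_spatial(pr)
        assert 0.6 < mean < 1.3

    def test_spatial_requires_nodes(self):
        with pytest.raises(ValueError):
            lzc_spatial(PRMatrix(values=np.zeros((1, 10), dtype=np.uint8)))
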