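import numpy as np
import pytest

from tepsim import (
    TEPData, bonferroni_adjust, cosine_similarity, lempel_ziv_complexity,
    match_individual_eigenmodes, network_average, pci, svd_eigenmodes,
    timewise_permutation_test,
)
from tepsim.errors import ParameterError


def _lz76_oracle(bits: str) -> int:
    """Brute-force exhaustive-history parser, written independently of the
    library implementation (explicit index-arithmetic substring search)."""
    n = len(bits)
    c, i = 0, 0
    while i < n:
        length = 1
        while i + length <= n:
            word = bits[i:i + length]
            prefix_end = i + length - 1
            found = False
            for start in range(prefix_end - length + 1):
                if all(bits[start + k] == word[k] for k in range(length)):
                    found = True
                    break
            if not found:
                break
            length += 1
        c += 1
        i += min(length, n - i)
    return c


class TestLempelZiv:
    def test_empty_sequence(self):
        assert lempel_ziv_complexity([]) == 0

    def test_constant_sequence_two_words(self):
        seq = "0000000000"
        assert lempel_ziv_complexity(seq) == _lz76_oracle(seq) == 2

    def test_exhaustive_length_12(self):
        """Exact match with the brute-force parser on all 2^12 strings."""
        for code in range(4096):
            bits = format(code, "012b")
            assert lempel_ziv_complexity(bits) == _lz76_oracle(bits), bits

    def test_subadditivity(self, rng):
        for _ in range(1000):
            n1, n2 = rng.integers(1, 30, size=2)
            s1 = "".join(rng.choice(["0", "1"], size=n1))
            s2 = "".join(rng.choice(["0", "1"], size=n2))
            assert lempel_ziv_complexity(s1 + s2) <= \
                lempel_ziv_complexity(s1) + lempel_ziv_complexity(s2)

    def test_non_binary_rejected(self):
        with pytest.raises(ParameterError):
            lempel_ziv_complexity([0, 1, 2])


def _pci_fixture(rng, kind: str, n_rows=12, n_base=100, n_resp=150):
    """Baseline noise plus a suprathreshold response block."""
    data = rng.normal(0, 0.1, size=(n_rows, n_base + n_resp))
    if kind == "constant":
        data[:6, n_base:] += 3.0
    elif kind == "random":
        data[:6, n_base:] += 3.0 * rng.choice([0.0, 1.0],
                                              size=(6, n_resp))
    time = np.arange(n_base + n_resp) - n_base
    return data, time


class TestPCI:
    def test_zero_response_gives_zero(self, rng):
        data = rng.normal(0, 0.1, size=(8, 200))
        data[:, 100:] = 0.0
        res = pci(data, np.arange(200) - 100.0, (-100, 0), (0, 100), seed=0)
        assert res.pci == 0.0
        assert res.n_significant_sources == 0

    def test_random_pattern_more_complex_than_constant(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d_const, t = _pci_fixture(rng, "constant")
            d_rand, _ = _pci_fixture(rng, "random")
            p_const = pci(d_const, t, (-100, 0), (0, 150), seed=seed)
            p_rand = pci(d_rand, t, (-100, 0), (0, 150), seed=seed)
            wins += p_rand.pci > p_const.pci
        assert wins == 20

    def test_row_duplication_changes_pci_little(self, rng):
        d, t = _pci_fixture(rng, "random")
        base = pci(d, t, (-100, 0), (0, 150), seed=5).pci
        dup = pci(np.vstack([d, d]), t, (-100, 0), (0, 150), seed=5).pci
        assert dup <= base * 1.05

    def test_row_permutation_changes_pci_below_ten_percent(self, rng):
        d, t = _pci_fixture(rng, "random")
        base = pci(d, t, (-100, 0), (0, 150), seed=5).pci
        perm = rng.permutation(d.shape[0])
        shuffled = pci(d[perm], t, (-100, 0), (0, 150), seed=5).pci
        assert abs(shuffled - base) < 0.10 * base

    def test_degenerate_baseline_rejected(self):
        data = np.zeros((4, 200))
        with pytest.raises(ParameterError):
            pci(data, np.arange(200) - 100.0, (-100, 0), (0, 100))


class TestSVD:
    def test_rank_one_single_mode(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=50)
        v -= v.mean()
        res = svd_eigenmodes(np.outer(u, v))
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_reconstruction_and_energy(self, rng):
        mat = rng.normal(size=(10, 50))
        res = svd_eigenmodes(mat)
        recon = res.spatial_modes @ np.diag(res.singular_values) \
            @ res.temporal_modes.T + res.channel_mean[:, None]
        np.testing.assert_allclose(recon, mat, atol=1e-9)
        centered = mat - mat.mean(axis=1, keepdims=True)
        assert np.sum(res.singular_values ** 2) == pytest.approx(
            np.sum(centered ** 2), abs=1e-9)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        ortho = res.spatial_modes.T @ res.spatial_modes
        np.testing.assert_allclose(ortho, np.eye(ortho.shape[0]), atol=1e-9)

    def test_variance_fractions_match_covariance_oracle(self, rng):
        mat = rng.normal(size=(10, 50))
        res = svd_eigenmodes(mat)
        centered = mat - mat.mean(axis=1, keepdims=True)
        eig = np.sort(np.linalg.eigvalsh(centered @ centered.T))[::-1]
        np.testing.assert_allclose(res.variance_explained,
                                   eig / eig.sum(), atol=1e-9)

    def test_peak_latency_uses_time_axis(self):
        t = np.linspace(-100, 300, 401)
        temporal = np.exp(-0.5 * ((t - 70) / 10) ** 2)
        mat = np.outer([1.0, -2.0, 0.5], temporal)
        res = svd_eigenmodes(mat, time=t)
        assert res.peak_latency[0] == pytest.approx(70.0, abs=1.0)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ParameterError):
            svd_eigenmodes(np.ones((4, 10)))


class TestModeMatch:
    def test_inserted_mode_found_at_correct_latency(self, rng):
        t = np.arange(-100.0, 300.0)
        mode = rng.normal(size=16)
        tep = np.zeros((16, t.size))
        tep[:, np.searchsorted(t, 70.0)] = 2.5 * mode
        res = match_individual_eigenmodes(tep, mode, time=t)
        assert res.latency == 70.0
        assert res.similarity == pytest.approx(1.0)
        assert res.amplitude == pytest.approx(2.5 * np.linalg.norm(mode))

    def test_orthogonal_pattern_flagged(self, rng):
        mode = np.zeros(10)
        mode[0] = 1.0
        tep = np.zeros((10, 50))
        tep[1] = rng.normal(size=50)
        res = match_individual_eigenmodes(tep, mode)
        assert abs(res.similarity) < 1e-9
        assert res.low_confidence

    def test_noisy_planted_latency_recovery(self):
        hits = 0
        t = np.arange(-100.0, 300.0)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mode = rng.normal(size=24)
            true_idx = np.searchsorted(t, 110.0)
            tep = rng.normal(0, 0.25, size=(24, t.size))
            bump = np.exp(-0.5 * ((np.arange(t.size) - true_idx) / 3.0) ** 2)
            tep += np.outer(mode, bump)
            res = match_individual_eigenmodes(tep, mode, time=t)
            hits += abs(res.latency - 110.0) <= 2.0
        assert hits == 20

    def test_zero_mode_rejected(self):
        with pytest.raises(ParameterError):
            match_individual_eigenmodes(np.ones((3, 5)), np.zeros(3))


def _tep(data, sfreq=1000.0):
    data = np.asarray(data, dtype=float)
    return TEPData(data=data, time=np.arange(data.shape[1], dtype=float),
                   sfreq=sfreq)


class TestPermutationTest:
    def test_identical_series(self, rng):
        x = rng.normal(size=(4, 120))
        res = timewise_permutation_test(_tep(x), _tep(x.copy()), n_perm=200,
                                        seed=0)
        np.testing.assert_allclose(res["r"], 1.0)
        np.testing.assert_allclose(res["p"], 1.0 / 201.0)
        assert res["significant"].all()

    def test_anticorrelated_series(self, rng):
        x = rng.normal(size=(3, 100))
        res = timewise_permutation_test(_tep(x), _tep(-x), n_perm=200, seed=0)
        np.testing.assert_allclose(res["r"], -1.0)
        assert (res["p"] > 0.9).all()

    def test_constant_channel_reported_missing(self, rng):
        x = rng.normal(size=(3, 80))
        y = x.copy()
        y[1] = 2.0
        res = timewise_permutation_test(_tep(x), _tep(y), n_perm=100, seed=0)
        assert np.isnan(res["r"][1]) and np.isnan(res["p"][1])
        assert np.isfinite(res["r"][[0, 2]]).all()

    def test_shape_mismatch(self, rng):
        with pytest.raises(ParameterError):
            timewise_permutation_test(_tep(rng.normal(size=(3, 10))),
                                      _tep(rng.normal(size=(3, 12))))


class TestCosine:
    def test_canonical_values(self):
        a = np.array([1.0, 0.0])
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, [0.0, 1.0]) == pytest.approx(0.0)
        assert cosine_similarity(a, -a) == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ParameterError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestNetworkAverage:
    def test_single_network_equals_grand_mean(self, rng):
        series = rng.normal(size=(5, 40))
        out = network_average(series, ["DMN"] * 5)
        np.testing.assert_allclose(out.loc["DMN"], series.mean(axis=0))

    def test_singleton_networks_identity(self, rng):
        series = rng.normal(size=(3, 10))
        out = network_average(series, ["a", "b", "c"])
        np.testing.assert_allclose(out.to_numpy(), series)

    def test_grouped_mean_oracle(self, rng):
        series = rng.normal(size=(20, 30))
        nets = list(rng.choice(["VISN", "SMN", "DAN"], size=20))
        out = network_average(series, nets)
        for net in set(nets):
            idx = [i for i, x in enumerate(nets) if x == net]
            np.testing.assert_allclose(out.loc[net],
                                       series[idx].mean(axis=0))

    def test_empty_network_is_missing(self, rng, caplog):
        series = rng.normal(size=(2, 5))
        out = network_average(series, ["SMN", "SMN"],
                              networks=["SMN", "DMN"])
        assert np.isnan(out.loc["DMN"]).all()


class TestBonferroni:
    def test_seven_tests_threshold(self):
        flags, thr = bonferroni_adjust([0.004, 0.01], n_tests=7)
        assert thr == pytest.approx(0.05 / 7)
        assert thr == pytest.approx(0.00714, abs=2e-5)
        np.testing.assert_array_equal(flags, [True, False])

    def test_single_test_unchanged(self):
        flags, thr = bonferroni_adjust([0.04], n_tests=1)
        assert thr == 0.05 and flags[0]

    def test_vector_matches_scalar_loop(self, rng):
        p = rng.random(50)
        flags, thr = bonferroni_adjust(p, n_tests=50)
        expected = [pv < 0.05 / 50 for pv in p]
        np.testing.assert_array_equal(flags, expected)
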