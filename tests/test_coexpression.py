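"""MAD selection, soft adjacency, TOM, module detection and eigengenes."""

import numpy as np
import pandas as pd
import pytest

from triohet import (
    TrioSimConfig,
    compute_fpkm,
    detect_modules,
    generate_trio_counts,
    module_eigengene,
    module_eigengenes,
    module_trait_correlation,
    select_top_mad,
    soft_adjacency,
    topological_overlap,
)


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the topological-overlap formula."""
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    tom = np.zeros_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_network(rng, n=8):
    x = rng.uniform(0, 1, size=(n, n))
    a = (x + x.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestSelectTopMad:
    def test_varying_beats_constant(self):
        mat = pd.DataFrame([[5.0] * 6, [1, 9, 1, 9, 1, 9]], index=["flat", "vary"])
        assert list(select_top_mad(mat, 1).index) == ["vary"]

    def test_identity_when_n_equals_genes(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(30, 8)))
        pd.testing.assert_frame_equal(select_top_mad(mat, 30), mat)

    def test_matches_bruteforce_sorted_mad(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(100, 12)), index=[f"g{i:03d}" for i in range(100)])
        kept = select_top_mad(mat, 40)
        mads = {g: np.median(np.abs(mat.loc[g] - np.median(mat.loc[g]))) for g in mat.index}
        expected = set(sorted(mat.index, key=lambda g: (-mads[g], g))[:40])
        assert set(kept.index) == expected

    def test_too_many_requested(self):
        with pytest.raises(ValueError):
            select_top_mad(pd.DataFrame(np.ones((3, 4))), 5)


class TestSoftAdjacency:
    def test_perfect_correlation_and_closed_form(self):
        s = np.linspace(0, 1, 10)
        mat = pd.DataFrame([s, 2 * s + 1], index=["a", "b"])
        net = soft_adjacency(mat, power=20)
        assert net.adjacency[0, 1] == pytest.approx(1.0)
        # |cor|=0.9 at power 20 -> 0.9^20
        assert 0.9**20 == pytest.approx(0.121576654, abs=1e-8)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.normal(size=(10, 12)))
        perm = rng.permutation(12)
        a1 = soft_adjacency(mat, 6).adjacency
        a2 = soft_adjacency(mat.iloc[:, perm], 6).adjacency
        np.testing.assert_allclose(a1, a2, atol=1e-12)

    def test_zero_variance_gene_warns_and_zeroes(self):
        mat = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [0, 1, 2, 3]], index=["flat", "v"])
        with pytest.warns(UserWarning):
            net = soft_adjacency(mat, 2)
        assert net.adjacency[0, 1] == 0.0
        assert net.adjacency[0, 0] == 1.0

    def test_bounds_and_symmetry_random(self):
        rng = np.random.default_rng(3)
        net = soft_adjacency(pd.DataFrame(rng.normal(size=(15, 9))), 7)
        a = net.adjacency
        assert ((a >= 0) & (a <= 1)).all()
        np.testing.assert_allclose(a, a.T)
        np.testing.assert_allclose(np.diag(a), 1.0)


class TestTopologicalOverlap:
    def test_two_gene_closed_form(self):
        from triohet.coexpression import Network

        for aval in (0.2, 0.7, 0.95):
            a = np.array([[1.0, aval], [aval, 1.0]])
            net = topological_overlap(Network(pd.Index(["x", "y"]), a, 1))
            assert net.tom[0, 1] == pytest.approx(aval, abs=1e-12)

    def test_identity_adjacency(self):
        from triohet.coexpression import Network

        net = topological_overlap(Network(pd.Index(range(5)), np.eye(5), 1))
        assert np.allclose(net.tom, np.eye(5))

    def test_matches_bruteforce_oracle(self):
        from triohet.coexpression import Network

        rng = np.random.default_rng(4)
        for _ in range(3):
            a = random_network(rng)
            net = topological_overlap(Network(pd.Index(range(8)), a, 1))
            np.testing.assert_allclose(net.tom, brute_force_tom(a), atol=1e-12)

    def test_bounds_on_random_adjacency(self):
        from triohet.coexpression import Network

        rng = np.random.default_rng(5)
        a = random_network(rng, 20)
        tom = topological_overlap(Network(pd.Index(range(20)), a, 1)).tom
        assert ((tom >= 0) & (tom <= 1 + 1e-12)).all()
        np.testing.assert_allclose(tom, tom.T)


class TestDetectModules:
    def _planted(self, seed=0):
        cfg = TrioSimConfig(
            n_genes=300, seed=seed, effect_scale=0.05,
            module_spec=((50, 0.9), (50, 0.9)),
        )
        cm, design, truth = generate_trio_counts(cfg)
        lexpr = np.log2(compute_fpkm(cm) + 1)
        return lexpr, truth

    def test_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        lexpr, truth = self._planted()
        net = topological_overlap(soft_adjacency(lexpr, 20))
        labels = detect_modules(net.dissimilarity, lexpr.index, min_module_size=30)
        mask = truth.module != "none"
        assert adjusted_rand_score(truth.module[mask], labels[mask]) == 1.0
        assert len(set(labels) - {"grey"}) == 2

    def test_min_size_larger_than_n_all_grey(self):
        rng = np.random.default_rng(6)
        d = 1 - np.abs(np.corrcoef(rng.normal(size=(20, 10))))
        labels = detect_modules(d, [f"g{i}" for i in range(20)], min_module_size=50)
        assert set(labels) == {"grey"}

    def test_gene_order_permutation_invariance(self):
        lexpr, _ = self._planted(seed=1)
        net = topological_overlap(soft_adjacency(lexpr, 20))
        labels = detect_modules(net.dissimilarity, lexpr.index, 30)
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(lexpr))
        shuffled = lexpr.iloc[perm]
        net2 = topological_overlap(soft_adjacency(shuffled, 20))
        labels2 = detect_modules(net2.dissimilarity, shuffled.index, 30)
        # same partition: co-membership preserved for a sample of pairs
        idx = lexpr.index[:60]
        for g in idx[1:]:
            same1 = labels[g] == labels[idx[0]]
            same2 = labels2[g] == labels2[idx[0]]
            assert same1 == same2


class TestEigengene:
    def test_identical_profiles(self):
        s = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        mat = pd.DataFrame([s, s, s], columns=[f"c{i}" for i in range(5)])
        eig = module_eigengene(mat)
        z = (s - s.mean()) / s.std()
        np.testing.assert_allclose(eig.to_numpy() * np.linalg.norm(z) / np.linalg.norm(eig), z, atol=1e-9)
        assert np.corrcoef(eig, z)[0, 1] > 0.999

    def test_rank_one_recovery(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=12)
        w = rng.uniform(0.5, 2.0, size=15)
        mat = pd.DataFrame(np.outer(w, s), columns=[f"c{i}" for i in range(12)])
        eig = module_eigengene(mat)
        assert abs(np.corrcoef(eig, s)[0, 1]) > 0.999999

    def test_power_iteration_oracle(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.normal(size=(20, 10)))
        z = mat.sub(mat.mean(axis=1), axis=0).div(mat.std(axis=1), axis=0).to_numpy()
        # power iteration on z^T z for the leading sample-space eigenvector
        v = rng.normal(size=10)
        for _ in range(500):
            v = z.T @ (z @ v)
            v /= np.linalg.norm(v)
        eig = module_eigengene(mat).to_numpy()
        assert abs(np.corrcoef(eig, v)[0, 1]) > 0.9999

    def test_single_gene_module(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        eig = module_eigengene(mat)
        np.testing.assert_allclose(eig.mean(), 0.0, atol=1e-12)


class TestModuleTraitCorrelation:
    def _eigs(self):
        rng = np.random.default_rng(10)
        samples = [f"s{i}" for i in range(36)]
        return pd.DataFrame(rng.normal(size=(36, 3)), index=samples, columns=["M1", "M2", "M3"])

    def test_trait_equal_to_eigengene(self):
        mes = self._eigs()
        traits = pd.DataFrame({"t": mes["M1"]})
        r, p = module_trait_correlation(mes, traits)
        assert r.loc["M1", "t"] == pytest.approx(1.0)
        assert p.loc["M1", "t"] < 1e-20

    def test_planted_negative_trait(self):
        rng = np.random.default_rng(11)
        mes = self._eigs()
        traits = pd.DataFrame({"t": -mes["M2"] + 0.1 * rng.normal(size=36)}, index=mes.index)
        r, _ = module_trait_correlation(mes, traits)
        assert r["t"].idxmin() == "M2"
        assert r.loc["M2", "t"] < -0.9

    def test_constant_trait_contract(self):
        mes = self._eigs()
        traits = pd.DataFrame({"t": np.ones(36)}, index=mes.index)
        with pytest.warns(UserWarning):
            r, p = module_trait_correlation(mes, traits)
        assert (r["t"] == 0).all() and (p["t"] == 1).all()

    def test_misaligned_samples_error(self):
        mes = self._eigs()
        traits = pd.DataFrame({"t": np.arange(36)}, index=[f"x{i}" for i in range(36)])
        with pytest.raises(ValueError):
            module_trait_correlation(mes, traits)


def test_pipeline_determinism():
    """Identical input matrices give identical module labels."""
    cfg = TrioSimConfig(n_genes=200, seed=12, effect_scale=0.05, module_spec=((40, 0.85),))
    cm, design, truth = generate_trio_counts(cfg)
    lexpr = np.log2(compute_fpkm(cm) + 1)

    def run():
        net = topological_overlap(soft_adjacency(lexpr, 20))
        return detect_modules(net.dissimilarity, lexpr.index, 20)

    pd.testing.assert_series_equal(run(), run())


def test_module_eigengenes_matrix(trio_dataset):
    cm, design, truth = trio_dataset
    lexpr = np.log2(compute_fpkm(cm) + 1)
    labels = pd.Series("M1", index=lexpr.index)
    labels.iloc[: len(labels) // 2] = "M2"
    mes = module_eigengenes(lexpr, labels)
    assert list(mes.columns) == ["M1", "M2"]
    assert mes.index.equals(lexpr.columns)
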