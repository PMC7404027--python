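"""Adjacency, TOM, tree cut, eigengenes, merging, kME and correlation reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chillnet as cn
from chillnet.network import UNASSIGNED, eigengene_matrix


def frame(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=labels, columns=cols)


def random_adjacency(rng, n):
    r = rng.uniform(0, 1, (n, n))
    a = (r + r.T) / 2
    np.fill_diagonal(a, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=genes, columns=genes)


def tom_bruteforce(a):
    """O(n^3) topological overlap straight from the definition."""
    n = a.shape[0]
    out = np.eye(n)
    k = a.sum(axis=1) - 1.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return out


class TestAdjacency:
    def test_perfect_correlation_any_power(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = frame([x, 2 * x + 1])
        for beta in (1, 6, 12):
            adj = cn.soft_adjacency(m, beta=beta)
            assert adj.iloc[0, 1] == pytest.approx(1.0)

    def test_power_attenuation(self):
        # r = 0.5 at beta 12 -> 0.5^12
        x = np.array([1.0, -1.0, 1.0, -1.0, 0, 0, 0, 0])
        y = np.array([1.0, -1.0, 0, 0, 1.0, -1.0, 0, 0])  # cor exactly 0.5
        adj = cn.soft_adjacency(frame([x, y]), beta=12)
        assert adj.iloc[0, 1] == pytest.approx(0.5 ** 12, abs=1e-15)

    def test_beta_one_is_abs_correlation(self):
        rng = np.random.default_rng(0)
        m = frame(rng.normal(size=(6, 10)))
        adj = cn.soft_adjacency(m, beta=1)
        r = np.corrcoef(m.to_numpy())
        np.testing.assert_allclose(adj.to_numpy(), np.abs(r), atol=1e-12)

    def test_zero_variance_gene_flagged_zero(self):
        m = frame([[1, 1, 1, 1], [1, 2, 3, 4], [4, 1, 2, 2]])
        adj = cn.soft_adjacency(m, beta=2)
        assert adj.iloc[0, 1] == 0.0 and adj.iloc[0, 0] == 1.0


class TestTOM:
    def test_complete_graph(self):
        a = random_adjacency(np.random.default_rng(0), 3)
        a.iloc[:, :] = 1.0
        assert (cn.tom(a).to_numpy() == 1.0).all()

    def test_empty_graph(self):
        genes = list("abc")
        a = pd.DataFrame(np.eye(3), index=genes, columns=genes)
        t = cn.tom(a).to_numpy()
        assert (t[~np.eye(3, dtype=bool)] == 0.0).all()

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        a = random_adjacency(rng, 12)
        np.testing.assert_allclose(
            cn.tom(a).to_numpy(), tom_bruteforce(a.to_numpy()), atol=1e-12)

    def test_asymmetric_rejected(self):
        a = random_adjacency(np.random.default_rng(1), 4)
        a.iloc[0, 1] += 0.2
        with pytest.raises(ValueError):
            cn.tom(a)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounds_on_random_adjacency(self, seed):
        a = random_adjacency(np.random.default_rng(seed), 10)
        t = cn.tom(a).to_numpy()
        assert (t >= 0).all() and (t <= 1 + 1e-12).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        a = random_adjacency(rng, 8)
        perm = rng.permutation(8)
        genes = [a.index[i] for i in perm]
        t = cn.tom(a)
        t_perm = cn.tom(a.loc[genes, genes])
        np.testing.assert_allclose(
            t_perm.to_numpy(), t.loc[genes, genes].to_numpy(), atol=1e-12)


def planted_tom(n_blocks=2, size=60, inside=0.8, outside=0.05):
    n = n_blocks * size
    t = np.full((n, n), outside)
    for b in range(n_blocks):
        sl = slice(b * size, (b + 1) * size)
        t[sl, sl] = inside
    np.fill_diagonal(t, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(t, index=genes, columns=genes)


class TestDetectModules:
    def test_two_planted_blocks(self):
        part = cn.detect_modules(planted_tom(), min_module_size=50)
        assert len(part.modules) == 2
        assert (part.labels != UNASSIGNED).all()
        # block membership preserved
        first = part.labels.iloc[:60]
        assert first.nunique() == 1

    def test_too_few_genes_all_unassigned(self):
        part = cn.detect_modules(planted_tom(1, 30), min_module_size=50)
        assert (part.labels == UNASSIGNED).all()

    def test_identical_rows_single_module(self):
        t = planted_tom(1, 60, inside=1.0)
        t.iloc[:, :] = 1.0
        part = cn.detect_modules(t, min_module_size=50)
        assert len(part.modules) == 1

    def test_newick_export_parses(self):
        part = cn.detect_modules(planted_tom(2, 30), min_module_size=10)
        nwk = part.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 59


class TestEigengene:
    def test_identical_profiles_variance_one(self):
        x = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
        m = frame([x, x, x])
        e, varexp = cn.eigengene(m, m.index)
        assert varexp == pytest.approx(1.0)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(e.to_numpy(), z / np.linalg.norm(z), atol=1e-12)

    def test_sign_contract_never_anticorrelated(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = frame(rng.normal(size=(8, 6)))
            e, _ = cn.eigengene(m, m.index)
            zm = ((m.T - m.mean(axis=1)) / m.std(axis=1)).T.mean(axis=0)
            assert float(np.dot(e, zm)) >= -1e-12

    def test_matches_independent_pca(self):
        """First PC from the eigendecomposition of the sample covariance."""
        rng = np.random.default_rng(11)
        base = rng.normal(size=12)
        m = frame(base + rng.normal(0, 0.3, size=(20, 12)))
        e, varexp = cn.eigengene(m, m.index)
        z = ((m.T - m.mean(axis=1)) / m.std(axis=1)).T.to_numpy()
        evals, evecs = np.linalg.eigh(z.T @ z)
        lead = evecs[:, -1]
        if np.dot(lead, z.mean(axis=0)) < 0:
            lead = -lead
        np.testing.assert_allclose(e.to_numpy(), lead, atol=1e-9)
        assert varexp == pytest.approx(evals[-1] / evals.sum(), abs=1e-9)

    def test_unit_norm(self, fitted):
        _, res = fitted
        norms = np.linalg.norm(res.eigengenes.to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)


class TestMerge:
    def _partition(self, labels, genes):
        return cn.ModulePartition(pd.Series(labels, index=genes), min_module_size=2)

    def _matrix_with_eigcor(self, r):
        """Two 3-gene modules whose eigengene correlation is ~r."""
        rng = np.random.default_rng(0)
        n = 12
        e1 = rng.normal(size=n)
        e1 = (e1 - e1.mean()) / e1.std()
        raw = rng.normal(size=n)
        raw = raw - raw.mean()
        raw -= (raw @ e1) / (e1 @ e1) * e1
        e2 = r * e1 + np.sqrt(max(1 - r * r, 0)) * raw / raw.std()
        rows = [e1, e1, e1, e2, e2, e2]
        genes = [f"g{i}" for i in range(6)]
        m = frame(rows, labels=genes)
        part = self._partition(["A"] * 3 + ["B"] * 3, genes)
        return m, part

    def test_high_correlation_merges(self):
        m, part = self._matrix_with_eigcor(0.9)
        merged, eig = cn.merge_modules(m, part, cut_height=0.75)
        assert len(merged.modules) == 1

    def test_anticorrelated_never_merges(self):
        m, part = self._matrix_with_eigcor(-1.0)
        merged, _ = cn.merge_modules(m, part, cut_height=0.75)
        assert len(merged.modules) == 2

    def test_boundary_is_strict(self):
        """Eigengene dissimilarity exactly at the cut is NOT merged."""
        n = 12
        rng = np.random.default_rng(1)
        e1 = rng.normal(size=n)
        e1 = (e1 - e1.mean()) / e1.std()
        raw = rng.normal(size=n)
        raw = raw - raw.mean()
        raw -= (raw @ e1) / (e1 @ e1) * e1
        raw /= raw.std()
        e2 = 0.25 * e1 + np.sqrt(1 - 0.25 ** 2) * raw
        m = frame([e1, e1, e1, e2, e2, e2])
        part = self._partition(["A"] * 3 + ["B"] * 3, list(m.index))
        diss = 1 - np.corrcoef(e1, e2)[0, 1]
        merged, _ = cn.merge_modules(m, part, cut_height=diss)
        assert len(merged.modules) == 2


class TestKme:
    def test_identity_and_orthogonal(self):
        e = np.array([1.0, -1.0, 1.0, -1.0, 0.0])
        orth = np.array([1.0, 1.0, -1.0, -1.0, 0.0])
        m = frame([e, orth])
        eig = frame([e], labels=["M1"])
        k = cn.kme(m, eig)
        assert k.loc["g0", "M1"] == pytest.approx(1.0)
        assert k.loc["g1", "M1"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_pearson(self):
        g = np.array([2.0, 4.0, 4.0, 7.0, 9.0])
        e = np.array([1.0, 3.0, 2.0, 6.0, 7.0])
        k = cn.kme(frame([g]), frame([e], labels=["M1"]))
        expected = (((g - g.mean()) * (e - e.mean())).sum()
                    / np.sqrt(((g - g.mean()) ** 2).sum() * ((e - e.mean()) ** 2).sum()))
        assert k.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_flagged(self):
        k = cn.kme(frame([[1.0, 1.0, 1.0, 1.0, 1.0]]),
                   frame([[1.0, 2.0, 3.0, 4.0, 5.0]], labels=["M1"]))
        assert np.isnan(k.iloc[0, 0])


class TestModuleCorrelations:
    def test_r_zero_gives_p_one(self):
        assert cn.correlation_pvalue(0.0, 18) == pytest.approx(1.0)

    def test_report_shape_and_bounds(self, fitted, bundle):
        _, res = fitted
        _, design, truth = bundle
        rep = res.module_sample_correlations()
        assert set(rep["target"]) == set(design.stages)
        assert rep["r"].abs().max() <= 1.0
        assert ((rep["p"] > 0) & (rep["p"] <= 1)).all()
        assert (rep["n"] == 18).all()

    def test_planted_stage_has_top_correlation(self, fitted, bundle):
        """Each detected module correlates most with its planted peak stage."""
        _, res = fitted
        _, _, truth = bundle
        rep = res.module_sample_correlations()
        peak = res.preponderant_stages()
        for module in res.eigengenes.index:
            sub = rep[rep["module"] == module].set_index("target")
            assert sub["r"].idxmax() == peak[module]
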