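import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import primary_probes
from hybcoex.io_core import ExpressionMatrix, NetworkParams
from hybcoex.network import (
    average_linkage_cluster,
    connectivity_filter,
    consensus_tom,
    dynamic_tree_cut,
    eigengene_matrix,
    kme,
    merge_close_modules,
    module_eigengene,
    module_trait_correlation,
    pearson_matrix,
    pick_soft_threshold,
    relabel_by_size,
    signed_adjacency,
    tom_from_adjacency,
)


def _matrix(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=samples), "log2"
    )


def _random_adjacency(n, rng):
    A = rng.uniform(0, 1, (n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return A


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "cor,beta,expected", [(1.0, 5, 1.0), (-1.0, 5, 0.0), (0.0, 5, 0.03125)]
    )
    def test_closed_form(self, cor, beta, expected):
        C = np.array([[1.0, cor], [cor, 1.0]])
        A = signed_adjacency(C, beta)
        assert A[0, 1] == pytest.approx(expected, abs=1e-15)
        assert A[0, 0] == 1.0

    def test_entries_in_unit_interval(self, rng):
        C = np.clip(rng.uniform(-1, 1, (10, 10)), -1, 1)
        C = (C + C.T) / 2
        A = signed_adjacency(C, 7)
        assert ((A >= 0) & (A <= 1)).all()


class TestTOM:
    def test_perfect_clique(self):
        A = np.ones((3, 3))
        tom = tom_from_adjacency(A)
        # TOM_12 = (L + a) / (min(k) + 1 - a) = (1 + 1) / (2 + 1 - 1) = 1
        np.testing.assert_allclose(tom, 1.0)

    def test_empty_network(self):
        A = np.eye(4)
        tom = tom_from_adjacency(A)
        assert (tom[~np.eye(4, dtype=bool)] == 0).all()
        assert (np.diag(tom) == 1).all()

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            A = _random_adjacency(6, rng)
            tom = tom_from_adjacency(A)
            n = 6
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    L = sum(
                        A[i, u] * A[u, j] for u in range(n) if u not in (i, j)
                    )
                    k_i = sum(A[i, u] for u in range(n) if u != i)
                    k_j = sum(A[j, u] for u in range(n) if u != j)
                    expect = (L + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
                    assert tom[i, j] == pytest.approx(expect, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 12))
    def test_entries_bounded_and_symmetric(self, seed, n):
        A = _random_adjacency(n, np.random.default_rng(seed))
        tom = tom_from_adjacency(A)
        assert ((tom >= 0) & (tom <= 1)).all()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(tom), 1.0)


class TestConsensusTOM:
    def test_identical_inputs_are_fixed_point(self, rng):
        tom = tom_from_adjacency(_random_adjacency(8, rng))
        cons = consensus_tom({"a": tom, "b": tom.copy()})
        np.testing.assert_allclose(cons, tom, atol=1e-12)

    def test_zero_population_forces_zero_consensus(self, rng):
        tom = tom_from_adjacency(_random_adjacency(8, rng))
        zero = np.eye(8)
        cons = consensus_tom({"a": tom, "b": zero})
        off = ~np.eye(8, dtype=bool)
        assert (cons[off] == 0).all()

    def test_consensus_below_each_calibrated_input(self, rng):
        t1 = tom_from_adjacency(_random_adjacency(10, rng))
        t2 = tom_from_adjacency(_random_adjacency(10, rng))
        q = 0.95
        cons = consensus_tom({"a": t1, "b": t2}, q)
        iu = np.triu_indices(10, 1)
        target = np.mean([np.quantile(t1[iu], q), np.quantile(t2[iu], q)])
        for t in (t1, t2):
            cal = np.clip(t * target / np.quantile(t[iu], q), 0, 1)
            assert (cons[iu] <= cal[iu] + 1e-12).all()


class TestConnectivityFilter:
    def test_matches_brute_force_rule(self, rng):
        vals = rng.normal(size=(20, 30))
        m = _matrix(vals)
        kept = connectivity_filter(m, beta=5)
        C = np.corrcoef(vals)
        A = ((1 + C) / 2) ** 5
        k = A.sum(axis=1) - np.diag(A)
        expect = [f"p{i}" for i in range(20) if k[i] > np.median(k)]
        assert kept == expect

    def test_all_equal_connectivity_keeps_nothing(self):
        # x, y, -x, -y with x orthogonal to y: every probe has connectivity
        # exactly 2 * (1/2)^beta, so nothing is strictly above the median
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        m = _matrix(np.vstack([x, y, -x, -y]))
        assert connectivity_filter(m, beta=5) == []


class TestSoftThreshold:
    def test_median_connectivity_nonincreasing_in_beta(self, rng):
        C = pearson_matrix(rng.normal(size=(40, 25)))
        table = pick_soft_threshold(C, candidate_betas=list(range(1, 10)))
        assert (np.diff(table["median_k"]) <= 1e-9).all()

    def test_zero_correlation_closed_form(self):
        n = 12
        C = np.eye(n)
        table = pick_soft_threshold(C, candidate_betas=[2, 4])
        for _, row in table.iterrows():
            assert row["median_k"] == pytest.approx(
                (n - 1) * 0.5 ** row["beta"], abs=1e-12
            )

    def test_recommendation_reproduces_plateau_rule(self, rng):
        C = pearson_matrix(rng.normal(size=(60, 40)))
        betas = list(range(1, 13))
        table = pick_soft_threshold(C, candidate_betas=betas, plateau_rtol=0.05)
        med = table["median_k"].to_numpy()
        expect = len(betas) - 1
        for i in range(len(betas) - 1):
            if med[i] <= 0 or abs(med[i + 1] - med[i]) / med[i] < 0.05:
                expect = i
                break
        assert table.index[table["recommended"]][0] == expect


class TestUPGMA:
    def test_three_points_with_tie(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        Z = average_linkage_cluster(D)
        assert Z[0, 2] == pytest.approx(1.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # lowest pair on ties

    def test_identical_rows_merge_at_zero(self):
        D = np.array(
            [[0, 0, 5], [0, 0, 5], [5, 5, 0]], dtype=float
        )
        Z = average_linkage_cluster(D)
        assert Z[0, 2] == 0.0

    def test_matches_naive_upgma_oracle(self, rng):
        # O(n^3) literal UPGMA with distinct distances (no tie ambiguity)
        n = 8
        vals = rng.normal(size=(n, 5))
        D = np.sqrt(((vals[:, None] - vals[None]) ** 2).sum(-1))

        clusters = {i: [i] for i in range(n)}
        D_work = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
        heights = []
        next_id = n
        while len(clusters) > 1:
            (a, b), h = min(D_work.items(), key=lambda kv: kv[1])
            heights.append(h)
            merged = clusters.pop(a) + clusters.pop(b)
            for c in list(clusters):
                d_new = np.mean([D[i, j] for i in merged for j in clusters[c]])
                D_work[tuple(sorted((next_id, c)))] = d_new
            D_work = {k: v for k, v in D_work.items()
                      if a not in k and b not in k}
            clusters[next_id] = merged
            next_id += 1

        Z = average_linkage_cluster(D)
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(heights), atol=1e-10)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            average_linkage_cluster(D)


class TestDynamicTreeCut:
    def _blocks(self, sizes, within, between, rng):
        n = sum(sizes)
        D = np.full((n, n), between)
        start = 0
        labels = np.zeros(n, dtype=int)
        for k, sz in enumerate(sizes):
            D[start:start + sz, start:start + sz] = within
            labels[start:start + sz] = k
            start += sz
        D += rng.uniform(0, 0.02, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        return D, labels

    def test_two_well_separated_blocks(self, rng):
        D, truth = self._blocks([60, 60], 0.1, 0.9, rng)
        Z = average_linkage_cluster(D)
        labels = dynamic_tree_cut(Z, D, deep_split=0, min_module_size=50)
        assert set(labels) == {1, 2}
        assert (pd.Series(labels).groupby(truth).nunique() == 1).all()

    def test_single_small_block_all_unassigned(self, rng):
        D, _ = self._blocks([30], 0.1, 0.9, rng)
        Z = average_linkage_cluster(D)
        labels = dynamic_tree_cut(Z, D, deep_split=0, min_module_size=50)
        assert (labels == 0).all()

    def test_min_size_larger_than_n(self, rng):
        D, _ = self._blocks([10], 0.1, 0.9, rng)
        Z = average_linkage_cluster(D)
        assert (dynamic_tree_cut(Z, D, 0, 99) == 0).all()

    def test_five_planted_modules_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        D, truth = self._blocks([90, 80, 70, 65, 60], 0.2, 0.9, rng)
        Z = average_linkage_cluster(D)
        labels = dynamic_tree_cut(Z, D, deep_split=0, min_module_size=50)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_labels_ordered_by_size(self, rng):
        D, _ = self._blocks([60, 90, 75], 0.15, 0.9, rng)
        Z = average_linkage_cluster(D)
        labels = dynamic_tree_cut(Z, D, 0, 50)
        sizes = pd.Series(labels[labels > 0]).value_counts()
        assert list(sizes.index) == sorted(sizes.index)
        assert (np.diff(sizes.reindex(sorted(sizes.index))) <= 0).all()


class TestEigengene:
    def test_identical_profiles(self, rng):
        profile = rng.normal(size=10)
        vals = np.vstack([profile, profile * 2 + 1])
        me, pve = module_eigengene(vals, np.array([0, 1]))
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(me, z, atol=1e-8)
        assert pve == pytest.approx(1.0, abs=1e-12)

    def test_sign_symmetric_pair(self, rng):
        profile = rng.normal(size=12)
        vals = np.vstack([profile, -profile])
        me, pve = module_eigengene(vals, np.array([0, 1]))
        assert pve == pytest.approx(1.0, abs=1e-12)
        kmes = np.array([np.corrcoef(v, me)[0, 1] for v in vals])
        assert kmes.mean() >= 0

    def test_matches_dense_svd(self, rng):
        vals = rng.normal(size=(30, 15))
        vals += rng.normal(size=15) * 2  # shared component
        me, _ = module_eigengene(vals, np.arange(30))
        Z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        ref = Vt[0] / Vt[0].std(ddof=1)
        err = min(np.abs(me - ref).max(), np.abs(me + ref).max())
        assert err < 1e-8

    def test_unit_variance(self, rng):
        me, _ = module_eigengene(rng.normal(size=(8, 20)), np.arange(8))
        assert me.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestKME:
    def test_probe_equal_to_eigengene(self, rng):
        me = rng.normal(size=25)
        vals = np.vstack([me, -me, rng.normal(size=25)])
        m = _matrix(vals)
        mes = pd.DataFrame({"ME1": me}, index=m.sample_ids)
        out = kme(m, mes)
        assert out.loc["p0", "ME1"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc["p1", "ME1"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula(self, rng):
        vals = rng.normal(size=(6, 30))
        me = rng.normal(size=30)
        m = _matrix(vals)
        out = kme(m, pd.DataFrame({"ME1": me}, index=m.sample_ids))
        for i in range(6):
            x, y = vals[i], me
            expect = (
                ((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            assert out.iloc[i, 0] == pytest.approx(expect, abs=1e-12)


class TestMergeCloseModules:
    def _dataset(self, rng, cor_factors):
        """Three 20-probe modules driven by factors with given correlation."""
        n = 60
        L = np.linalg.cholesky(cor_factors + 1e-9 * np.eye(3))
        f = (L @ rng.normal(size=(3, n)))
        vals = np.vstack(
            [f[k] * 0.95 + rng.normal(0, 0.3, (20, n)) for k in range(3)]
        )
        m = _matrix(vals)
        assignment = pd.Series(
            [1] * 20 + [2] * 20 + [3] * 20, index=m.probe_ids
        )
        return m, assignment

    def test_identical_modules_merged(self, rng):
        cor = np.array([[1, 0.999, 0], [0.999, 1, 0], [0, 0, 1]], dtype=float)
        m, assignment = self._dataset(rng, cor)
        merged = merge_close_modules({"a": m, "b": m}, assignment, 0.2)
        assert merged.nunique() == 2  # modules 1 and 2 collapse

    def test_max_rule_blocks_one_sided_merge(self, rng):
        close = np.array([[1, 0.95, 0], [0.95, 1, 0], [0, 0, 1]], dtype=float)
        far = np.array([[1, 0.3, 0], [0.3, 1, 0], [0, 0, 1]], dtype=float)
        m1, assignment = self._dataset(rng, close)
        m2, _ = self._dataset(np.random.default_rng(5), far)
        merged = merge_close_modules({"a": m1, "b": m2}, assignment, 0.2)
        assert merged.nunique() == 3  # consensus diss = max > threshold

    def test_matches_direct_iteration(self, rng):
        cor = np.array([[1, 0.97, 0.2], [0.97, 1, 0.2], [0.2, 0.2, 1]])
        m, assignment = self._dataset(rng, cor)
        merged = merge_close_modules({"a": m}, assignment, 0.2)
        # direct check: eigengene correlation of planted modules 1 and 2
        mes, _ = eigengene_matrix(m, assignment)
        diss = 1 - np.corrcoef(mes.to_numpy().T)
        assert diss[0, 1] <= 0.2  # so they must merge
        assert merged[assignment == 1].iloc[0] == merged[assignment == 2].iloc[0]
        assert merged.nunique() == 2


class TestModuleTraitCorrelation:
    def test_me_equal_to_trait(self, rng):
        me = rng.normal(size=30)
        mes = pd.DataFrame({"ME1": me}, index=[f"s{i}" for i in range(30)])
        traits = pd.DataFrame({"t": me}, index=mes.index)
        row = module_trait_correlation(mes, traits).iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-12)
        assert row["p"] < 1e-20

    def test_t_statistic_closed_form(self):
        # r = 0.5, n = 27 -> t = 0.5 * sqrt(25 / 0.75) = 2.887
        from scipy import stats as sps

        r, n = 0.5, 27
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert t == pytest.approx(2.887, abs=1e-3)
        # the implementation reproduces p = 2 * sf(|t|, n - 2) on random data
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=n), rng.normal(size=n)
        mes = pd.DataFrame({"ME1": x}, index=[f"s{i}" for i in range(n)])
        traits = pd.DataFrame({"t": y}, index=mes.index)
        row = module_trait_correlation(mes, traits).iloc[0]
        tt = row["r"] * np.sqrt((n - 2) / (1 - row["r"] ** 2))
        assert row["p"] == pytest.approx(2 * sps.t.sf(abs(tt), n - 2), rel=1e-9)

    def test_null_type_one_error(self, rng):
        n, reps = 100, 400
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            mes = pd.DataFrame({"ME1": x}, index=[f"s{i}" for i in range(n)])
            traits = pd.DataFrame({"t": y}, index=mes.index)
            if module_trait_correlation(mes, traits).iloc[0]["p"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08

    def test_constant_trait_reported_missing(self, rng):
        mes = pd.DataFrame({"ME1": rng.normal(size=10)},
                           index=[f"s{i}" for i in range(10)])
        traits = pd.DataFrame({"t": np.ones(10)}, index=mes.index)
        row = module_trait_correlation(mes, traits).iloc[0]
        assert np.isnan(row["r"]) and np.isnan(row["p"])

    def test_missing_values_dropped_pairwise(self, rng):
        me = rng.normal(size=12)
        mes = pd.DataFrame({"ME1": me}, index=[f"s{i}" for i in range(12)])
        traits = pd.DataFrame({"t": me.copy()}, index=mes.index)
        traits.iloc[:4, 0] = np.nan
        row = module_trait_correlation(mes, traits).iloc[0]
        assert row["n"] == 8
        assert row["r"] == pytest.approx(1.0, abs=1e-12)


class TestConsensusRecovery:
    def test_planted_modules_recovered(self, consensus_setup):
        from sklearn.metrics import adjusted_rand_score

        data = consensus_setup["data"]
        net = consensus_setup["net"]
        truth_mod = data.truth.module_of_gene.reindex(
            data.truth.probe_to_gene.reindex(net.probes)
        ).fillna(-1).to_numpy()
        ari = adjusted_rand_score(truth_mod, net.assignment.to_numpy())
        assert ari >= 0.8

    def test_assignment_invariant_to_sample_and_probe_order(self, small_dataset):
        from sklearn.metrics import adjusted_rand_score
        from hybcoex.network import build_consensus_network

        data = small_dataset
        cls = data.truth.class_of_sample
        rng = np.random.default_rng(0)
        mats = {}
        for pop in ("F2", "HZ"):
            m = data.log2[pop]
            fert = [s for s in m.sample_ids if cls[s] == "fertile"]
            mats[pop] = m.subset_samples(fert)
        probes = primary_probes(mats["F2"])[:300]
        base = build_consensus_network(
            {p: m.subset_probes(probes) for p, m in mats.items()},
            NetworkParams(min_module_size=30),
        )
        perm_probes = list(rng.permutation(probes))
        shuffled = build_consensus_network(
            {
                p: m.subset_probes(perm_probes).subset_samples(
                    list(rng.permutation(mats[p].sample_ids))
                )
                for p, m in mats.items()
            },
            NetworkParams(min_module_size=30),
        )
        a = base.assignment.reindex(probes).to_numpy()
        b = shuffled.assignment.reindex(probes).to_numpy()
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)


def test_relabel_by_size_orders_labels():
    labels = np.array([7, 7, 7, 3, 3, 0, 9, 9, 9, 9])
    out = relabel_by_size(labels)
    assert list(out) == [2, 2, 2, 3, 3, 0, 1, 1, 1, 1]
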