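import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from hybcoex.io_core import HubParams, Interval
from hybcoex.enrichment import (
    bh_adjust,
    fisher_overlap,
    genes_in_intervals,
    identify_hubs,
    permutation_region_enrichment,
    set_overrepresentation,
)


class TestFisherOverlap:
    def test_complete_enumeration_example(self):
        # k=2, K=2, n=2, N=4: only 1 of C(4,2)=6 draws hits both -> p = 1/6
        _, p = fisher_overlap(2, 2, 2, 4)
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        _, p = fisher_overlap(0, 10, 10, 100)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_summation_oracle(self, rng):
        from math import comb

        for _ in range(50):
            N = int(rng.integers(10, 60))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            lo = max(0, K + n - N)
            k = int(rng.integers(lo, min(K, n) + 1))
            _, p = fisher_overlap(k, K, n, N)
            expect = sum(
                comb(K, x) * comb(N - K, n - x)
                for x in range(k, min(K, n) + 1)
            ) / comb(N, n)
            assert p == pytest.approx(expect, abs=1e-12)

    def test_large_universe_matches_log_gamma_oracle(self):
        # N = 10^6 with a deep tail: counts overflow naive factorials, so
        # check against a log-gamma (logsumexp) computation
        from scipy.special import gammaln, logsumexp

        k, K, n, N = 60, 2000, 5000, 10**6
        _, p = fisher_overlap(k, K, n, N)

        def log_pmf(x):
            return (
                gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
                + gammaln(N - K + 1) - gammaln(n - x + 1)
                - gammaln(N - K - n + x + 1)
                - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
            )

        log_expect = logsumexp([log_pmf(x) for x in range(k, min(K, n) + 1)])
        assert p > 0
        assert np.log(p) == pytest.approx(log_expect, rel=1e-6)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(5, 3, 10, 100)


class TestBH:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_at_least_p_and_rank_monotone(self, p_values):
        p = np.asarray(p_values)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_decreasing_a_p_never_increases_q(self, rng):
        p = rng.uniform(size=12)
        q = bh_adjust(p)
        p2 = p.copy()
        p2[3] = p[3] / 2
        q2 = bh_adjust(p2)
        assert q2[3] <= q[3] + 1e-12


class TestSetOverrepresentation:
    UNIVERSE = {f"g{i}" for i in range(200)}

    def test_small_set_excluded_by_term_filter(self):
        sets = {"tiny": [f"g{i}" for i in range(9)]}
        out = set_overrepresentation(
            {1: {f"g{i}" for i in range(50)}}, sets, self.UNIVERSE, 11, 499
        )
        assert out.empty

    def test_module_equal_to_set_is_minimal_p(self):
        module = {f"g{i}" for i in range(30)}
        out = set_overrepresentation({1: module}, {"s": sorted(module)},
                                     self.UNIVERSE, 11, 499)
        row = out.iloc[0]
        assert row["overlap"] == 30
        _, p_min = fisher_overlap(30, 30, 30, 200)
        assert row["p"] == pytest.approx(p_min, abs=1e-15)

    def test_sets_intersected_with_universe(self):
        sets = {"s": [f"g{i}" for i in range(15)] + ["missing1", "missing2"]}
        out = set_overrepresentation({1: {f"g{i}" for i in range(20)}}, sets,
                                     self.UNIVERSE, 11, 499)
        assert out.iloc[0]["set_size"] == 15

    def test_bh_family_within_call(self, rng):
        sets = {f"s{k}": [f"g{i}" for i in rng.choice(200, 30, replace=False)]
                for k in range(5)}
        out = set_overrepresentation({1: {f"g{i}" for i in range(40)}}, sets,
                                     self.UNIVERSE, 11, 499)
        np.testing.assert_allclose(
            out["q"], bh_adjust(out["p"].to_numpy()), atol=1e-12
        )


class TestGenesInIntervals:
    POS = {
        "gA": Interval("chr1", 100, 200, "gA"),
        "gB": Interval("chr1", 300, 400, "gB"),
        "gC": Interval("chr2", 100, 200, "gC"),
    }

    def test_overlap_half_open(self):
        hits = genes_in_intervals(self.POS, [Interval("chr1", 150, 250)])
        assert hits == {"gA"}

    def test_abutting_interval_does_not_overlap(self):
        hits = genes_in_intervals(self.POS, [Interval("chr1", 200, 300)])
        assert hits == set()

    def test_chromosome_must_match(self):
        hits = genes_in_intervals(self.POS, [Interval("chr3", 0, 10**6)])
        assert hits == set()


class TestRegionEnrichment:
    def test_empty_region_not_significant(self, rng):
        res = permutation_region_enrichment(
            {"g1", "g2"}, [f"g{i}" for i in range(10)], set(), n_draws=200, seed=0
        )
        assert res.observed == 0
        assert not res.significant
        assert res.empirical_p == pytest.approx(1.0)

    def test_empirical_p_matches_hypergeometric_tail(self):
        # universe 10, hubs 3, region 5: exact tail from the hypergeometric
        universe = [f"g{i}" for i in range(10)]
        region = {f"g{i}" for i in range(5)}
        hubs = {"g0", "g1", "g7"}  # observed overlap 2
        res = permutation_region_enrichment(hubs, universe, region,
                                            n_draws=10000, seed=1)
        exact = sps.hypergeom.sf(res.observed - 1, 10, 5, 3)
        se = np.sqrt(exact * (1 - exact) / 10000)
        assert abs(res.empirical_p - exact) <= 3 * se + 2 / 10001

    def test_same_seed_reproduces(self):
        universe = [f"g{i}" for i in range(30)]
        region = {f"g{i}" for i in range(10)}
        hubs = {f"g{i}" for i in range(0, 30, 4)}
        a = permutation_region_enrichment(hubs, universe, region, 500, seed=7)
        b = permutation_region_enrichment(hubs, universe, region, 500, seed=7)
        assert (a.empirical_p, a.null_quantile_95) == (b.empirical_p, b.null_quantile_95)

    def test_hub_set_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            permutation_region_enrichment(
                {f"g{i}" for i in range(5)}, ["g0", "g1"], set(), 100, 0
            )


class TestIdentifyHubs:
    def _network(self, kme_by_pop, toms, probes, assignment_labels):
        """Minimal ConsensusNetwork stand-in with hand-set kME and TOM."""
        from hybcoex.network import ConsensusNetwork
        from hybcoex.io_core import NetworkParams

        assignment = pd.Series(assignment_labels, index=probes)
        net = ConsensusNetwork(
            params=NetworkParams(),
            probes=list(probes),
            correlations={},
            toms=toms,
            consensus=next(iter(toms.values())),
            assignment=assignment,
        )
        for pop, kmes in kme_by_pop.items():
            net.kme[pop] = pd.DataFrame({"ME1": kmes}, index=probes)
        return net

    def test_kme_rule_with_min_combination(self):
        probes = [f"p{i}" for i in range(6)]
        kme_a = [0.9, 0.9, 0.5, 0.86, 0.3, 0.2]
        kme_b = [0.9, 0.8, 0.5, 0.88, 0.3, 0.2]
        tom = np.full((6, 6), 0.05)
        np.fill_diagonal(tom, 1.0)
        net = self._network(
            {"F2": kme_a, "HZ": kme_b}, {"F2": tom, "HZ": tom}, probes, [1] * 6
        )
        p2g = pd.Series({p: p.upper() for p in probes})
        hubs = identify_hubs(net, p2g, HubParams(top_n_degree=1))
        kme_hubs = set(hubs.loc[hubs["is_kme_hub"], "probe_id"])
        # p0: min(0.9, 0.9) >= 0.85 -> hub; p1: min(0.9, 0.8) < 0.85 -> no
        assert "p0" in kme_hubs and "p1" not in kme_hubs
        assert "p3" in kme_hubs

    def test_top_degree_matches_brute_force(self, rng):
        n = 10
        probes = [f"p{i}" for i in range(n)]
        tom = rng.uniform(0, 0.4, (n, n))
        tom = (tom + tom.T) / 2
        np.fill_diagonal(tom, 1.0)
        net = self._network(
            {"F2": [0.0] * n}, {"F2": tom}, probes, [1] * n
        )
        p2g = pd.Series({p: p for p in probes})
        hp = HubParams(top_n_degree=5, edge_threshold=0.1)
        hubs = identify_hubs(net, p2g, hp)
        got = set(hubs.loc[hubs["is_degree_hub"], "probe_id"])
        off = tom - np.eye(n)
        degree = (off >= 0.1).sum(axis=1)
        strength = off.sum(axis=1)
        order = sorted(range(n), key=lambda i: (-degree[i], -strength[i], probes[i]))
        assert got == {probes[i] for i in order[:5]}

    def test_planted_high_loading_genes_become_hubs(self, consensus_setup):
        data = consensus_setup["data"]
        net = consensus_setup["net"]
        p2g = data.truth.probe_to_gene
        hubs = identify_hubs(net, p2g, HubParams())
        hub_genes = set(hubs["gene_id"])
        abs_lam = data.truth.loadings.abs()
        net_genes = set(p2g.reindex(net.probes))
        # map each network module to its dominant planted module
        truth_mod = data.truth.module_of_gene.reindex(
            p2g.reindex(net.probes)
        ).fillna(-1).to_numpy()
        labels = net.assignment.to_numpy()
        rates = []
        for lab in sorted(set(labels) - {0}):
            vals, counts = np.unique(truth_mod[labels == lab], return_counts=True)
            m = int(vals[counts.argmax()])
            if m < 0 or m in data.truth.disrupted_modules:
                continue
            members = [
                g for g in data.truth.module_of_gene.index[
                    data.truth.module_of_gene == m
                ] if g in net_genes
            ]
            lam = abs_lam[members]
            top = lam[lam >= lam.quantile(0.9)].index
            rates.append(np.mean([g in hub_genes for g in top]))
        assert np.mean(rates) >= 0.8
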