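import numpy as np
import pytest

from dropcell import (
    BackgroundProfile,
    barcode_totals,
    bh_adjust,
    call_cells,
    cluster_mc_test,
    dm_loglik,
    ed_barcode_test,
    filter_mito,
    mc_pvalue,
)

from conftest import make_matrix


class TestMcPvalueFormula:
    def test_below_all_nulls(self):
        nulls = np.linspace(0.5, 0.9, 1000)
        assert mc_pvalue(nulls, 0.1) == pytest.approx(1 / 1001)

    def test_above_all_nulls(self):
        nulls = np.linspace(0.5, 0.9, 1000)
        assert mc_pvalue(nulls, 0.95) == 1.0

    def test_hand_constructed(self):
        # 3 of 4 nulls <= observed -> (3 + 1) / (4 + 1)
        assert mc_pvalue([0.1, 0.2, 0.3, 0.9], 0.3) == pytest.approx(4 / 5)

    def test_tie_counts_as_le(self):
        assert mc_pvalue([0.5, 0.5], 0.5) == 1.0

    def test_floor_bound(self, rng):
        for _ in range(20):
            nulls = rng.normal(size=50)
            obs = rng.normal()
            p = mc_pvalue(nulls, obs)
            assert 1 / 51 <= p <= 1.0


def background_fixture(rng, n_genes=300, n_bg=40):
    p = rng.dirichlet(np.full(n_genes, 2.0))
    prof = BackgroundProfile(p_b0=p)
    return p, prof


class TestClusterTest:
    def test_background_like_cluster_large_p(self, rng):
        p, prof = background_fixture(rng)
        dense = rng.multinomial(500, p, size=10).T
        m = make_matrix(dense)
        res = cluster_mc_test(m, np.arange(10), prof, m_iter=500, seed=1)
        assert res.p_value > 0.05

    def test_distinct_cluster_small_p(self, rng):
        p, prof = background_fixture(rng)
        q = rng.dirichlet(np.full(300, 0.05))
        dense = rng.multinomial(500, q, size=10).T
        m = make_matrix(dense)
        res = cluster_mc_test(m, np.arange(10), prof, m_iter=500, seed=1)
        assert res.p_value == pytest.approx(1 / 501)

    def test_monotone_in_statistic(self, rng):
        # same null draws (shared cache + N): smaller T_C gives smaller p
        p, prof = background_fixture(rng)
        cache = {}
        dense_bg = rng.multinomial(500, p, size=4).T
        q = rng.dirichlet(np.full(300, 0.05))
        dense_far = rng.multinomial(500, q, size=4).T
        m_bg = make_matrix(dense_bg)
        m_far = make_matrix(dense_far)
        r_bg = cluster_mc_test(m_bg, np.arange(4), prof, m_iter=400, seed=2, null_cache=cache)
        # force identical null set by reusing the cache entry under the far N
        cache[int(barcode_totals(m_far)[1])] = cache[r_bg.n_ref]
        r_far = cluster_mc_test(m_far, np.arange(4), prof, m_iter=400, seed=2, null_cache=cache)
        assert r_far.t_c < r_bg.t_c
        assert r_far.p_value <= r_bg.p_value

    def test_n_ref_even_cluster_uses_middle_pair(self, rng):
        p, prof = background_fixture(rng)
        dense = rng.multinomial(300, p, size=6).T
        dense[:, 0] *= 3  # distinct totals so the reference is identifiable
        m = make_matrix(dense)
        res = cluster_mc_test(m, np.arange(6), prof, m_iter=100, seed=0)
        totals = barcode_totals(m)
        assert res.n_ref in totals.tolist()

    def test_requires_two_members(self, rng):
        p, prof = background_fixture(rng)
        m = make_matrix(rng.multinomial(100, p, size=3).T)
        with pytest.raises(ValueError):
            cluster_mc_test(m, [0], prof)

    def test_m_iter_validation(self, rng):
        p, prof = background_fixture(rng)
        m = make_matrix(rng.multinomial(100, p, size=3).T)
        with pytest.raises(ValueError):
            cluster_mc_test(m, [0, 1], prof, m_iter=0)


class TestEdTest:
    def test_floor_bound(self, rng):
        p, prof = background_fixture(rng)
        m = make_matrix(rng.multinomial(200, p, size=2).T)
        res = ed_barcode_test(m, 0, prof, m_iter=100, seed=1)
        assert res.p_value >= 1 / 101

    def test_background_like_barcode_large_p(self, rng):
        p, prof = background_fixture(rng)
        x = np.round(500 * p).astype(int)  # proportional to expectations
        m = make_matrix(x[:, None])
        res = ed_barcode_test(m, 0, prof, m_iter=500, seed=3)
        assert res.p_value > 0.5

    def test_low_mass_genes_barcode_small_p(self, rng):
        p, prof = background_fixture(rng)
        order = np.argsort(p)
        x = np.zeros(300, dtype=int)
        x[order[:3]] = [200, 200, 100]  # all mass on rarest genes
        m = make_matrix(x[:, None])
        res = ed_barcode_test(m, 0, prof, m_iter=500, seed=3)
        assert res.p_value < 0.05

    def test_dm_null_used_with_finite_concentration(self, rng):
        p = rng.dirichlet(np.full(100, 2.0))
        prof = BackgroundProfile(p_b0=p, concentration=5.0)
        m = make_matrix(rng.multinomial(300, p, size=2).T)
        res = ed_barcode_test(m, 0, prof, m_iter=200, seed=0)
        assert 0 < res.p_value <= 1

    def test_dm_loglik_multinomial_limit(self):
        p = np.array([0.5, 0.3, 0.2])
        x = np.array([2, 1, 0])
        # log [ 3!/(2!1!) * 0.5^2 * 0.3 ] = log(3 * 0.075)
        assert dm_loglik(x, p, np.inf) == pytest.approx(np.log(3 * 0.25 * 0.3))

    def test_dm_loglik_closed_form(self):
        # DM(n=2, alpha=2, p=[0.5,0.5]), x=[2,0]:
        # 2!/(2!0!) * B-ratio = Gamma(2)/Gamma(4) * Gamma(1+2)/Gamma(1) = (1/6)*2 = 1/3...
        # computed independently: P(X=[2,0]) = (a1)(a1+1)/((a)(a+1)) = 1*2/(2*3) = 1/3
        p = np.array([0.5, 0.5])
        assert dm_loglik(np.array([2, 0]), p, 2.0) == pytest.approx(np.log(1 / 3))


def bh_oracle(pvals):
    """Brute-force BH: q_i = min_{j: p_j >= p_i} p_j * m / rank_j, monotone."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [None] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pvals[i] * m / rank)
        q[i] = best
    return q


class TestBH:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.4]).tolist() == [0.4]

    def test_order_preserved(self, rng):
        p = np.sort(rng.random(50).clip(1e-6, 1))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(1000):
            n = rng.integers(1, 12)
            p = rng.random(n).clip(1e-9, 1.0)
            assert np.allclose(bh_adjust(p), bh_oracle(p.tolist()), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestPipeline:
    def test_empty_b1_returns_b2_exactly(self, rng):
        totals = np.concatenate([np.full(5, 9000), np.full(200, 50)])
        dense = np.zeros((20, 205), dtype=int)
        p = rng.dirichlet(np.full(20, 1.0))
        for j, t in enumerate(totals):
            dense[:, j] = rng.multinomial(t, p)
        m = make_matrix(dense)
        calls = call_cells(m, lower=100, upper=500, m_iter=100, seed=0)
        assert set(calls.provenance.values()) == {"high_count"}
        assert calls.retained.size == 5

    def test_determinism(self, small_sim):
        c1 = call_cells(small_sim.matrix, m_iter=150, seed=77)
        c2 = call_cells(small_sim.matrix, m_iter=150, seed=77)
        assert np.array_equal(c1.retained, c2.retained)
        assert c1.provenance == c2.provenance
        assert [r.p_value for r in c1.cluster_results] == [r.p_value for r in c2.cluster_results]
        assert [r.p_value for r in c1.barcode_results] == [r.p_value for r in c2.barcode_results]

    def test_retained_q_values_below_fdr(self, small_sim):
        calls = call_cells(small_sim.matrix, m_iter=150, seed=77)
        retained = set(calls.retained.tolist())
        for r in calls.cluster_results:
            if set(r.cluster.tolist()) <= retained and all(
                calls.provenance[int(i)] == "cluster_test" for i in r.cluster
            ):
                assert r.q_value <= calls.fdr_target
        for r in calls.barcode_results:
            if r.barcode in retained and calls.provenance[r.barcode] == "individual_test":
                assert r.q_value <= calls.fdr_target

    def test_b2_always_retained(self, small_sim):
        calls = call_cells(small_sim.matrix, m_iter=150, seed=77)
        assert set(calls.partition.b2.tolist()) <= set(calls.retained.tolist())

    def test_invalid_fdr(self, small_sim):
        with pytest.raises(ValueError):
            call_cells(small_sim.matrix, fdr=1.5)


class TestFilterMito:
    def make_calls(self, dense, symbols):
        m = make_matrix(dense, symbols=symbols)
        from dropcell import BarcodePartition, CellCalls

        part = BarcodePartition(1, 2, np.array([0]), np.array([], dtype=int), np.array([1, 2]))
        retained = np.arange(dense.shape[1])
        return m, CellCalls(
            retained=retained,
            provenance={int(i): "high_count" for i in retained},
            fdr_target=0.01,
            barcode_ids=m.barcode_ids,
            matrix=m,
            partition=part,
        )

    def test_forty_percent_removed(self):
        dense = np.array([[40, 39, 10], [60, 61, 90]])
        m, calls = self.make_calls(dense, symbols=["MT-ND1", "ACTB"])
        out = filter_mito(m, calls, threshold=0.40)
        assert out.retained.tolist() == [1, 2]  # 40/100 removed, 39/100 kept

    def test_no_match_identity(self):
        dense = np.array([[40, 39], [60, 61]])
        m, calls = self.make_calls(dense, symbols=["ACTB", "GAPDH"])
        out = filter_mito(m, calls, threshold=0.40)
        assert out is calls

    def test_case_insensitive_multi_prefix(self):
        dense = np.array([[90, 5], [10, 95]])
        m, calls = self.make_calls(dense, symbols=["mt-Nd1", "ACTB"])
        out = filter_mito(m, calls, mito_prefix=["MT-", "GRCH38_MT-"], threshold=0.40)
        assert out.retained.tolist() == [1]

    def test_threshold_validation(self):
        dense = np.array([[1, 1], [1, 1]])
        m, calls = self.make_calls(dense, symbols=["MT-A", "B"])
        with pytest.raises(ValueError):
            filter_mito(m, calls, threshold=1.5)
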