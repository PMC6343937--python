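import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sstrans.datasets import CONTROL, DISEASE, GeneSetCollection
from sstrans.deg_pathway import (bh_fdr, call_degs, enrich, significant_genes,
                                 wmw_test)
from .conftest import make_dataset


def exact_wmw_p(a, b):
    """Enumeration oracle: exact two-sided WMW p over all relabelings."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(n), na):
        r = ranks[list(combo)]
        us.append(r.sum() - na * (na + 1) / 2.0)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


def bh_reference(p):
    """Brute-force step-up: q_i = min_{j: p_j >= p_i} n*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, n * p[i] / rank_from_top)
        q[i] = min(running, 1.0)
    return q


class TestWMW:
    def test_fully_separated_groups(self):
        u, p = wmw_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_null(self):
        _, p = wmw_test([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            wmw_test([1.0], [])

    @given(st.integers(2, 8), st.integers(1, 7), st.integers(0, 10 ** 6))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, n, na_raw, seed):
        na = min(na_raw, n - 1)
        rng = np.random.default_rng(seed)
        pooled = rng.permutation(np.arange(1.0, n + 1))  # tie-free
        a, b = pooled[:na], pooled[na:]
        _, p = wmw_test(a, b)
        assert p == pytest.approx(exact_wmw_p(a, b), abs=1e-12)


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_value_identity(self):
        np.testing.assert_allclose(bh_fdr([0.5]), [0.5])

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.integers(0, 10 ** 6))
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariance_and_reference(self, ps, seed):
        ps = np.asarray(ps)
        q = bh_fdr(ps)
        np.testing.assert_allclose(q, bh_reference(ps), atol=1e-12)
        perm = np.random.default_rng(seed).permutation(len(ps))
        np.testing.assert_allclose(bh_fdr(ps[perm]), q[perm], atol=1e-12)


def planted_deg_dataset(seed, n_null=100, n_sig=10, shift=3.0, n_per=20):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    y = np.array([0] * n_per + [1] * n_per)
    vals = rng.normal(size=(n_null + n_sig, n))
    vals[n_null:, :] += shift * y[None, :]
    genes = [f"N{i:03d}" for i in range(n_null)] + [f"S{i:02d}" for i in range(n_sig)]
    labels = [CONTROL if v == 0 else DISEASE for v in y]
    ds = make_dataset(vals, genes, [f"s{i:02d}" for i in range(n)], labels)
    return ds, {g for g in genes if g.startswith("S")}


class TestCallDegs:
    def test_planted_genes_recovered(self):
        full_hits = 0
        for seed in range(10):
            ds, planted = planted_deg_dataset(seed)
            called = significant_genes(call_degs(ds))
            full_hits += planted <= called
        assert full_hits >= 9

    def test_null_data_calls_almost_nothing(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=(100, 30))
            labels = [CONTROL, DISEASE] * 15
            ds = make_dataset(vals, [f"G{i}" for i in range(100)],
                              [f"s{i}" for i in range(30)], labels)
            counts.append(len(significant_genes(call_degs(ds))))
        assert np.median(counts) <= 1

    def test_one_vs_one_runs_without_calls(self):
        ds = make_dataset([[1.0, 2.0], [3.0, 1.0]], ["A", "B"], ["s1", "s2"],
                          [CONTROL, DISEASE])
        table = call_degs(ds)
        assert not table["is_significant"].any()
        assert (table["p"] >= 0.5).all()

    def test_single_class_error(self):
        ds = make_dataset([[1.0, 2.0]], ["A"], ["s1", "s2"],
                          [CONTROL, CONTROL])
        with pytest.raises(ValueError, match="both classes"):
            call_degs(ds)

    def test_sample_order_invariance(self):
        ds, _ = planted_deg_dataset(3, n_null=20, n_sig=5, n_per=8)
        t1 = call_degs(ds)
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        shuffled = make_dataset(ds.values.to_numpy()[:, perm], ds.gene_ids,
                                [ds.sample_ids[i] for i in perm],
                                [ds.labels.iloc[i] for i in perm])
        t2 = call_degs(shuffled)
        pd.testing.assert_frame_equal(t1, t2)


class TestEnrich:
    def _gsc(self, sets, universe):
        return GeneSetCollection(sets=sets, universe=set(universe))

    def test_perfect_overlap_extreme_p(self):
        universe = [f"G{i:03d}" for i in range(100)]
        degs = set(universe[:10])
        gsc = self._gsc({"HIT": set(universe[:10])}, universe)
        table = enrich(degs, gsc, set(universe))
        p = table.loc[table.set_name == "HIT", "p"].iloc[0]
        # exact tail: 1 / C(100,10)
        assert p == pytest.approx(1.0 / math.comb(100, 10), rel=1e-6)
        assert p < 1e-10

    def test_zero_overlap_not_flagged(self):
        universe = [f"G{i:03d}" for i in range(50)]
        degs = set(universe[:5])
        gsc = self._gsc({"MISS": set(universe[40:45])}, universe)
        table = enrich(degs, gsc, set(universe))
        assert table["p"].iloc[0] >= 0.5
        assert not table["is_enriched"].any()

    def test_empty_deg_set_empty_table(self):
        gsc = self._gsc({"A": {"G1", "G2", "G3"}}, ["G1", "G2", "G3", "G4"])
        table = enrich(set(), gsc, {"G1", "G2", "G3", "G4"})
        assert table.empty

    def test_small_sets_skipped_after_restriction(self):
        universe = {f"G{i}" for i in range(20)}
        gsc = self._gsc({"TINY": {"G0", "G1", "UNMEASURED"}},
                        universe | {"UNMEASURED"})
        table = enrich({"G0"}, gsc, universe)
        assert "TINY" not in set(table.get("set_name", []))

    def test_matches_exact_combinatorial_tail(self):
        # universe 30, set of 6, 8 DEGs, overlap k: tail sum of hypergeom pmf
        universe = [f"G{i:02d}" for i in range(30)]
        members = set(universe[:4]) | {universe[10], universe[11]}
        degs = set(universe[:8])
        gsc = self._gsc({"S": members}, universe)
        table = enrich(degs, gsc, set(universe))
        k_obs = len(members & degs)
        tail = sum(math.comb(6, k) * math.comb(24, 8 - k) / math.comb(30, 8)
                   for k in range(k_obs, 7))
        assert table["p"].iloc[0] == pytest.approx(tail, rel=1e-9)
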