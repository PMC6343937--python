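import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sstrans.cohorts import enumerate_case_studies
from sstrans.datasets import CONTROL, DISEASE
from sstrans.deg_pathway import call_degs, enrich, enriched_sets, significant_genes
from sstrans.evaluation import (auc, confusion_sets, grid_registry,
                                meta_analyze, prf, score_mouse_direct,
                                summarize_ci)
from sstrans.synthetic_data import SimConfig, generate_case_study


class TestConfusionAndPRF:
    def test_set_algebra(self):
        tp, fp, fn = confusion_sets({"a", "b", "c"}, {"b", "c", "d"})
        assert (tp, fp, fn) == ({"b", "c"}, {"a"}, {"d"})

    def test_empty_prediction(self):
        tp, fp, fn = confusion_sets(set(), {"x"})
        assert (tp, fp, fn) == (set(), set(), {"x"})

    def test_perfect_prediction(self):
        tp, fp, fn = confusion_sets({"x"}, {"x"})
        assert fp == set() and fn == set()

    def test_reported_sepsis_operating_point(self):
        # precision 0.72, recall 0.96 combine to F = 0.8229
        p, r, f = 0.72, 0.96, 2 * 0.72 * 0.96 / (0.72 + 0.96)
        tp = 72
        fp = round(tp / p) - tp
        fn = round(tp / r) - tp
        got = prf(tp, fp, fn)
        assert got[0] == pytest.approx(0.72)
        assert got[1] == pytest.approx(0.96)
        assert got[2] == pytest.approx(0.8229, abs=5e-5)

    def test_degenerate_zero_counts(self):
        assert prf(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_harmonic_mean_fixed_point(self):
        _, _, f = prf(5, 5, 5)
        assert f == pytest.approx(0.5)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_against_naive_formulas(self, tp, fp, fn):
        p, r, f = prf(tp, fp, fn)
        p_ref = tp / (tp + fp) if tp + fp else 0.0
        r_ref = tp / (tp + fn) if tp + fn else 0.0
        f_ref = 2 * p_ref * r_ref / (p_ref + r_ref) if p_ref + r_ref else 0.0
        assert (p, r, f) == pytest.approx((p_ref, r_ref, f_ref))


def auc_pairwise(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_hand_enumerated_pairs(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])

    @given(st.lists(st.floats(0, 1, width=16), min_size=4, max_size=30),
           st.integers(0, 10 ** 6))
    @settings(max_examples=150, deadline=None)
    def test_matches_pairwise_count(self, scores, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, size=len(scores))
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(
            auc_pairwise(scores, labels), abs=1e-12)


class TestGridRegistry:
    def test_full_benchmark_cardinality(self):
        grid = grid_registry(["knn", "svm", "rf", "nn"], ["supervised", "semi"],
                             [1.0, 0.9, 0.7, 0.5, 0.3, 0.1],
                             enumerate_case_studies())
        assert len(grid) == 1728

    def test_singleton_grid(self):
        grid = grid_registry(["nn"], ["semi"], [1.0], ["cs1"])
        assert len(grid) == 1

    def test_empty_axis_error(self):
        with pytest.raises(ValueError, match="families"):
            grid_registry([], ["semi"], [1.0], ["cs1"])

    def test_cell_seeds_stable_and_distinct(self):
        g1 = grid_registry(["knn", "nn"], ["semi"], [1.0, 0.5], ["a", "b"],
                           master_seed=3)
        g2 = grid_registry(["knn", "nn"], ["semi"], [1.0, 0.5], ["a", "b"],
                           master_seed=3)
        assert (g1["seed"] == g2["seed"]).all()
        assert g1["seed"].nunique() == len(g1)


def random_grid(seed, n=200, alpha_effect=0.0, noise_sd=1.0):
    rng = np.random.default_rng(seed)
    fam = rng.choice(["knn", "svm", "rf", "nn"], size=n)
    alpha = rng.choice([1.0, 0.9, 0.7, 0.5, 0.3, 0.1], size=n)
    resp = alpha_effect * alpha + rng.normal(scale=noise_sd, size=n)
    return pd.DataFrame({"family": fam, "alpha": alpha, "fscore": resp})


class TestMetaAnalyze:
    def test_planted_alpha_effect_detected(self):
        hits = 0
        for seed in range(5):
            grid = random_grid(seed, alpha_effect=0.1, noise_sd=0.1)
            table = meta_analyze(grid)
            row = table[table["term"] == "alpha"].iloc[0]
            hits += (row["coef"] > 0) and (row["p"] < 0.05)
        assert hits >= 4

    def test_single_family_error(self):
        grid = random_grid(0)
        grid["family"] = "nn"
        with pytest.raises(ValueError, match="family"):
            meta_analyze(grid)

    def test_rank_deficient_design_names_columns(self):
        grid = random_grid(1)
        grid["dup"] = grid["alpha"]
        with pytest.raises(ValueError, match="alpha|dup"):
            meta_analyze(grid, covariates=("dup",))


class TestSummarizeCI:
    def test_constant_vector(self):
        lo, hi, mean = summarize_ci([0.4] * 10, seed=0)
        assert lo == hi == mean == pytest.approx(0.4)

    def test_bernoulli_mean_interval(self):
        values = [0.0, 1.0] * 50
        lo, hi, mean = summarize_ci(values, seed=1)
        assert mean == pytest.approx(0.5)
        assert 0.3 <= lo <= 0.5 <= hi <= 0.7

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            summarize_ci([0.5])


class TestDoubleEntryScoring:
    def test_mouse_direct_report_matches_independent_path(self):
        """The packaged scorer agrees with a second, naive scoring path."""
        cfg = SimConfig(n_genes=80, n_shared_deg=10, n_mouse_only_deg=5,
                        n_human_only_deg=5, n_mouse_per_class=(10, 10),
                        n_human_per_class=(10, 10), n_pathways=8,
                        pathway_size=6, seed=5)
        cs, truth, gsc = generate_case_study(cfg)
        report = score_mouse_direct(cs, gsc)

        # independent path: recompute everything with raw calls + formulas
        m_degs = significant_genes(call_degs(cs.mouse))
        h_degs = significant_genes(call_degs(cs.human))
        tp = m_degs & h_degs
        fp = m_degs - h_degs
        fn = h_degs - m_degs
        prec = len(tp) / len(m_degs) if m_degs else 0.0
        rec = len(tp) / len(h_degs) if h_degs else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert report.deg.tp == tp and report.deg.fp == fp and report.deg.fn == fn
        assert report.deg.precision == pytest.approx(prec)
        assert report.deg.recall == pytest.approx(rec)
        assert report.deg.fscore == pytest.approx(f)

        m_paths = enriched_sets(enrich(m_degs, gsc, set(cs.mouse.gene_ids)))
        h_paths = enriched_sets(enrich(h_degs, gsc, set(cs.human.gene_ids)))
        assert report.pathway.tp == (m_paths & h_paths)
        assert report.pathway.fn == (h_paths - m_paths)
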