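"""Differential expression and gene-set over-representation analysis.

Differential expression between the two phenotype classes is assessed
per gene by the two-sided Wilcoxon-Mann-Whitney rank-sum test, with
Benjamini-Hochberg FDR adjustment across genes.  A gene is called a DEG
when p < 0.05 and q < 0.25 — deliberately permissive thresholds suited
to small model-system cohorts.

Pathway over-representation of a DEG list against GMT gene sets uses the
one-sided hypergeometric tail with the measured genes as the sampling
universe, BH adjustment across sets, and an enrichment call at q < 0.05;
sets with fewer than 3 measured genes are skipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datasets import CONTROL, DISEASE, ExpressionDataset, GeneSetCollection

P_THRESHOLD = 0.05
Q_THRESHOLD = 0.25
ENRICH_Q_THRESHOLD = 0.05
MIN_SET_SIZE = 3
_EXACT_MAX_N = 12

DEG_COLUMNS = ("gene", "U", "p", "q", "direction", "is_significant")
ENRICH_COLUMNS = ("set_name", "overlap", "set_size", "universe_size",
                  "n_degs", "p", "q", "is_enriched")


def wmw_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test; returns (U of group A, p).

    Uses the exact null distribution when the pooled sample size is at
    most 12 and the data are tie-free, otherwise the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (a.size + b.size <= _EXACT_MAX_N and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def call_degs(ds: ExpressionDataset, labels: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene WMW test across the two classes, with BH FDR.

    ``labels`` may override the dataset's own phenotypes (e.g. with
    model-predicted ones).  Raises on single-class labels — a degenerate
    translation; callers score such runs with an empty predicted DEG set.

    Returns a DataFrame with columns ``gene, U, p, q, direction,
    is_significant`` where direction is the sign of the disease-minus-
    control median difference.
    """
    lab = ds.labels if labels is None else pd.Series(labels).loc[ds.sample_ids]
    y = lab.to_numpy()
    mask_d = y == DISEASE
    mask_c = y == CONTROL
    if mask_d.sum() == 0 or mask_c.sum() == 0:
        raise ValueError(
            f"DEG calling requires both classes; got "
            f"{ {DISEASE: int(mask_d.sum()), CONTROL: int(mask_c.sum())} }")
    vals = ds.values.to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(ds.gene_ids):
        a = vals[i, mask_d]
        b = vals[i, mask_c]
        u, p = wmw_test(a, b)
        rows.append((gene, u, p, float(np.sign(np.median(a) - np.median(b)))))
    df = pd.DataFrame(rows, columns=["gene", "U", "p", "direction"])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["is_significant"] = (df["p"] < P_THRESHOLD) & (df["q"] < Q_THRESHOLD)
    return df[list(DEG_COLUMNS)]


def significant_genes(deg_table: pd.DataFrame) -> set[str]:
    return set(deg_table.loc[deg_table["is_significant"], "gene"])


def enrich(degs: set[str], gsc: GeneSetCollection, measured: set[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a DEG list.

    Gene sets are restricted to the measured genes first; sets smaller
    than 3 after restriction are skipped.  The universe is the measured
    gene list.  Returns a DataFrame with columns ``set_name, overlap,
    set_size, universe_size, n_degs, p, q, is_enriched`` (empty for an
    empty DEG list).
    """
    degs = set(degs) & set(measured)
    columns = list(ENRICH_COLUMNS)
    if not degs:
        return pd.DataFrame(columns=columns)
    restricted = gsc.restricted(set(measured))
    M = len(measured)
    N = len(degs)
    rows = []
    for name in sorted(restricted.sets):
        genes = restricted.sets[name]
        K = len(genes)
        if K < MIN_SET_SIZE:
            continue
        k = len(genes & degs)
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append((name, k, K, M, N, p))
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows, columns=columns[:6])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["is_enriched"] = df["q"] < ENRICH_Q_THRESHOLD
    return df[columns]


def enriched_sets(enrich_table: pd.DataFrame) -> set[str]:
    if enrich_table.empty:
        return set()
    return set(enrich_table.loc[enrich_table["is_enriched"], "set_name"])
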