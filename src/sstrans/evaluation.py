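"""Scoring translated predictions against truth-phenotype analyses.

A predicted DEG (or enriched-pathway) set is compared with the set derived
from the true human phenotypes: true positives are predictions also
implicated under the truth, false positives are predictions absent from
the truth, and false negatives are truth items missed.  Precision, recall
and the (equal-weight, F1) F-score summarize each prediction modality —
the mouse cohort analyzed directly, or a classifier's predicted human
phenotypes.  Phenotype-level discrimination is the rank-based AUC.

The grid registry enumerates the full benchmark Cartesian product
(classifier family x training mode x elastic-net alpha x case study) with
stable per-cell seeds, and the meta-analysis stage fits an ordinary
linear model of a performance response on classifier family (dummy
coded), alpha (numeric) and optional design covariates.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata, wilcoxon

from .datasets import DISEASE, CaseStudy, GeneSetCollection
from .deg_pathway import call_degs, enrich, enriched_sets, significant_genes


@dataclass
class EvalReport:
    """Confusion sets and precision/recall/F-score at one level."""

    level: str                      # "deg" or "pathway"
    tp: set = field(default_factory=set)
    fp: set = field(default_factory=set)
    fn: set = field(default_factory=set)
    precision: float = 0.0
    recall: float = 0.0
    fscore: float = 0.0
    auc: float | None = None

    def to_json_dict(self) -> dict:
        return {"level": self.level, "tp": sorted(self.tp), "fp": sorted(self.fp),
                "fn": sorted(self.fn), "precision": self.precision,
                "recall": self.recall, "fscore": self.fscore, "auc": self.auc}


def confusion_sets(predicted: set, truth: set) -> tuple[set, set, set]:
    predicted, truth = set(predicted), set(truth)
    return predicted & truth, predicted - truth, truth - predicted


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F-score from confusion counts (0 on empty sides)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    fscore = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, fscore


def score_sets(predicted: set, truth: set, level: str) -> EvalReport:
    tp, fp, fn = confusion_sets(predicted, truth)
    p, r, f = prf(len(tp), len(fp), len(fn))
    return EvalReport(level=level, tp=tp, fp=fp, fn=fn,
                      precision=p, recall=r, fscore=f)


def auc(scores, labels) -> float:
    """Rank-based AUC (U statistic / n1*n0, midranks on ties).

    ``scores`` lean toward the positive class; ``labels`` are binary
    (1/True/"disease" positive).  Raises on a single-class label vector.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray([_as_positive(v) for v in np.asarray(labels).ravel()])
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes in the labels")
    ranks = rankdata(s, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _as_positive(v) -> int:
    if isinstance(v, str):
        return int(v == DISEASE)
    return int(bool(v))


def positive_scores(labels: pd.Series, confidences: pd.Series) -> pd.Series:
    """Convert (predicted label, confidence) into a disease-leaning score."""
    lab = labels.to_numpy()
    conf = confidences.to_numpy(dtype=float)
    return pd.Series(np.where(lab == DISEASE, conf, 1.0 - conf),
                     index=labels.index)


# ---------------------------------------------------------------------------
# End-to-end scoring of one case study

@dataclass
class TranslationScore:
    deg: EvalReport
    pathway: EvalReport
    accuracy: float | None = None
    auc: float | None = None
    predicted_degs: set = field(default_factory=set)
    predicted_pathways: set = field(default_factory=set)


def human_truth_sets(cs: CaseStudy, gsc: GeneSetCollection) -> tuple[set, set]:
    """DEGs and enriched pathways of the human cohort under true phenotypes."""
    measured = set(cs.human.gene_ids)
    truth_degs = significant_genes(call_degs(cs.human))
    truth_paths = enriched_sets(enrich(truth_degs, gsc, measured))
    return truth_degs, truth_paths


def predicted_sets(cs: CaseStudy, labels: pd.Series,
                   gsc: GeneSetCollection) -> tuple[set, set]:
    """DEGs/pathways of the human cohort under predicted phenotypes.

    A single-class prediction yields empty sets (degenerate translation).
    """
    measured = set(cs.human.gene_ids)
    lab = pd.Series(labels).loc[cs.human.sample_ids]
    if lab.nunique() < 2:
        return set(), set()
    degs = significant_genes(call_degs(cs.human, labels=lab))
    paths = enriched_sets(enrich(degs, gsc, measured))
    return degs, paths


def mouse_direct_sets(cs: CaseStudy, gsc: GeneSetCollection) -> tuple[set, set]:
    """DEGs/pathways implicated by analyzing the mouse cohort directly."""
    measured = set(cs.mouse.gene_ids)
    degs = significant_genes(call_degs(cs.mouse))
    paths = enriched_sets(enrich(degs, gsc, measured))
    return degs, paths


def score_translation(cs: CaseStudy, predicted_labels: pd.Series,
                      gsc: GeneSetCollection,
                      confidences: pd.Series | None = None) -> TranslationScore:
    """Score a predicted human phenotype assignment against the truth."""
    truth_degs, truth_paths = human_truth_sets(cs, gsc)
    pred_degs, pred_paths = predicted_sets(cs, predicted_labels, gsc)
    lab = pd.Series(predicted_labels).loc[cs.human.sample_ids]
    accuracy = float((lab.to_numpy() == cs.human.labels.to_numpy()).mean())
    auc_val = None
    if confidences is not None and cs.human.labels.nunique() == 2:
        scores = positive_scores(lab, pd.Series(confidences).loc[cs.human.sample_ids])
        auc_val = auc(scores.to_numpy(), cs.human.labels.to_numpy())
    return TranslationScore(
        deg=score_sets(pred_degs, truth_degs, "deg"),
        pathway=score_sets(pred_paths, truth_paths, "pathway"),
        accuracy=accuracy, auc=auc_val,
        predicted_degs=pred_degs, predicted_pathways=pred_paths)


def score_mouse_direct(cs: CaseStudy, gsc: GeneSetCollection) -> TranslationScore:
    """Score the mouse cohort's own DEGs/pathways against the human truth."""
    truth_degs, truth_paths = human_truth_sets(cs, gsc)
    degs, paths = mouse_direct_sets(cs, gsc)
    return TranslationScore(deg=score_sets(degs, truth_degs, "deg"),
                            pathway=score_sets(paths, truth_paths, "pathway"),
                            predicted_degs=degs, predicted_pathways=paths)


# ---------------------------------------------------------------------------
# Benchmark grid

def derive_cell_seed(master_seed: int, *parts) -> int:
    """Stable per-cell seed: CRC32 of the cell coordinates (< 2**31)."""
    key = "|".join(str(p) for p in (master_seed, *parts))
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def grid_registry(families, modes, alphas, case_studies,
                  master_seed: int = 0) -> pd.DataFrame:
    """Enumerate the benchmark Cartesian product with per-cell seeds."""
    families, modes = list(families), list(modes)
    alphas, case_studies = list(alphas), list(case_studies)
    for name, axis in (("families", families), ("modes", modes),
                       ("alphas", alphas), ("case_studies", case_studies)):
        if not axis:
            raise ValueError(f"grid axis {name!r} is empty")
    rows = []
    for fam, mode, alpha, cs in itertools.product(families, modes, alphas,
                                                  case_studies):
        cs_id = getattr(cs, "identifier", str(cs))
        rows.append({"family": fam, "mode": mode, "alpha": float(alpha),
                     "case_study": cs_id,
                     "seed": derive_cell_seed(master_seed, fam, mode, alpha, cs_id)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Meta-analysis of grid performance

def meta_analyze(grid: pd.DataFrame, response: str = "fscore",
                 covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """OLS linear model of a performance response on the grid factors.

    Fits ``response ~ C(family) + alpha [+ covariates]`` with dummy-coded
    family and numeric alpha, returning a per-coefficient table with
    estimates, standard errors and two-sided t-test p-values.  Raises on
    single-level factors or a rank-deficient (collinear) design.
    """
    cols = {"family", "alpha", response, *covariates}
    missing = cols - set(grid.columns)
    if missing:
        raise ValueError(f"grid is missing columns: {sorted(missing)}")
    if grid["family"].nunique() < 2:
        raise ValueError("factor 'family' has fewer than 2 levels")
    if grid["alpha"].nunique() < 2:
        raise ValueError("factor 'alpha' has fewer than 2 levels")
    dummies = pd.get_dummies(grid["family"], prefix="family", drop_first=True)
    X = pd.concat([dummies.astype(float),
                   grid[["alpha", *covariates]].astype(float)], axis=1)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = _collinear_columns(X)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    model = sm.OLS(grid[response].astype(float).to_numpy(), X.to_numpy()).fit()
    return pd.DataFrame({
        "term": list(X.columns),
        "coef": model.params,
        "se": model.bse,
        "t": model.tvalues,
        "p": model.pvalues,
    }).reset_index(drop=True)


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    base = np.linalg.matrix_rank(X.to_numpy())
    out = []
    for col in X.columns:
        reduced = X.drop(columns=[col]).to_numpy()
        if np.linalg.matrix_rank(reduced) == base:
            out.append(col)
    return out


def compare_families(grid: pd.DataFrame, target: str = "nn_semi",
                     response: str = "fscore") -> pd.DataFrame:
    """Paired Wilcoxon signed-rank of one family-mode against each other.

    Pairs are case studies (scores averaged over alpha).  Provided as the
    default significance test for claims that one approach outperforms the
    rest; the comparison procedure is a documented package choice.
    """
    g = grid.copy()
    g["config"] = g["family"] + "_" + g["mode"]
    pivot = g.pivot_table(index="case_study", columns="config", values=response,
                          aggfunc="mean")
    if target not in pivot.columns:
        raise ValueError(f"no configuration {target!r} in grid")
    rows = []
    for other in pivot.columns:
        if other == target:
            continue
        diff = (pivot[target] - pivot[other]).dropna()
        if len(diff) < 2 or np.allclose(diff, 0):
            stat, p = np.nan, 1.0
        else:
            stat, p = wilcoxon(diff)
        rows.append({"target": target, "other": other, "n_pairs": len(diff),
                     "median_diff": float(np.median(diff)), "w": float(stat),
                     "p": float(p)})
    return pd.DataFrame(rows)


def summarize_ci(values, n_boot: int = 10_000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float, float]:
    """Percentile-bootstrap confidence interval and mean of a score vector."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    rng = np.random.default_rng(seed % (2 ** 31))
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi), float(v.mean())
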