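"""Transductive mouse-to-human translation by iterative self-training.

The supervised path selects features on the mouse cohort, trains one
classifier, and labels every human sample once.  The semi-supervised path
starts the same way, then folds the human test cohort itself into training:
at iteration *i* the human samples in the top 10·i% of prediction
confidence are merged (with their predicted phenotypes) into an augmented
training set; features are re-selected and the model retrained on it, and
all human samples are re-predicted.  Membership and pseudo-labels of the
merged set are refreshed from the newest predictions each iteration — the
confidence threshold only ever drops, so the merged-set size never
shrinks.  The loop ends at the iteration whose threshold admits every
human sample (at most 10 iterations), and that final prediction is the
translated phenotype assignment.

Because network training is stochastic, the semi-supervised NN applies a
restart guard at iteration 1: it proceeds only once more than one human
sample lands in each class, retraining with fresh initial weights up to 50
times, after which it proceeds with the last model regardless.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import TrainedClassifier, train_classifier
from .datasets import CaseStudy, ExpressionDataset, concat_samples
from .feature_selection import FeatureSet, SelectionConfig, select_features

logger = logging.getLogger(__name__)

MAX_ITERATIONS = 10
NN_MAX_RESTARTS = 50
MODES = ("supervised", "semi")


@dataclass
class IterationRecord:
    iteration: int
    percentile: float
    merged_ids: list[str]
    merged_labels: dict[str, str]
    n_features: int
    predicted_labels: dict[str, str]
    confidences: dict[str, float]
    nn_attempts: int = 1

    def to_json_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "percentile": self.percentile,
            "merged_ids": self.merged_ids,
            "merged_labels": self.merged_labels,
            "n_features": self.n_features,
            "predicted_labels": self.predicted_labels,
            "confidences": self.confidences,
            "nn_attempts": self.nn_attempts,
        }


@dataclass
class LoopTrace:
    records: list[IterationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def merged_sizes(self) -> list[int]:
        return [len(r.merged_ids) for r in self.records]


@dataclass
class TranslationResult:
    """Predicted human phenotypes plus the loop's full iteration trace."""

    predicted_labels: pd.Series
    trace: LoopTrace
    final_features: FeatureSet
    family: str
    alpha: float
    mode: str
    seed: int

    def supervised_labels(self) -> pd.Series:
        """The iteration-1 (mouse-only model) predictions."""
        first = self.trace.records[0].predicted_labels
        return pd.Series(first)


def nn_restart_guard(predicted: pd.Series | dict, attempt: int,
                     classes=("control", "disease"),
                     max_attempts: int = NN_MAX_RESTARTS) -> bool:
    """Decide whether a first-iteration NN prediction may proceed.

    Proceed when more than one human sample is classified into *each*
    class, or when ``attempt`` has reached the retry cap; otherwise the
    caller should retrain with a fresh weight initialization.  The guard
    never aborts.
    """
    labels = pd.Series(predicted)
    counts = labels.value_counts()
    if all(int(counts.get(c, 0)) > 1 for c in classes):
        return True
    return attempt >= max_attempts


def _derive_seed(seed: int, *parts) -> int:
    import zlib
    key = "|".join(str(p) for p in (seed, *parts))
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _merge_cutoff(n_human: int, iteration: int, prev_count: int) -> int:
    """Target merged-set size: top 10·i percent, never shrinking."""
    return max(int(math.ceil(iteration * n_human / MAX_ITERATIONS)), prev_count)


def _top_confident(conf: pd.Series, k: int) -> list[str]:
    """IDs of the k most confident samples, extended to include boundary
    ties; order of appearance breaks the ranking deterministically."""
    order = np.argsort(-conf.to_numpy(), kind="stable")
    ids = conf.index.to_numpy()[order]
    vals = conf.to_numpy()[order]
    if k >= len(ids):
        return list(ids)
    cut = vals[k - 1]
    while k < len(ids) and vals[k] == cut:
        k += 1
    return list(ids[:k])


def _fit_iteration(train_ds: ExpressionDataset, family: str,
                   cfg: SelectionConfig, seed: int
                   ) -> tuple[FeatureSet, TrainedClassifier]:
    fs = select_features(train_ds, SelectionConfig(alpha=cfg.alpha,
                                                   cv_folds=cfg.cv_folds,
                                                   seed=seed))
    clf = train_classifier(family, train_ds, fs, seed=seed)
    return fs, clf


def supervised_translate(cs: CaseStudy, family: str, cfg: SelectionConfig,
                         seed: int = 0) -> TranslationResult:
    """Mouse-only model applied once to the human cohort."""
    it_seed = _derive_seed(seed, "iter", 1)
    fs, clf = _fit_iteration(cs.mouse, family, cfg, it_seed)
    labels, conf = clf.predict_dataset(cs.human)
    rec = IterationRecord(
        iteration=1, percentile=0.0, merged_ids=[], merged_labels={},
        n_features=len(fs), predicted_labels=labels.to_dict(),
        confidences=conf.astype(float).to_dict())
    return TranslationResult(predicted_labels=labels, trace=LoopTrace([rec]),
                             final_features=fs, family=family,
                             alpha=cfg.alpha, mode="supervised", seed=seed)


def semi_supervised_translate(cs: CaseStudy, family: str, cfg: SelectionConfig,
                              seed: int = 0) -> TranslationResult:
    """The full self-training loop (descending confidence schedule)."""
    n_human = cs.human.n_samples
    records: list[IterationRecord] = []
    merged_ids: list[str] = []
    merged_labels = pd.Series(dtype=object)
    prev_count = 0
    fs: FeatureSet | None = None
    labels = conf = None

    for iteration in range(1, MAX_ITERATIONS + 1):
        it_seed = _derive_seed(seed, "iter", iteration)
        if iteration == 1:
            train_ds = cs.mouse
        else:
            train_ds = concat_samples(
                cs.mouse, _human_subset(cs.human, merged_ids),
                labels_b=merged_labels)
        fs, clf = _fit_iteration(train_ds, family, cfg, it_seed)
        labels, conf = clf.predict_dataset(cs.human)
        attempts = 1
        if family == "nn" and iteration == 1:
            while not nn_restart_guard(labels, attempts):
                attempts += 1
                retry_seed = _derive_seed(seed, "iter", iteration, "retry", attempts)
                clf = train_classifier(family, train_ds, fs, seed=retry_seed)
                labels, conf = clf.predict_dataset(cs.human)

        k = _merge_cutoff(n_human, iteration, prev_count)
        merged_ids = _top_confident(conf, k)
        merged_labels = labels.loc[merged_ids]
        prev_count = len(merged_ids)
        records.append(IterationRecord(
            iteration=iteration, percentile=100.0 - 10.0 * iteration,
            merged_ids=list(merged_ids),
            merged_labels=merged_labels.to_dict(),
            n_features=len(fs), predicted_labels=labels.to_dict(),
            confidences=conf.astype(float).to_dict(), nn_attempts=attempts))
        if len(merged_ids) >= n_human:
            break

    return TranslationResult(predicted_labels=labels, trace=LoopTrace(records),
                             final_features=fs, family=family,
                             alpha=cfg.alpha, mode="semi", seed=seed)


def _human_subset(human: ExpressionDataset, sample_ids: list[str]) -> ExpressionDataset:
    from dataclasses import replace
    return replace(human, values=human.values[list(sample_ids)].copy(),
                   labels=human.labels.loc[list(sample_ids)].copy())


def translate(cs: CaseStudy, family: str, mode: str, cfg: SelectionConfig,
              seed: int = 0) -> TranslationResult:
    if mode == "supervised":
        return supervised_translate(cs, family, cfg, seed=seed)
    if mode == "semi":
        return semi_supervised_translate(cs, family, cfg, seed=seed)
    raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
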