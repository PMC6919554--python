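"""Evaluation metrics and reports.

Classification is scored with the unweighted average recall (UAR), the mean of
per-class recalls, which is insensitive to class imbalance; its chance level
(BCUAR) is estimated by permuting the ground-truth labels.  Reconstruction
quality is the Pearson correlation (CC) between each articulatory target and
its linear reconstruction from acoustics over the training rows.  Differences
between classifiers are tested with the two-sided pooled-variance difference
of proportions z-test at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acl_core import ACLModel, ReconstructionSet, standardize_columns

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "per_class_recall",
    "uar",
    "bcuar",
    "bcuar_analytic",
    "reconstruction_cc",
    "diff_of_proportions_test",
    "rank_features",
    "support_f1",
    "ablate_targets",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = ground truth and columns = recognized class."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        self.classes = tuple(self.classes)
        if len(self.classes) != self.counts.shape[0]:
            raise ValueError("class labels must match matrix size")

    def row_normalized(self) -> np.ndarray:
        """Per-class percentages (rows sum to 100)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        return 100.0 * self.counts / sums

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion_matrix(y_true, y_pred, classes: Sequence | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)))
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, classes)


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    sums = cm.counts.sum(axis=1)
    empty = np.flatnonzero(sums == 0)
    if empty.size:
        names = [cm.classes[i] for i in empty]
        raise ValueError(f"no ground-truth samples for class(es): {names}")
    return np.diag(cm.counts) / sums


def uar(cm: ConfusionMatrix) -> float:
    """Unweighted average recall: mean of the per-class recalls, in [0, 1]."""
    return float(np.mean(per_class_recall(cm)))


def bcuar(
    y_true,
    y_pred,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """By-chance UAR: mean UAR of fixed predictions against label-permuted
    ground truth.  Converges to 1/C for a label-independent predictor."""
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = tuple(sorted(set(y_true)))
    if len(classes) < 2:
        raise ValueError("labels are single-class; chance level undefined")
    classes = tuple(sorted(set(y_true) | set(y_pred)))
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scores = np.empty(n_permutations)
    for b in range(n_permutations):
        scores[b] = uar(confusion_matrix(rng.permutation(y_true), y_pred, classes))
    return float(np.mean(scores))


def bcuar_analytic(y_true) -> float:
    """Prior-based chance UAR: a predictor independent of the labels has
    expected recall equal in every class, so chance is 1/C regardless of the
    class priors."""
    classes = set(np.asarray(y_true).tolist())
    if len(classes) < 2:
        raise ValueError("labels are single-class; chance level undefined")
    return 1.0 / len(classes)


def reconstruction_cc(
    model: ACLModel,
    recon: ReconstructionSet,
    speaker_ids: Sequence | None = None,
) -> np.ndarray:
    """Pearson correlation per target between ground truth and the model's
    linear reconstruction over the given (training) rows.

    The features are standardized with the reconstruction rows' own statistics
    — the same convention used at fit time.  A single-column model (the
    acoustic-only criterion) is broadcast over all targets.  When
    ``speaker_ids`` is given, correlations are computed per speaker and then
    averaged.  A zero-variance reconstruction scores 0 with a warning.
    """
    Xs, _, _ = standardize_columns(recon.Xr)
    K = recon.n_targets
    if model.n_targets == K:
        W = model.W
    elif model.n_targets == 1:
        W = np.repeat(model.W, K, axis=1)
    else:
        raise ValueError(
            f"model has {model.n_targets} columns but recon has {K} targets"
        )
    A_hat = Xs @ W

    def _cc_block(A, A_hat_block) -> np.ndarray:
        out = np.empty(K)
        for k in range(K):
            a = A[:, k]
            r = A_hat_block[:, k]
            if np.std(a) == 0:
                raise ValueError(f"target {recon.target_names[k]!r} has zero variance")
            if np.std(r) == 0:
                warnings.warn(
                    f"zero-variance reconstruction for target "
                    f"{recon.target_names[k]!r}; CC set to 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
                out[k] = 0.0
            else:
                out[k] = np.corrcoef(a, r)[0, 1]
        return out

    if speaker_ids is None:
        return _cc_block(recon.A, A_hat)
    speaker_ids = np.asarray(speaker_ids)
    per_speaker = [
        _cc_block(recon.A[speaker_ids == s], A_hat[speaker_ids == s])
        for s in np.unique(speaker_ids)
    ]
    return np.mean(per_speaker, axis=0)


def diff_of_proportions_test(
    k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05
) -> tuple[float, bool]:
    """Two-sided pooled-variance z-test for p1 = k1/n1 vs p2 = k2/n2."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    z = 0.0 if denom == 0 else (p1 - p2) / np.sqrt(denom)
    critical = stats.norm.ppf(1 - alpha / 2)
    return float(z), bool(abs(z) > critical)


def rank_features(w: np.ndarray, feature_names: Sequence[str]) -> list[str]:
    """Feature names by descending |weight|; exact zeros are dropped and ties
    keep column order (stable sort)."""
    w = np.asarray(w, dtype=float).ravel()
    if len(feature_names) != w.shape[0]:
        raise ValueError("feature_names must match weight length")
    order = np.argsort(-np.abs(w), kind="stable")
    return [feature_names[i] for i in order if w[i] != 0.0]


def support_f1(
    w: np.ndarray, true_support: Sequence[int], rel_threshold: float = 0.25
) -> float:
    """F1 of support recovery: a coordinate is called active when its |weight|
    reaches ``rel_threshold`` times the largest |weight| in the vector."""
    w = np.asarray(w, dtype=float).ravel()
    top = np.max(np.abs(w))
    estimated = set(np.flatnonzero(np.abs(w) >= rel_threshold * top)) if top > 0 else set()
    truth = set(int(i) for i in true_support)
    if not estimated and not truth:
        return 1.0
    tp = len(estimated & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(estimated)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvaluationReport:
    """Bundle of headline numbers for one evaluated model."""

    uar: float
    bcuar: float | None
    recalls: np.ndarray
    cm: ConfusionMatrix
    cc_per_target: np.ndarray | None = None
    significance: dict = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        rows = [{"metric": "UAR", "value": self.uar}]
        if self.bcuar is not None:
            rows.append({"metric": "BCUAR", "value": self.bcuar})
        for cls, rec in zip(self.cm.classes, self.recalls):
            rows.append({"metric": f"recall[{cls}]", "value": float(rec)})
        if self.cc_per_target is not None:
            rows.append({"metric": "mean_CC", "value": float(np.mean(self.cc_per_target))})
        return pd.DataFrame(rows)


def ablate_targets(
    features: pd.DataFrame,
    target_tables: dict[str, pd.DataFrame],
    grid,
    spec,
    task: str = "valence",
    speaker: str | None = None,
) -> dict:
    """Independent selection + evaluation per single target and per anatomical
    group; returns all reports plus the best target and best group by mean
    evaluation recall.  Per-target failures are recorded, not propagated.
    """
    # local import: model_selection depends on this module's metrics
    from .featurization import split_feature_target_columns
    from .model_selection import grid_search

    corpus = str(features["corpus_id"].iloc[0])
    base = target_tables[corpus]
    _, target_cols = split_feature_target_columns(base)
    groups: dict[str, list[str]] = {}
    for t in target_cols:
        groups.setdefault(t.split("_")[0], []).append(t)

    def _restrict(cols: list[str]) -> dict[str, pd.DataFrame]:
        out = {}
        for cid, df in target_tables.items():
            _, tcols = split_feature_target_columns(df)
            drop = [t for t in tcols if t not in cols]
            out[cid] = df.drop(columns=drop)
        return out

    per_target: dict[str, object] = {}
    failures: dict[str, str] = {}
    for t in target_cols:
        try:
            per_target[t] = grid_search(
                features, _restrict([t]), grid, spec, task=task, speaker=speaker
            )
        except Exception as err:  # recorded, never aborts the sweep
            failures[t] = f"{type(err).__name__}: {err}"
    per_group: dict[str, object] = {}
    for g, cols in groups.items():
        try:
            per_group[g] = grid_search(
                features, _restrict(cols), grid, spec, task=task, speaker=speaker
            )
        except Exception as err:
            failures[g] = f"{type(err).__name__}: {err}"

    def _best(results: dict) -> tuple[str, float] | None:
        if not results:
            return None
        name = max(results, key=lambda n: results[n].evaluation_mean_uar)
        return name, results[name].evaluation_mean_uar

    return {
        "per_target": per_target,
        "per_group": per_group,
        "best_target": _best(per_target),
        "best_group": _best(per_group),
        "failures": failures,
    }
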