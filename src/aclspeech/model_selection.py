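"""Regularization-coefficient search and cross-validation protocols.

Two protocols are provided, matching the two kinds of corpora the method is
used on:

* ``speaker_dependent_repeated`` — classification is trained and tested on
  random halves of a single designated speaker's segments (default train/test
  ratio 0.5), while the articulatory reconstruction rows come from the
  remaining speakers (speaker-independent) or from another corpus.  Lambda
  selection averages test recall over 15 independent partitions, then the
  chosen coefficients are re-evaluated on 10 fresh partitions.
* ``loso_speaker_independent`` — leave-one-speaker-out: each speaker in turn
  is held out entirely; classification training uses all other speakers, and
  the reconstruction rows likewise never include the test speaker.  Lambda is
  chosen by the best average recall over speakers; by default the average for
  a fold excludes that fold itself (nested selection), with a
  ``pooled_selection`` switch restoring the simpler pooled average.

The default search grid is lambda1 in {0.1, 0.5, 1.0} and lambda2 in
{0.001, 0.005, 0.01, 0.05, 0.1}.  Ties on mean recall break toward larger
lambda1, then smaller lambda2 (the sparser, less constrained model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .acl_core import (
    ACLModel,
    ClassificationSet,
    ConvergenceError,
    ReconstructionSet,
    RegularizationConfig,
    fit_multi_target,
)
from .evaluation import confusion_matrix, uar
from .featurization import (
    AROUSAL_MAP,
    VALENCE_MAP,
    BinaryLabelMap,
    binarize_labels,
    split_feature_target_columns,
)
from .inference import decide_binary, posterior_averaged

__all__ = [
    "LambdaGrid",
    "ProtocolSpec",
    "PartitionError",
    "GridSearchResult",
    "make_partitions",
    "assemble_reconstruction_set",
    "classification_set_from_table",
    "reconstruction_set_from_table",
    "grid_search",
    "label_map_for_task",
]

DEFAULT_LAMBDA1 = (0.1, 0.5, 1.0)
DEFAULT_LAMBDA2 = (0.001, 0.005, 0.01, 0.05, 0.1)


class PartitionError(RuntimeError):
    """A usable train/test partition could not be produced."""


@dataclass(frozen=True)
class LambdaGrid:
    """Cartesian (lambda1, lambda2) search grid."""

    lambda1_values: tuple[float, ...] = DEFAULT_LAMBDA1
    lambda2_values: tuple[float, ...] = DEFAULT_LAMBDA2

    def __post_init__(self) -> None:
        if not self.lambda1_values or not self.lambda2_values:
            raise ValueError("grid must be nonempty")
        if any(l1 <= 0 for l1 in self.lambda1_values):
            raise ValueError("lambda1 values must be positive")
        if any(l2 < 0 for l2 in self.lambda2_values):
            raise ValueError("lambda2 values must be nonnegative")

    def points(self) -> list[tuple[float, float]]:
        return [
            (l1, l2) for l1 in self.lambda1_values for l2 in self.lambda2_values
        ]


@dataclass(frozen=True)
class ProtocolSpec:
    """Cross-validation protocol configuration."""

    mode: str = "speaker_dependent_repeated"
    train_ratio: float = 0.5
    selection_trials: int = 15
    evaluation_trials: int = 10
    seed: int = 0
    reconstruction_source: str = "same_corpus_loso"  # or "other_corpus"
    pooled_selection: bool = False  # LOSO: pool the test fold into selection
    max_resample: int = 20

    def __post_init__(self) -> None:
        if self.mode not in ("speaker_dependent_repeated", "loso_speaker_independent"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if not 0.0 < self.train_ratio < 1.0:
            raise ValueError("train_ratio must lie in (0, 1)")
        if self.selection_trials < 1 or self.evaluation_trials < 1:
            raise ValueError("trial counts must be >= 1")
        if self.reconstruction_source not in ("same_corpus_loso", "other_corpus"):
            raise ValueError(
                f"unknown reconstruction source {self.reconstruction_source!r}"
            )


def label_map_for_task(task: str) -> BinaryLabelMap:
    maps = {"arousal": AROUSAL_MAP, "valence": VALENCE_MAP}
    try:
        return maps[task]
    except KeyError:
        raise ValueError(f"unknown binary task {task!r}") from None


# ---------------------------------------------------------------------------
# Partitioning and reconstruction-set assembly
# ---------------------------------------------------------------------------


def _random_split(
    labels: np.ndarray,
    train_ratio: float,
    rng: np.random.Generator,
    max_resample: int,
) -> tuple[np.ndarray, np.ndarray]:
    n = labels.shape[0]
    n_train = int(round(train_ratio * n))
    if n_train < 1 or n_train >= n:
        raise PartitionError(f"degenerate split sizes for n={n}")
    for _ in range(max_resample):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if len(set(labels[train])) >= 2 and len(set(labels[test])) >= 2:
            return np.sort(train), np.sort(test)
    raise PartitionError(
        f"could not produce a split with both classes in {max_resample} attempts"
    )


def make_partitions(
    table: pd.DataFrame,
    spec: ProtocolSpec,
    n_trials: int | None = None,
    speaker: str | None = None,
    label_map: BinaryLabelMap | None = None,
    seed: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Produce (train, test) positional index pairs into ``table``.

    ``speaker_dependent_repeated`` splits the designated speaker's rows into
    random halves ``n_trials`` times (resampling, boundedly, if a class is
    absent from either side).  ``loso_speaker_independent`` yields one fold per
    speaker with that speaker held out entirely.  Reproducible from the seed.
    """
    if spec.mode == "loso_speaker_independent":
        folds = []
        speakers = sorted(table["speaker_id"].unique())
        if len(speakers) < 2:
            raise PartitionError("LOSO needs at least two speakers")
        pos = np.arange(len(table))
        spk = table["speaker_id"].to_numpy()
        for s in speakers:
            test = pos[spk == s]
            train = pos[spk != s]
            folds.append((train, test))
        return folds

    if speaker is None:
        raise ValueError("speaker_dependent_repeated mode needs a designated speaker")
    if n_trials is None:
        raise ValueError("speaker_dependent_repeated mode needs n_trials")
    pool = np.flatnonzero((table["speaker_id"] == speaker).to_numpy())
    if pool.size < 4:
        raise PartitionError(f"speaker {speaker!r} has too few segments")
    if label_map is not None:
        labels = binarize_labels(table["emotion"].iloc[pool].tolist(), label_map)
    else:
        labels = table["emotion"].iloc[pool].to_numpy()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    partitions = []
    for _ in range(n_trials):
        train_loc, test_loc = _random_split(
            np.asarray(labels), spec.train_ratio, rng, spec.max_resample
        )
        partitions.append((pool[train_loc], pool[test_loc]))
    return partitions


def assemble_reconstruction_set(
    target_tables: dict[str, pd.DataFrame],
    spec: ProtocolSpec,
    test_speaker: str,
    classification_corpus: str,
) -> pd.DataFrame:
    """Rows eligible for the articulatory reconstruction term.

    ``same_corpus_loso``: every non-test speaker of the classification corpus.
    ``other_corpus``: the entire other corpus.  The test speaker's segments are
    never included (asserted structurally).
    """
    if spec.reconstruction_source == "same_corpus_loso":
        df = target_tables[classification_corpus]
        out = df[df["speaker_id"] != test_speaker]
    else:
        others = [c for c in target_tables if c != classification_corpus]
        if not others:
            raise ValueError("other_corpus mode needs a second corpus")
        out = pd.concat([target_tables[c] for c in others], axis=0)
    if out.empty:
        raise PartitionError("empty reconstruction pool")
    assert not (out["speaker_id"] == test_speaker).any()
    return out.reset_index(drop=True)


def classification_set_from_table(
    table: pd.DataFrame,
    label_map: BinaryLabelMap,
    feature_cols: Sequence[str] | None = None,
) -> ClassificationSet:
    if feature_cols is None:
        feature_cols, _ = split_feature_target_columns(table)
    X = table[list(feature_cols)].to_numpy(dtype=float)
    y = binarize_labels(table["emotion"].tolist(), label_map)
    return ClassificationSet(X, y)


def reconstruction_set_from_table(
    table: pd.DataFrame,
    feature_cols: Sequence[str] | None = None,
    target_cols: Sequence[str] | None = None,
) -> ReconstructionSet:
    auto_feat, auto_targ = split_feature_target_columns(table)
    feature_cols = list(feature_cols) if feature_cols is not None else auto_feat
    target_cols = list(target_cols) if target_cols is not None else auto_targ
    return ReconstructionSet(
        table[feature_cols].to_numpy(dtype=float),
        table[target_cols].to_numpy(dtype=float),
        tuple(target_cols),
    )


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass
class GridSearchResult:
    """Outcome of one lambda search + evaluation run."""

    selected: tuple[float, float]
    selection_table: pd.DataFrame  # lambda1, lambda2, mean_uar, sd_uar, n_trials
    evaluation_uars: np.ndarray
    evaluation_mean_uar: float
    per_fold_selected: dict[str, tuple[float, float]] = field(default_factory=dict)

    def report_csv(self, path) -> None:
        self.selection_table.to_csv(path, index=False)


def _fit_and_score(
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    recon: ReconstructionSet | None,
    label_map: BinaryLabelMap,
    lambdas: tuple[float, float],
    feature_cols: Sequence[str],
    tolerance: float,
    max_iter: int,
) -> float:
    data = classification_set_from_table(train_df, label_map, feature_cols)
    model = fit_multi_target(
        data,
        recon if lambdas[1] > 0 else None,
        RegularizationConfig(lambdas[0], lambdas[1]),
        feature_names=feature_cols,
        tolerance=tolerance,
        max_iter=max_iter,
    )
    X_test = test_df[list(feature_cols)].to_numpy(dtype=float)
    y_test = binarize_labels(test_df["emotion"].tolist(), label_map)
    y_hat = decide_binary(posterior_averaged(model, X_test))
    return uar(confusion_matrix(y_test, y_hat, classes=(0, 1)))


def _tie_break_argmax(
    points: Sequence[tuple[float, float]], scores: Sequence[float]
) -> tuple[float, float]:
    best = None
    best_key = None
    for (l1, l2), s in zip(points, scores):
        if np.isnan(s):
            continue
        key = (s, l1, -l2)  # higher score, then larger l1, then smaller l2
        if best_key is None or key > best_key:
            best_key, best = key, (l1, l2)
    if best is None:
        raise RuntimeError("every grid point failed to fit")
    return best


def grid_search(
    features: pd.DataFrame,
    target_tables: dict[str, pd.DataFrame],
    grid: LambdaGrid,
    spec: ProtocolSpec,
    task: str = "valence",
    speaker: str | None = None,
    classification_corpus: str | None = None,
    tolerance: float = 1e-5,
    max_iter: int = 10_000,
) -> GridSearchResult:
    """Exhaustive lambda search under the configured protocol.

    Selection recall is computed only on selection trials/folds and the
    reported evaluation recall only on evaluation trials (or held-out folds);
    fit failures at a grid point count as missing rather than zero.
    """
    label_map = label_map_for_task(task)
    feature_cols, _ = split_feature_target_columns(features)
    if classification_corpus is None:
        classification_corpus = str(features["corpus_id"].iloc[0])
    points = grid.points()
    ss = np.random.SeedSequence(spec.seed)
    sel_seed, eval_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]

    if spec.mode == "speaker_dependent_repeated":
        if speaker is None:
            raise ValueError("speaker_dependent_repeated mode needs a speaker")
        recon_df = assemble_reconstruction_set(
            target_tables, spec, speaker, classification_corpus
        )
        recon = reconstruction_set_from_table(recon_df, feature_cols=feature_cols)
        sel_parts = make_partitions(
            features, spec, spec.selection_trials, speaker, label_map, seed=sel_seed
        )
        rows = []
        means = []
        for l1, l2 in points:
            scores = []
            for train_idx, test_idx in sel_parts:
                try:
                    scores.append(
                        _fit_and_score(
                            features.iloc[train_idx],
                            features.iloc[test_idx],
                            recon,
                            label_map,
                            (l1, l2),
                            feature_cols,
                            tolerance,
                            max_iter,
                        )
                    )
                except (ConvergenceError, PartitionError):
                    continue
            mean = float(np.mean(scores)) if scores else float("nan")
            sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
            rows.append(
                {"lambda1": l1, "lambda2": l2, "mean_uar": mean, "sd_uar": sd,
                 "n_trials": len(scores)}
            )
            means.append(mean)
        selected = _tie_break_argmax(points, means)

        eval_parts = make_partitions(
            features, spec, spec.evaluation_trials, speaker, label_map, seed=eval_seed
        )
        eval_uars = []
        for train_idx, test_idx in eval_parts:
            eval_uars.append(
                _fit_and_score(
                    features.iloc[train_idx],
                    features.iloc[test_idx],
                    recon,
                    label_map,
                    selected,
                    feature_cols,
                    tolerance,
                    max_iter,
                )
            )
        eval_uars = np.asarray(eval_uars)
        return GridSearchResult(
            selected=selected,
            selection_table=pd.DataFrame(rows),
            evaluation_uars=eval_uars,
            evaluation_mean_uar=float(np.mean(eval_uars)),
        )

    # -- LOSO speaker-independent ------------------------------------------
    folds = make_partitions(features, spec)
    speakers = sorted(features["speaker_id"].unique())
    fold_scores = np.full((len(points), len(folds)), np.nan)
    for f, ((train_idx, test_idx), spk) in enumerate(zip(folds, speakers)):
        recon_df = assemble_reconstruction_set(
            target_tables, spec, spk, classification_corpus
        )
        recon = reconstruction_set_from_table(recon_df, feature_cols=feature_cols)
        for p, (l1, l2) in enumerate(points):
            try:
                fold_scores[p, f] = _fit_and_score(
                    features.iloc[train_idx],
                    features.iloc[test_idx],
                    recon,
                    label_map,
                    (l1, l2),
                    feature_cols,
                    tolerance,
                    max_iter,
                )
            except (ConvergenceError, PartitionError):
                continue

    rows = [
        {
            "lambda1": l1,
            "lambda2": l2,
            "mean_uar": float(np.nanmean(fold_scores[p])),
            "sd_uar": float(np.nanstd(fold_scores[p], ddof=1))
            if np.sum(~np.isnan(fold_scores[p])) > 1
            else 0.0,
            "n_trials": int(np.sum(~np.isnan(fold_scores[p]))),
        }
        for p, (l1, l2) in enumerate(points)
    ]

    per_fold_selected: dict[str, tuple[float, float]] = {}
    eval_uars = []
    if spec.pooled_selection:
        pooled = [float(np.nanmean(fold_scores[p])) for p in range(len(points))]
        selected = _tie_break_argmax(points, pooled)
        sel_idx = points.index(selected)
        for f, spk in enumerate(speakers):
            per_fold_selected[spk] = selected
            eval_uars.append(fold_scores[sel_idx, f])
    else:
        # nested: the fold being evaluated is excluded from its own selection
        for f, spk in enumerate(speakers):
            others = [g for g in range(len(folds)) if g != f]
            means = [float(np.nanmean(fold_scores[p][others])) for p in range(len(points))]
            sel_f = _tie_break_argmax(points, means)
            per_fold_selected[spk] = sel_f
            eval_uars.append(fold_scores[points.index(sel_f), f])
        pooled = [float(np.nanmean(fold_scores[p])) for p in range(len(points))]
        selected = _tie_break_argmax(points, pooled)

    eval_uars = np.asarray(eval_uars, dtype=float)
    return GridSearchResult(
        selected=selected,
        selection_table=pd.DataFrame(rows),
        evaluation_uars=eval_uars,
        evaluation_mean_uar=float(np.nanmean(eval_uars)),
        per_fold_selected=per_fold_selected,
    )
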