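"""Posterior computation and label assignment.

Recognition needs acoustic features only: the posterior for one weight column
is sigma(w_k . x) on the model's stored feature scaling, the multi-target
posterior is the arithmetic mean of the per-target posteriors (optionally
restricted to a subset of targets or one anatomical group, which lets single
targets or groups be ablated without retraining), and categorical decisions
take the argmax over one-vs-rest class models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acl_core import ACLModel, sigmoid

__all__ = [
    "CANONICAL_CLASS_ORDER",
    "PosteriorEstimate",
    "CategoricalDecision",
    "posterior_single",
    "posterior_averaged",
    "decide_binary",
    "decide_categorical",
    "reconstruct_targets",
    "predictions_frame",
]

# Tie-breaking order for categorical decisions.
CANONICAL_CLASS_ORDER: tuple[str, ...] = ("neutral", "angry", "sad", "happy")


@dataclass
class PosteriorEstimate:
    """Averaged posterior p(y=1|x) per sample plus the contributing targets."""

    p: np.ndarray
    target_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("posterior outside [0, 1]")


@dataclass
class CategoricalDecision:
    """Argmax-of-posteriors decision over one-vs-rest class models."""

    labels: np.ndarray
    class_order: tuple[str, ...]
    posteriors: np.ndarray  # (n_samples, n_classes), columns in class_order


def posterior_single(w: np.ndarray, x: np.ndarray) -> np.ndarray | float:
    """sigma(w . x) for raw weight/feature vectors (no scaling applied)."""
    w = np.asarray(w, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if x.shape[0] != w.shape[0]:
            raise ValueError("dimension mismatch between w and x")
        return float(sigmoid(float(w @ x)))
    if x.shape[1] != w.shape[0]:
        raise ValueError("dimension mismatch between w and x")
    return sigmoid(x @ w)


def _resolve_subset(
    model: ACLModel,
    target_subset: Sequence[str] | None,
    group: str | None,
) -> list[int]:
    if target_subset is not None and group is not None:
        raise ValueError("give either target_subset or group, not both")
    if group is not None:
        idx = [k for k, g in enumerate(model.target_groups) if g == group]
        if not idx:
            raise ValueError(f"no targets in group {group!r}")
        return idx
    if target_subset is None:
        return list(range(model.n_targets))
    if len(target_subset) == 0:
        raise ValueError("target subset must be nonempty")
    return [model.target_index(name) for name in target_subset]


def posterior_averaged(
    model: ACLModel,
    X: np.ndarray,
    target_subset: Sequence[str] | None = None,
    group: str | None = None,
) -> PosteriorEstimate:
    """Mean of per-target posteriors over the chosen targets (all by default).

    Applies the model's stored feature standardization; articulatory inputs are
    never read.
    """
    idx = _resolve_subset(model, target_subset, group)
    Xs = model.scale_features(X)
    P = sigmoid(Xs @ model.W[:, idx])
    return PosteriorEstimate(
        p=P.mean(axis=1),
        target_names=tuple(model.target_names[k] for k in idx),
    )


def decide_binary(p: PosteriorEstimate | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 iff posterior >= threshold (default 0.5)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    probs = p.p if isinstance(p, PosteriorEstimate) else np.atleast_1d(np.asarray(p, float))
    return (probs >= threshold).astype(int)


def decide_categorical(
    models: Mapping[str, ACLModel],
    X: np.ndarray,
    target_subset: Sequence[str] | None = None,
    group: str | None = None,
    class_order: Sequence[str] | None = None,
) -> CategoricalDecision:
    """One-vs-rest decision: argmax over per-class averaged posteriors.

    Exact ties resolve to the earliest class in the canonical order
    (neutral, angry, sad, happy).
    """
    if len(models) < 2:
        raise ValueError("need at least two one-vs-rest class models")
    if class_order is None:
        class_order = [c for c in CANONICAL_CLASS_ORDER if c in models]
        class_order += [c for c in models if c not in class_order]
    class_order = tuple(class_order)
    if set(class_order) != set(models):
        raise ValueError("class_order must name exactly the model classes")
    dims = {models[c].n_features for c in class_order}
    if len(dims) != 1:
        raise ValueError("class models have inconsistent feature spaces")

    cols = [
        posterior_averaged(models[c], X, target_subset=target_subset, group=group).p
        for c in class_order
    ]
    P = np.column_stack(cols)
    winners = np.argmax(P, axis=1)  # argmax takes the first maximum: tie rule
    labels = np.array([class_order[j] for j in winners])
    return CategoricalDecision(labels=labels, class_order=class_order, posteriors=P)


def reconstruct_targets(model: ACLModel, X: np.ndarray) -> np.ndarray:
    """Linear reconstruction of every articulatory target from acoustics,
    mapped back through the stored target scaling (physical units)."""
    Xs = model.scale_features(X)
    return Xs @ model.W * model.target_scale + model.target_center


def predictions_frame(
    segment_ids: Sequence[str],
    estimate: PosteriorEstimate,
    decisions: np.ndarray,
) -> pd.DataFrame:
    """Standard prediction output table (CSV-ready)."""
    return pd.DataFrame(
        {
            "segment_id": list(segment_ids),
            "posterior": estimate.p,
            "decision": decisions,
            "target_subset": ";".join(estimate.target_names),
        }
    )
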