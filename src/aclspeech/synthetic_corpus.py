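"""Synthetic two-corpus generator.

Emulates the statistical structure the articulation-constrained model assumes:
supra-segmental acoustic features with additive speaker and corpus effects,
articulatory targets tied to the features through sparse linear maps, and
emotion labels whose own sparse weight vector partially shares support with
the target weights.  The overlap fraction rho is the knob that controls how
much the articulatory reconstruction task can transfer to classification:
rho = 0 makes the reconstruction term uninformative for the labels by
construction.

Two target layouts mirror the two kinds of articulatory instrumentation found
in real corpora: an electromagnetic-articulography layout (tongue/jaw/lip x
position/velocity/acceleration x X/Y axes, 18 targets) and a facial-marker
layout (five chin/lip markers x X/Y/Z axes, 15 targets).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .acl_core import sigmoid

__all__ = [
    "GeneratorSpec",
    "SyntheticTruth",
    "EMA_TARGET_LAYOUT",
    "MARKER_TARGET_LAYOUT",
    "target_layout",
    "generate_corpus",
    "generate_paired_corpora",
]

# Canonical emotion inventory and class order used throughout the package.
EMOTIONS = ("neutral", "angry", "sad", "happy")

# 18 targets: three sensor locations x {position, velocity, acceleration} x
# {forward-backward X, vertical Y}.
EMA_TARGET_LAYOUT = tuple(
    f"{loc}_{attr}_{axis}"
    for loc in ("TNG", "JAW", "LIP")
    for attr in ("POS", "VEL", "ACC")
    for axis in ("X", "Y")
)

# 15 targets: five facial-marker attributes x {X, Y, Z}.
MARKER_TARGET_LAYOUT = tuple(
    f"{attr}_{axis}"
    for attr in ("CHP", "CHW", "LPP", "LPH", "LPW")
    for axis in ("X", "Y", "Z")
)


def target_layout(name: str) -> tuple[str, ...]:
    """Named target layouts: "ema" (18 targets) or "marker" (15 targets)."""
    layouts = {"ema": EMA_TARGET_LAYOUT, "marker": MARKER_TARGET_LAYOUT}
    try:
        return layouts[name]
    except KeyError:
        raise ValueError(f"unknown layout {name!r}; choose from {sorted(layouts)}") from None


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic corpus.

    Defaults give a corpus of realistic desk scale: 400 segments from 3
    speakers, the full 150-dimensional feature space, the 18-target
    articulography layout, sparse supports of size 10 with 80% overlap between
    the label support and each target support, and moderate noise everywhere
    (target noise and speaker/corpus effects at half the unit feature scale).
    """

    n_segments: int = 400
    n_speakers: int = 3
    n_features: int = 150
    layout: str = "ema"
    targets: tuple[str, ...] | None = None  # overrides layout when given
    s_label: int = 10
    s_target: int = 10
    rho: float = 0.8
    weight_magnitude: float = 1.0
    label_flip_rate: float = 0.0
    target_noise_sd: float = 0.5
    speaker_sd: float = 0.5
    corpus_shift_sd: float = 0.5
    categorical: bool = False
    corpus_id: str = "E"
    seed: int = 0

    def target_names(self) -> tuple[str, ...]:
        if self.targets is not None:
            return tuple(self.targets)
        return target_layout(self.layout)

    def validate(self) -> None:
        D = self.n_features
        if not (0 < self.s_label <= D and 0 < self.s_target <= D):
            raise ValueError("support sizes must be in 1..D")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.n_speakers < 1 or self.n_segments < self.n_speakers:
            raise ValueError("need at least one segment per speaker")
        overlap = self.overlap_size()
        if self.s_target - overlap > D - self.s_label:
            raise ValueError("not enough off-support coordinates for the targets")

    def overlap_size(self) -> int:
        return int(round(self.rho * min(self.s_label, self.s_target)))


@dataclass
class SyntheticTruth:
    """Ground-truth weights and supports stored alongside a generated corpus."""

    label_weights: np.ndarray  # (D,) or (4, D) in categorical mode
    target_weights: np.ndarray  # (D, K)
    label_support: np.ndarray  # sorted indices
    target_supports: tuple[np.ndarray, ...]
    spec: GeneratorSpec

    def to_json_dict(self) -> dict:
        return {
            "label_weights": np.asarray(self.label_weights).tolist(),
            "target_weights": self.target_weights.tolist(),
            "label_support": self.label_support.tolist(),
            "target_supports": [s.tolist() for s in self.target_supports],
        }


def _draw_truth(spec: GeneratorSpec, rng: np.random.Generator) -> SyntheticTruth:
    D = spec.n_features
    names = spec.target_names()
    K = len(names)
    mag = spec.weight_magnitude

    label_support = np.sort(rng.choice(D, size=spec.s_label, replace=False))
    if spec.categorical:
        label_weights = np.zeros((4, D))
        for c in range(4):
            signs = rng.choice((-1.0, 1.0), size=spec.s_label)
            label_weights[c, label_support] = mag * signs
        shared = label_weights[0]  # overlap values copied from the first class
    else:
        label_weights = np.zeros(D)
        label_weights[label_support] = mag * rng.choice((-1.0, 1.0), size=spec.s_label)
        shared = label_weights

    overlap = spec.overlap_size()
    off_support = np.setdiff1d(np.arange(D), label_support)
    target_weights = np.zeros((D, K))
    supports = []
    for k in range(K):
        on = rng.choice(label_support, size=overlap, replace=False)
        extra = rng.choice(off_support, size=spec.s_target - overlap, replace=False)
        support_k = np.sort(np.concatenate([on, extra]).astype(int))
        # shared coordinates inherit the label weight (consistent sign), the
        # rest get fresh random-sign weights
        target_weights[on, k] = shared[on]
        target_weights[extra, k] = mag * rng.choice((-1.0, 1.0), size=extra.size)
        supports.append(support_k)
    return SyntheticTruth(
        label_weights=label_weights,
        target_weights=target_weights,
        label_support=label_support,
        target_supports=tuple(supports),
        spec=spec,
    )


def generate_corpus(
    spec: GeneratorSpec,
    truth: SyntheticTruth | None = None,
    feature_names: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one corpus: a segment feature table, an articulatory target
    table over the same segments, and the generating truth.

    Fully reproducible from ``spec.seed``.  Passing an explicit ``truth``
    (e.g. from a paired corpus) reuses its weights instead of drawing new ones.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_truth, rng_data = [np.random.default_rng(s) for s in ss.spawn(2)]
    if truth is None:
        truth = _draw_truth(spec, rng_truth)

    n, D = spec.n_segments, spec.n_features
    names = spec.target_names()
    K = len(names)
    if feature_names is None:
        feature_names = tuple(f"F{i}" for i in range(D))
    feature_names = tuple(feature_names)
    if len(feature_names) != D:
        raise ValueError("feature_names length must equal n_features")

    speakers = np.arange(n) % spec.n_speakers
    base = rng_data.standard_normal((n, D))
    speaker_offsets = spec.speaker_sd * rng_data.standard_normal((spec.n_speakers, D))
    corpus_shift = spec.corpus_shift_sd * rng_data.standard_normal(D)
    X = base + speaker_offsets[speakers] + corpus_shift

    A = X @ truth.target_weights
    if spec.target_noise_sd > 0:
        A = A + spec.target_noise_sd * rng_data.standard_normal((n, K))

    if spec.categorical:
        logits = X @ truth.label_weights.T  # (n, 4)
        gumbel = rng_data.gumbel(size=logits.shape)
        classes = np.argmax(logits + gumbel, axis=1)
        emotions = np.array(EMOTIONS)[classes]
    else:
        p = sigmoid(X @ truth.label_weights)
        y = (rng_data.random(n) < p).astype(int)
        if spec.label_flip_rate > 0:
            flips = rng_data.random(n) < spec.label_flip_rate
            y = np.where(flips, 1 - y, y)
        # happy / sad sit on the positive / negative side of BOTH binary axes,
        # so a binary corpus supports arousal and valence maps alike
        emotions = np.where(y == 1, "happy", "sad")

    meta = pd.DataFrame(
        {
            "segment_id": [f"{spec.corpus_id}-{i:05d}" for i in range(n)],
            "speaker_id": [f"{spec.corpus_id}-spk{s}" for s in speakers],
            "corpus_id": spec.corpus_id,
            "unit_label": "FULL",
            "emotion": emotions,
        }
    )
    feats = pd.DataFrame(X, columns=list(feature_names))
    features = pd.concat([meta, feats], axis=1)

    targets = pd.concat(
        [
            meta.drop(columns=["unit_label", "emotion"]),
            feats,
            pd.DataFrame(A, columns=list(names)),
        ],
        axis=1,
    )
    return features, targets, truth


def generate_paired_corpora(
    spec_E: GeneratorSpec,
    spec_I: GeneratorSpec,
    shared_truth: bool = True,
) -> tuple[tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth],
           tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]]:
    """Generate two corpora with distinct corpus shifts and target layouts.

    With ``shared_truth`` the second corpus reuses the first corpus's label
    weights when drawing its own target weights, so its articulatory targets
    carry transferable information about the labels of the first corpus (the
    cross-corpus setting).  Without it the two corpora are generated
    independently.
    """
    if spec_E.n_features != spec_I.n_features:
        raise ValueError("paired corpora must share the feature dimension")
    E = generate_corpus(spec_E)
    if shared_truth:
        truth_E = E[2]
        ss = np.random.SeedSequence(spec_I.seed)
        rng_truth = np.random.default_rng(ss.spawn(1)[0])
        spec_I.validate()
        # corpus I's target supports are drawn around corpus E's label truth,
        # so they overlap the SAME label support
        truth_I = _retarget_truth(spec_I, truth_E, rng_truth)
        I = generate_corpus(spec_I, truth=truth_I)
    else:
        I = generate_corpus(spec_I)
    return E, I


def _retarget_truth(
    spec: GeneratorSpec, base: SyntheticTruth, rng: np.random.Generator
) -> SyntheticTruth:
    """Draw target weights for ``spec``'s layout around ``base``'s label truth."""
    D = spec.n_features
    names = spec.target_names()
    K = len(names)
    label_support = base.label_support
    shared = (
        base.label_weights[0] if base.label_weights.ndim == 2 else base.label_weights
    )
    overlap = spec.overlap_size()
    off_support = np.setdiff1d(np.arange(D), label_support)
    target_weights = np.zeros((D, K))
    supports = []
    for k in range(K):
        on = rng.choice(label_support, size=overlap, replace=False)
        extra = rng.choice(off_support, size=spec.s_target - overlap, replace=False)
        target_weights[on, k] = shared[on]
        target_weights[extra, k] = spec.weight_magnitude * rng.choice(
            (-1.0, 1.0), size=extra.size
        )
        supports.append(np.sort(np.concatenate([on, extra]).astype(int)))
    return SyntheticTruth(
        label_weights=base.label_weights,
        target_weights=target_weights,
        label_support=label_support,
        target_supports=tuple(supports),
        spec=spec,
    )
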