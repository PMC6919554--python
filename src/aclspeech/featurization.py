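"""Supra-segmental feature construction.

Frame-level low-level descriptors (LLDs) — by default the energies of 26 Mel
filter banks, pitch, the first two formants, and overall intensity, extracted
at 200 frames/s — are summarized per vowel segment (or full utterance) by five
statistics: mean, standard deviation, minimum, maximum, and range.  With the
default 30-descriptor registry this yields a 150-dimensional acoustic feature
vector per segment.  Articulatory target trajectories are summarized by their
mean over the segment.  Categorical emotions are mapped onto two binary axes:
arousal (happy/angry vs neutral/sad) and valence (happy/neutral vs angry/sad).

Missing frames (e.g. pitch in unvoiced regions) are carried as NaN and masked
from all five statistics; a trajectory with no observed frames at all is an
error, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LLDTrajectory",
    "BinaryLabelMap",
    "AROUSAL_MAP",
    "VALENCE_MAP",
    "DEFAULT_LLD_REGISTRY",
    "STATISTICS",
    "FRAME_RATE_HZ",
    "METADATA_COLUMNS",
    "AggregationError",
    "FeaturizationError",
    "aggregate_statistics",
    "build_feature_table",
    "aggregate_articulatory_targets",
    "binarize_labels",
    "feature_column_names",
    "split_feature_target_columns",
    "read_frame_csv",
    "read_feature_table",
    "read_target_table",
]

# Frame rate of the LLD trajectories; metadata only, no resampling happens here.
FRAME_RATE_HZ = 200.0

# 26 Mel-filter-bank energies + pitch + first two formants + overall intensity.
DEFAULT_LLD_REGISTRY: tuple[str, ...] = tuple(
    [f"MFB{i:02d}" for i in range(1, 27)] + ["PITCH", "F1", "F2", "INTENSITY"]
)

# Statistic order is part of the deterministic column layout.
STATISTICS: tuple[str, ...] = ("MEAN", "STD", "MIN", "MAX", "RNG")

METADATA_COLUMNS: tuple[str, ...] = (
    "segment_id",
    "speaker_id",
    "corpus_id",
    "unit_label",
    "emotion",
)


class AggregationError(ValueError):
    """A trajectory had no observed (non-missing) frames."""


class FeaturizationError(ValueError):
    """A segment is missing one or more required descriptors."""


@dataclass
class LLDTrajectory:
    """One descriptor's frame values over one segment; NaN marks missing frames."""

    segment_id: str
    lld_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError(
                f"trajectory {self.lld_name!r} of segment {self.segment_id!r} is empty"
            )


@dataclass(frozen=True)
class BinaryLabelMap:
    """Partition of the categorical emotions into a positive and negative set."""

    axis: str
    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative sets overlap")


AROUSAL_MAP = BinaryLabelMap(
    "arousal", frozenset({"happy", "angry"}), frozenset({"neutral", "sad"})
)
VALENCE_MAP = BinaryLabelMap(
    "valence", frozenset({"happy", "neutral"}), frozenset({"angry", "sad"})
)


def aggregate_statistics(trajectory: LLDTrajectory) -> np.ndarray:
    """Five statistics (mean, sample std, min, max, range) over observed frames.

    The standard deviation uses the n-1 denominator and is defined as 0 for a
    single observed frame.
    """
    vals = trajectory.values
    observed = vals[~np.isnan(vals)]
    if observed.size == 0:
        raise AggregationError(
            f"all frames missing for descriptor {trajectory.lld_name!r} "
            f"of segment {trajectory.segment_id!r}"
        )
    std = float(np.std(observed, ddof=1)) if observed.size > 1 else 0.0
    lo, hi = float(np.min(observed)), float(np.max(observed))
    return np.array([float(np.mean(observed)), std, lo, hi, hi - lo])


def feature_column_names(registry: Sequence[str] = DEFAULT_LLD_REGISTRY) -> list[str]:
    """Deterministic column layout: registry order x statistic order."""
    return [f"{lld}_{stat}" for lld in registry for stat in STATISTICS]


def build_feature_table(
    trajectories: Iterable[LLDTrajectory],
    metadata: pd.DataFrame,
    registry: Sequence[str] = DEFAULT_LLD_REGISTRY,
) -> pd.DataFrame:
    """Assemble the per-segment feature table (one row per segment).

    ``metadata`` must have one row per segment with the standard metadata
    columns.  Every segment needs all registry descriptors present; missing
    descriptors raise :class:`FeaturizationError` naming them.
    """
    registry = list(registry)
    meta = metadata.copy()
    missing_meta = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_meta:
        raise ValueError(f"metadata lacks columns: {missing_meta}")
    if meta["segment_id"].duplicated().any():
        dupes = meta.loc[meta["segment_id"].duplicated(), "segment_id"].tolist()
        raise ValueError(f"duplicate segment_id in metadata: {dupes}")

    by_segment: dict[str, dict[str, LLDTrajectory]] = {}
    for traj in trajectories:
        by_segment.setdefault(traj.segment_id, {})[traj.lld_name] = traj

    rows = []
    for seg in meta["segment_id"]:
        have = by_segment.get(seg, {})
        absent = [lld for lld in registry if lld not in have]
        if absent:
            raise FeaturizationError(
                f"segment {seg!r} is missing descriptors: {absent}"
            )
        rows.append(
            np.concatenate([aggregate_statistics(have[lld]) for lld in registry])
        )
    feats = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, 5 * len(registry))),
        columns=feature_column_names(registry),
        index=meta.index,
    )
    out = pd.concat([meta[list(METADATA_COLUMNS)], feats], axis=1)
    if not np.all(np.isfinite(feats.to_numpy())):
        raise FeaturizationError("non-finite feature values after aggregation")
    return out


def aggregate_articulatory_targets(
    target_trajectories: Mapping[str, Mapping[str, np.ndarray]],
    metadata: pd.DataFrame,
    feature_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean of each articulatory target trajectory per segment.

    ``target_trajectories`` maps segment_id -> {target_name -> frame values}.
    When ``feature_table`` is given, its feature columns are joined in so the
    result is a complete articulatory target table (features + targets).
    """
    target_names: list[str] = []
    for per_seg in target_trajectories.values():
        for name in per_seg:
            if name not in target_names:
                target_names.append(name)

    rows = []
    for seg in metadata["segment_id"]:
        per_seg = target_trajectories.get(seg, {})
        values = []
        for name in target_names:
            traj = np.asarray(per_seg.get(name, []), dtype=float).ravel()
            observed = traj[~np.isnan(traj)]
            if observed.size == 0:
                raise AggregationError(
                    f"empty trajectory for target {name!r} of segment {seg!r}"
                )
            values.append(float(np.mean(observed)))
        rows.append(values)

    targets = pd.DataFrame(rows, columns=target_names, index=metadata.index)
    base = metadata[["segment_id", "speaker_id", "corpus_id"]].copy()
    if feature_table is not None:
        feat_cols, _ = split_feature_target_columns(feature_table)
        feats = feature_table.set_index("segment_id").loc[
            base["segment_id"], feat_cols
        ]
        feats.index = base.index
        return pd.concat([base, feats, targets], axis=1)
    return pd.concat([base, targets], axis=1)


def binarize_labels(emotions: Sequence[str], label_map: BinaryLabelMap) -> np.ndarray:
    """Map categorical emotions to 0/1 along one binary axis."""
    out = np.empty(len(emotions), dtype=int)
    for i, emo in enumerate(emotions):
        if emo in label_map.positive:
            out[i] = 1
        elif emo in label_map.negative:
            out[i] = 0
        else:
            raise ValueError(
                f"unknown emotion label {emo!r} for axis {label_map.axis!r}"
            )
    return out


def split_feature_target_columns(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split non-metadata columns into acoustic features (named <LLD>_<STAT>)
    and articulatory targets (everything else)."""
    stat_suffixes = tuple(f"_{s}" for s in STATISTICS)
    feat, targ = [], []
    for col in df.columns:
        if col in METADATA_COLUMNS:
            continue
        (feat if col.endswith(stat_suffixes) or col.startswith("F") else targ).append(col)
    return feat, targ


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def read_frame_csv(
    path, registry: Sequence[str] = DEFAULT_LLD_REGISTRY
) -> tuple[list[LLDTrajectory], pd.DataFrame]:
    """Read long-format frame-level CSV (one row per frame, one column per LLD,
    empty cells for missing frames) into trajectories plus segment metadata."""
    df = pd.read_csv(path)
    required = [c for c in METADATA_COLUMNS if c != "emotion"] + ["frame_index"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FeaturizationError(f"frame CSV lacks columns: {missing}")
    if "emotion" not in df.columns:
        df["emotion"] = "neutral"
    absent = [lld for lld in registry if lld not in df.columns]
    if absent:
        raise FeaturizationError(f"frame CSV lacks descriptor columns: {absent}")

    df = df.sort_values(["segment_id", "frame_index"], kind="stable")
    trajectories = []
    meta_rows = []
    for seg, grp in df.groupby("segment_id", sort=True):
        meta_rows.append(grp.iloc[0][list(METADATA_COLUMNS)])
        for lld in registry:
            trajectories.append(
                LLDTrajectory(str(seg), lld, grp[lld].to_numpy(dtype=float))
            )
    metadata = pd.DataFrame(meta_rows).reset_index(drop=True)
    return trajectories, metadata


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FeaturizationError(f"feature table lacks columns: {missing}")
    return df


def read_target_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("segment_id", "speaker_id", "corpus_id") if c not in df.columns]
    if missing:
        raise FeaturizationError(f"target table lacks columns: {missing}")
    return df
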