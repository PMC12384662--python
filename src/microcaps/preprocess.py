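"""Segmentation, dimensionality expansion and data splitting.

A recording is cut into fixed-length sliding windows (default 1 s, no
overlap). Each 1-D window is then expanded into a near-square 2-D matrix —
row-major fill, zero-padded at the tail when the window length has no
balanced factorisation — which is what the convolutional front end of the
capsule network consumes. Splitting follows the study protocol: shuffle,
stratified 7:3 train/test partition, then 3-fold cross-validation over the
training portion.

Two named presets pin the window length:

``table1``
    342 points, reshaped (19, 18) with no padding — the reference layout.
``ucistyle``
    178 points (the UCI-style segment length), padded to 180 -> (15, 12).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .bonn import BONN_FS, Recording

__all__ = [
    "SegmentationConfig",
    "Segment",
    "SplitPlan",
    "PRESETS",
    "segment_recording",
    "segment_labeled_recordings",
    "factorize_length",
    "expand_dims",
    "flatten_matrix",
    "standardize",
    "make_splits",
    "segments_to_csv",
    "segments_from_csv",
]


@dataclass
class SegmentationConfig:
    """Sliding-window parameters.

    window_s: window length in seconds (1.0 by default). overlap_frac:
    overlap between consecutive windows as a fraction of the window, in
    [0, 1). window_pts, when given, overrides the round(window_s * fs)
    derivation (used by the presets).
    """

    window_s: float = 1.0
    overlap_frac: float = 0.0
    fs: float = BONN_FS
    window_pts: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.overlap_frac < 1.0):
            raise ValueError("overlap_frac must be in [0, 1)")
        if self.window_pts is None:
            self.window_pts = int(round(self.window_s * self.fs))
        if self.window_pts < 2:
            raise ValueError("window must span at least 2 points")

    @property
    def stride(self) -> int:
        return max(1, int(round(self.window_pts * (1.0 - self.overlap_frac))))


PRESETS: dict[str, dict] = {
    "table1": {"window_pts": 342},
    "ucistyle": {"window_pts": 178},
}


def preset_config(name: str, fs: float = BONN_FS, overlap_frac: float = 0.0
                  ) -> SegmentationConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SegmentationConfig(fs=fs, overlap_frac=overlap_frac, **PRESETS[name])


@dataclass
class Segment:
    """One labelled window with provenance (source file, half-open
    0-based sample interval)."""

    values: np.ndarray
    class_idx: int
    source_id: str = ""
    start: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def stop(self) -> int:
        return self.start + self.values.size


def segment_recording(
    rec: Recording, cfg: SegmentationConfig, class_idx: int
) -> list[Segment]:
    """Cut one recording into windows; a trailing remainder shorter than a
    full window is discarded."""
    n, w, s = rec.samples.size, cfg.window_pts, cfg.stride
    if n < w:
        raise ValueError(
            f"recording {rec.source_id or '<anon>'} has {n} samples, "
            f"shorter than one {w}-point window"
        )
    count = (n - w) // s + 1
    return [
        Segment(rec.samples[i * s : i * s + w], class_idx, rec.source_id, i * s)
        for i in range(count)
    ]


def segment_labeled_recordings(
    labeled: list[tuple[Recording, int]], cfg: SegmentationConfig
) -> list[Segment]:
    out: list[Segment] = []
    for rec, class_idx in labeled:
        out.extend(segment_recording(rec, cfg, class_idx))
    return out


def factorize_length(length: int) -> tuple[int, int]:
    """Near-square factor pair (h, w), h >= w, for a window length.

    Searches upward from `length` for the smallest L whose most-square
    factorisation satisfies h/w <= 2; the difference L - length becomes
    zero padding. 342 -> (19, 18); 178 -> pad to 180 -> (15, 12).
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    candidate = length
    while True:
        w = int(math.isqrt(candidate))
        while candidate % w:
            w -= 1
        h = candidate // w
        if h <= 2 * w:
            return h, w
        candidate += 1


def expand_dims(seg: Segment, h: int, w: int) -> np.ndarray:
    """Row-major expansion of a window into an (h, w, 1) matrix; cells past
    the window length are zero."""
    n = seg.values.size
    if h * w < n:
        raise ValueError(f"target {h}x{w} too small for a {n}-point segment")
    grid = np.zeros(h * w)
    grid[:n] = seg.values
    return grid.reshape(h, w, 1)


def flatten_matrix(grid: np.ndarray, n: int) -> np.ndarray:
    """Inverse of expand_dims: row-major flatten, drop the trailing pad."""
    return np.asarray(grid).reshape(-1)[:n]


def standardize(
    segments: list[Segment] | np.ndarray,
    train_indices,
    mean: float | None = None,
    sd: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Z-score all segments using statistics of the training subset only.

    Returns (standardized array of shape (n_segments, window), mean, sd).
    Passing mean/sd explicitly reuses previously fitted statistics (e.g. at
    evaluation time on new data).
    """
    if isinstance(segments, np.ndarray):
        values = np.asarray(segments, dtype=float)
    else:
        values = np.stack([s.values for s in segments])
    if mean is None or sd is None:
        train_indices = np.asarray(train_indices)
        if train_indices.size == 0:
            raise ValueError("training indices must be non-empty")
        train_vals = values[train_indices]
        mean = float(train_vals.mean())
        sd = float(train_vals.std())
        if sd == 0.0:
            raise ValueError("zero variance in training segments")
    return (values - mean) / sd, mean, sd


@dataclass
class SplitPlan:
    """Stratified 7:3 train/test partition plus 3 CV folds over train.

    folds is a list of (fit_idx, val_idx) pairs whose validation parts
    partition train_idx.
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    def validate(self) -> None:
        train, test = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")
        val_union: set[int] = set()
        for fit_idx, val_idx in self.folds:
            fit, val = set(fit_idx.tolist()), set(val_idx.tolist())
            if (fit | val) != train or (fit & val):
                raise ValueError("fold does not partition the training indices")
            if val & val_union:
                raise ValueError("an index appears in two validation folds")
            val_union |= val
        if val_union != train:
            raise ValueError("validation folds do not cover the training indices")


def make_splits(
    labels, seed: int, test_frac: float = 0.3, n_folds: int = 3
) -> SplitPlan:
    """Shuffle, stratified split 7:3, then stratified k-fold over train."""
    labels = np.asarray(labels)
    n = labels.size
    if n < 10:
        raise ValueError("need at least 10 segments to split")
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, random_state=seed, shuffle=True, stratify=labels
    )
    train_labels = labels[train_idx]
    counts = np.bincount(train_labels)
    if counts.min(initial=n) < n_folds:
        scarce = int(np.argmin(counts))
        raise ValueError(
            f"class {scarce} has only {counts[scarce]} training segments; "
            f"need at least {n_folds}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [
        (train_idx[fit], train_idx[val]) for fit, val in skf.split(train_idx, train_labels)
    ]
    plan = SplitPlan(np.sort(train_idx), np.sort(test_idx), folds, seed)
    plan.validate()
    return plan


# -- segment CSV dialect ------------------------------------------------------


def segments_to_csv(path, segments: list[Segment], header: bool = False) -> None:
    """One row per segment: window-many values then the integer class."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if header and segments:
            writer.writerow(
                [f"x{i}" for i in range(segments[0].values.size)] + ["y"]
            )
        for seg in segments:
            writer.writerow([repr(float(v)) for v in seg.values] + [seg.class_idx])


def segments_from_csv(path, header: bool | None = None) -> list[Segment]:
    """Read the segment dialect back; header auto-detected when None."""
    segments: list[Segment] = []
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        return segments
    if header is None:
        try:
            float(rows[0][0])
            header = False
        except ValueError:
            header = True
    for i, row in enumerate(rows[1:] if header else rows):
        if not row:
            continue
        values = np.array([float(v) for v in row[:-1]])
        segments.append(Segment(values, int(row[-1]), source_id=f"csv:{i}"))
    return segments
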