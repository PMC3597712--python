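"""Quasi-stationary segment gluing and the two non-stationarity measures.

Temporally adjacent windows that fall in the same cluster are glued into one
quasi-stationary segment.  A channel's epoch is then summarised by

* ``n_states`` — the number of distinct states (clusters) visited, and
* ``mean_seg_len`` — the mean duration of the glued segments,

the two complementary measures of dynamical non-stationarity: with the state
repertoire fixed, faster alternation shortens the mean segment, while the
repertoire can grow without the segments getting shorter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import SegmentGrid

__all__ = [
    "GluedSegment",
    "StateSequence",
    "NonstatMeasures",
    "glue_segments",
    "compute_measures",
    "average_over_epochs",
]


@dataclass(frozen=True)
class GluedSegment:
    label: int
    first_window: int
    last_window: int
    duration_samples: int
    duration_s: float

    @property
    def n_windows(self) -> int:
        return self.last_window - self.first_window + 1


@dataclass
class StateSequence:
    """Window labels of one epoch/channel plus their maximal same-label runs."""

    labels: np.ndarray
    segments: list[GluedSegment]
    grid: SegmentGrid
    fs: float


@dataclass
class NonstatMeasures:
    """Per-channel non-stationarity summary (single epoch or epoch average)."""

    n_states: float
    mean_seg_len_s: float
    mean_seg_len_samples: float
    n_epochs: int = 1
    subject_id: str = ""
    condition: str = ""
    channel: str = ""


def glue_segments(labels: np.ndarray, grid: SegmentGrid, fs: float) -> StateSequence:
    """Merge maximal runs of equal window labels into quasi-stationary segments.

    A run of k windows spans ``(k-1)*step + window_len`` samples — the full
    temporal support of the run including the overlap hangover of the last
    window.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.size != grid.n_windows:
        raise ValueError(
            f"got {labels.size} labels for {grid.n_windows} windows"
        )
    segments: list[GluedSegment] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            dur = grid.duration_samples(i - start)
            segments.append(
                GluedSegment(
                    label=int(labels[start]),
                    first_window=start,
                    last_window=i - 1,
                    duration_samples=dur,
                    duration_s=dur / fs,
                )
            )
            start = i
    return StateSequence(labels=labels, segments=segments, grid=grid, fs=fs)


def compute_measures(
    seq: StateSequence,
    subject_id: str = "",
    condition: str = "",
    channel: str = "",
) -> NonstatMeasures:
    """Number of distinct states and mean glued-segment duration for one epoch.

    ``n_states`` counts distinct labels appearing in the epoch (not the number
    of glued runs); ``mean_seg_len`` is the arithmetic mean of the glued
    segments' durations.
    """
    durations = np.array([g.duration_samples for g in seq.segments], dtype=float)
    n_states = len(np.unique(seq.labels))
    return NonstatMeasures(
        n_states=float(n_states),
        mean_seg_len_s=float(durations.mean() / seq.fs),
        mean_seg_len_samples=float(durations.mean()),
        n_epochs=1,
        subject_id=subject_id,
        condition=condition,
        channel=channel,
    )


def average_over_epochs(per_epoch: list[NonstatMeasures]) -> NonstatMeasures:
    """Arithmetic mean of the measures across epochs of one subject/condition/channel."""
    if not per_epoch:
        raise ValueError("need at least one epoch")
    keys = {(m.subject_id, m.condition, m.channel) for m in per_epoch}
    if len(keys) > 1:
        raise ValueError(f"mixed subject/condition/channel inputs: {sorted(keys)}")
    return NonstatMeasures(
        n_states=float(np.mean([m.n_states for m in per_epoch])),
        mean_seg_len_s=float(np.mean([m.mean_seg_len_s for m in per_epoch])),
        mean_seg_len_samples=float(np.mean([m.mean_seg_len_samples for m in per_epoch])),
        n_epochs=int(sum(m.n_epochs for m in per_epoch)),
        subject_id=per_epoch[0].subject_id,
        condition=per_epoch[0].condition,
        channel=per_epoch[0].channel,
    )
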