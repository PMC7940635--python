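"""Shared threshold-merge-filter segment caller.

One code path produces both the training labels (from Poisson -log10 p score
tracks at cutoff 3) and the inference-time peak calls (from probability tracks
at cutoff 0.5), mirroring how MACS2's bdgpeakcall is applied to base-pair
resolution score tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import DenseTrack, Interval, IntervalSet

__all__ = ["SegmentCallParams", "call_segments"]


@dataclass(frozen=True)
class SegmentCallParams:
    """Parameters of the segment caller.

    threshold
        Bases with value strictly greater than this seed segments
        (strict so that an exactly-ambivalent 0.5 probability is excluded).
    min_len
        Segments shorter than this many bp are discarded.
    max_gap
        Runs of above-threshold bases separated by a gap of at most this many
        bp are merged before length filtering.
    """

    threshold: float = 0.5
    min_len: int = 200
    max_gap: int = 30

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


def call_segments(track: DenseTrack, params: SegmentCallParams) -> IntervalSet:
    """Call segments from a per-base score or probability track.

    Bases with value > threshold form runs; runs separated by <= max_gap bp
    are merged (the gap bases become part of the segment); merged segments
    shorter than min_len are dropped. Each surviving segment is annotated
    with its maximum value over the whole span (score) and the absolute
    position of the leftmost maximum (summit). Output intervals are disjoint,
    sorted in layout order, each >= min_len long.
    """
    out: list[Interval] = []
    for chrom, _length in track.layout:
        values = track[chrom]
        above = values > params.threshold
        if not above.any():
            continue
        # runs of True in the mask
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
        # merge runs whose gap <= max_gap
        merged: list[list[int]] = [[int(run_starts[0]), int(run_ends[0])]]
        for s, e in zip(run_starts[1:], run_ends[1:]):
            if int(s) - merged[-1][1] <= params.max_gap:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s < params.min_len:
                continue
            span = values[s:e]
            summit_off = int(np.argmax(span))  # argmax returns leftmost maximum
            out.append(
                Interval(
                    chrom, s, e,
                    score=float(span[summit_off]),
                    summit=s + summit_off,
                )
            )
    return IntervalSet(out, track.layout)
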