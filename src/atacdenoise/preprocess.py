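"""Reads -> cut sites -> coverage tracks -> labels -> padded training windows.

The Tn5 transposase inserts sequencing adapters 9 bp apart, so the insertion
site is recovered from a read's first aligned base with the conventional
strand-specific offsets: +4 bp on the plus strand, -5 bp on the minus strand
(where "first base" of a minus-strand read is its rightmost aligned base,
``end - 1`` in half-open coordinates). Each cut site is then extended by a
fixed number of bases in either direction (100 bp for accessibility tracks,
5 bp for footprinting) and accumulated into a per-base coverage track.

Training labels are derived from the clean track with a per-base Poisson
upper-tail test against a uniform-coverage control (lambda = genome-wide mean),
thresholded at -log10 p >= cutoff and segment-called with the same caller used
at inference time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genomic_io import DenseTrack, GenomeLayout, Interval, IntervalSet
from .segments import SegmentCallParams, call_segments
from .synthetic import ReadRecord

__all__ = [
    "CutSite",
    "TilingSpec",
    "TrainingExample",
    "cut_sites_from_reads",
    "coverage_from_cutsites",
    "poisson_label_scores",
    "label_peaks",
    "tile_genome",
    "extract_examples",
    "motif_channels",
]

#: default -log10 p cap; guards against double underflow in the Poisson tail
DEFAULT_SCORE_CAP = 350.0


@dataclass(frozen=True)
class CutSite:
    """A single Tn5 insertion position (0-based)."""

    chrom: str
    pos: int
    strand: str


@dataclass(frozen=True)
class TilingSpec:
    """Genome tiling: non-overlapping central intervals plus padding.

    interval_len
        Length of the non-overlapping central intervals (50 kb default).
    pad
        Extra context added at either end of each window (5 kb default), so
        convolutional filters see real neighboring bases when predicting the
        central interval.
    """

    interval_len: int = 50_000
    pad: int = 5_000

    def __post_init__(self) -> None:
        if self.interval_len < 1:
            raise ValueError("interval_len must be > 0")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")

    @property
    def window_len(self) -> int:
        return self.interval_len + 2 * self.pad


@dataclass
class TrainingExample:
    """One padded window: multi-channel input, clean target, binary labels.

    ``input`` has shape (C, interval_len + 2*pad): channel 0 is noisy coverage,
    optional further channels are binary motif indicators. ``start``/``end``
    delimit the central interval; positions outside the chromosome are
    zero-filled.
    """

    chrom: str
    start: int
    end: int
    pad: int
    input: np.ndarray  # (C, W) float32
    target_signal: np.ndarray  # (W,) float32
    target_labels: np.ndarray  # (W,) uint8


def cut_sites_from_reads(
    reads: Sequence[ReadRecord],
    layout: GenomeLayout,
    plus_offset: int = 4,
    minus_offset: int = -5,
) -> list[CutSite]:
    """Convert reads to single-base Tn5 cut sites with strand-specific offsets.

    Plus-strand reads: site = start + plus_offset. Minus-strand reads: the
    first base of the read is its rightmost aligned base, so
    site = (end - 1) + minus_offset. Sites shifted past a chromosome boundary
    are clipped to the boundary.
    """
    sites: list[CutSite] = []
    for r in reads:
        if r.strand == "+":
            pos = r.start + plus_offset
        elif r.strand == "-":
            pos = (r.end - 1) + minus_offset
        else:
            raise ValueError(f"unknown strand {r.strand!r}")
        length = layout.length_of(r.chrom)
        pos = min(max(pos, 0), length - 1)
        sites.append(CutSite(r.chrom, pos, r.strand))
    return sites


def coverage_from_cutsites(
    sites: Sequence[CutSite], extension: int, layout: GenomeLayout
) -> DenseTrack:
    """Accumulate cut sites extended by ``extension`` bp in either direction.

    Each site adds +1 over the inclusive window [pos-extension, pos+extension]
    (2*extension + 1 bp), truncated at chromosome ends; overlapping windows sum.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    # difference-array accumulation per chromosome, then cumulative sum
    deltas = {name: np.zeros(length + 1, dtype=np.float64) for name, length in layout}
    for s in sites:
        length = layout.length_of(s.chrom)
        lo = max(s.pos - extension, 0)
        hi = min(s.pos + extension + 1, length)
        deltas[s.chrom][lo] += 1.0
        deltas[s.chrom][hi] -= 1.0
    return DenseTrack(
        layout, {name: np.cumsum(d[:-1]) for name, d in deltas.items()}
    )


def poisson_label_scores(
    clean_track: DenseTrack,
    lam: float | None = None,
    cap: float = DEFAULT_SCORE_CAP,
) -> DenseTrack:
    """Per-base -log10 Poisson upper-tail p-values against a uniform control.

    For each base with observed coverage ``obs`` (rounded to the nearest
    integer), the score is -log10 P(X >= obs) for X ~ Poisson(lambda). The
    control rate lambda defaults to the genome-wide mean of the clean track
    (the equal-coverage-everywhere control). Scores are capped at ``cap``.
    P(X >= 0) = 1, so zero-coverage bases score 0.
    """
    if lam is None:
        lam = clean_track.total() / clean_track.layout.total_length
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    out: dict[str, np.ndarray] = {}
    for chrom, _length in clean_track.layout:
        obs = np.rint(clean_track[chrom]).astype(np.int64)
        obs = np.maximum(obs, 0)
        uniq, inv = np.unique(obs, return_inverse=True)
        # P(X >= k) = sf(k - 1); log10 survival for numerical range
        log_sf = stats.poisson.logsf(uniq - 1, lam) / np.log(10.0)
        scores = np.minimum(-log_sf, cap)
        scores[uniq == 0] = 0.0
        out[chrom] = scores[inv].astype(np.float64)
    return DenseTrack(clean_track.layout, out)


def label_peaks(
    score_track: DenseTrack,
    cutoff: float = 3.0,
    min_len: int = 200,
    max_gap: int = 30,
) -> IntervalSet:
    """Call label intervals from a -log10 p score track at the given cutoff.

    Thresholding, gap merging and length filtering go through the same segment
    caller used for inference-time peak calling. Note the caller uses a strict
    ``>`` comparison, so a base scoring exactly ``cutoff`` does not seed a
    label; with cutoff 3 this matters only on ties of the discrete score.
    """
    params = SegmentCallParams(threshold=cutoff, min_len=min_len, max_gap=max_gap)
    return call_segments(score_track, params)


def tile_genome(
    layout: GenomeLayout,
    tiling: TilingSpec,
    exclude_chroms: Sequence[str] = (),
) -> IntervalSet:
    """Partition each chromosome into non-overlapping central intervals.

    Intervals are [k*L, (k+1)*L) with the final partial interval
    [k*L, chrom_len) kept, so the intervals tile each chromosome exactly.
    """
    out: list[Interval] = []
    for chrom, length in layout:
        if chrom in exclude_chroms:
            continue
        for start in range(0, length, tiling.interval_len):
            out.append(Interval(chrom, start, min(start + tiling.interval_len, length)))
    return IntervalSet(out, layout)


def _window(values: np.ndarray, start: int, end: int, dtype=np.float32) -> np.ndarray:
    """Extract [start, end) from a chromosome array, zero-filling out of bounds."""
    length = values.shape[0]
    out = np.zeros(end - start, dtype=dtype)
    lo = max(start, 0)
    hi = min(end, length)
    if hi > lo:
        out[lo - start : hi - start] = values[lo:hi]
    return out


def extract_examples(
    noisy_track: DenseTrack,
    clean_track: DenseTrack | None,
    label_intervals: IntervalSet | None,
    tiling: TilingSpec,
    intervals: IntervalSet | None = None,
    extra_channels: Sequence[DenseTrack] = (),
) -> list[TrainingExample]:
    """Assemble padded multi-channel windows over the tiling intervals.

    Each example's window spans [start - pad, end + pad) with zeros beyond
    chromosome bounds. Channel 0 is the noisy coverage; each extra channel
    track (e.g. forward/reverse motif indicators) appends one channel.
    ``clean_track`` and ``label_intervals`` may be omitted for inference-time
    windows (targets are then zero-filled).
    """
    layout = noisy_track.layout
    if clean_track is not None and clean_track.layout != layout:
        raise ValueError("noisy and clean tracks must share a layout")
    for ch in extra_channels:
        if ch.layout != layout:
            raise ValueError("extra channel layout mismatch")
    if intervals is None:
        intervals = tile_genome(layout, tiling)
    label_masks = (
        label_intervals.mask_arrays(layout) if label_intervals is not None else None
    )
    examples: list[TrainingExample] = []
    for iv in intervals:
        if iv.start % tiling.interval_len != 0:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} is not from the tiling"
            )
        # fixed-length window: a final partial interval is zero-extended so
        # every example has length interval_len + 2*pad
        ws = iv.start - tiling.pad
        we = iv.start + tiling.interval_len + tiling.pad
        channels = [_window(noisy_track[iv.chrom], ws, we)]
        channels += [_window(ch[iv.chrom], ws, we) for ch in extra_channels]
        target = (
            _window(clean_track[iv.chrom], ws, we)
            if clean_track is not None
            else np.zeros(we - ws, dtype=np.float32)
        )
        labels = (
            _window(label_masks[iv.chrom], ws, we, dtype=np.uint8)
            if label_masks is not None
            else np.zeros(we - ws, dtype=np.uint8)
        )
        examples.append(
            TrainingExample(
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                pad=tiling.pad,
                input=np.stack(channels),
                target_signal=target,
                target_labels=labels,
            )
        )
    return examples


def motif_channels(
    fwd_sites: IntervalSet, rev_sites: IntervalSet, layout: GenomeLayout
) -> tuple[DenseTrack, DenseTrack]:
    """Binary per-base indicator tracks for motif occurrences on each strand.

    A base is 1 exactly when covered by at least one site interval on that
    strand; a base may be 1 in both channels. Together with the noisy coverage
    these form the three numeric inputs of the cross-modality model.
    """
    fwd = DenseTrack(
        layout,
        {c: m.astype(np.float64) for c, m in fwd_sites.mask_arrays(layout).items()},
    )
    rev = DenseTrack(
        layout,
        {c: m.astype(np.float64) for c, m in rev_sites.mask_arrays(layout).items()},
    )
    return fwd, rev
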