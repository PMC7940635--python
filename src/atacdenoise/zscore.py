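"""Background-ensemble z-scores and significant-region calling.

The differential-accessibility analysis for rare subpopulations: many random
background subsamples are denoised and coverage-normalized, a per-base mean
and standard deviation are accumulated over the ensemble inside a regulatory
mask (e.g. TSS positions of relevant genes expanded by 100 kb each way), and
each sample of interest is scored as z = (x - mu) / sigma per base. Bases with
|z| above a cutoff within a merge distance of each other are combined into
regions; each region's top |z| is converted to a two-sided normal p-value,
Benjamini-Hochberg corrected, thresholded at an FDR, and finally filtered by a
minimum sample coverage to drop regions invisible to conventional analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import DenseTrack, GenomeLayout, Interval, IntervalSet

__all__ = [
    "BackgroundEnsemble",
    "RegionCall",
    "regulatory_mask",
    "normalize_by_coverage",
    "ensemble_stats",
    "zscore_track",
    "call_significant_regions",
]


@dataclass
class BackgroundEnsemble:
    """Per-base mean/sd over B normalized background tracks, within a mask.

    ``mu`` and ``sigma`` are full-length per-chromosome arrays but are only
    meaningful where ``mask`` is True. ``target_total`` is the genome-wide
    total that every member was normalized to (the ensemble mean of the raw
    totals by default); samples scored against the ensemble must be
    normalized to the same total.
    """

    layout: GenomeLayout
    mask: dict[str, np.ndarray]
    mu: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]
    n_tracks: int
    target_total: float


@dataclass(frozen=True)
class RegionCall:
    """A significantly differential region."""

    chrom: str
    start: int
    end: int
    peak_z: float  # signed z of maximal |z| in the region
    p: float  # two-sided normal tail probability of peak_z
    q: float  # Benjamini-Hochberg adjusted p
    max_coverage: float  # max sample coverage within the region


def regulatory_mask(
    tss: IntervalSet, layout: GenomeLayout, flank: int = 100_000
) -> IntervalSet:
    """Expand single-base TSS sites by ``flank`` bp in both directions and merge."""
    windows = []
    for site in tss:
        length = layout.length_of(site.chrom)
        lo = max(site.start - flank, 0)
        hi = min(site.start + flank + 1, length)
        windows.append(Interval(site.chrom, lo, hi))
    return IntervalSet(windows, layout).merged()


def normalize_by_coverage(track: DenseTrack, target_total: float) -> DenseTrack:
    """Scale the track so its genome-wide total equals ``target_total``."""
    total = track.total()
    if total <= 0:
        raise ValueError("cannot normalize a track with non-positive total")
    return track.scaled(target_total / total)


def ensemble_stats(
    background_tracks: Iterable[DenseTrack],
    mask: IntervalSet,
    normalize: bool = True,
    target_total: float | None = None,
) -> BackgroundEnsemble:
    """Accumulate per-base mean and sample standard deviation over the ensemble.

    Tracks are streamed (sums and sums of squares), so arbitrarily large
    ensembles fit in memory. With ``normalize`` (default) every member is
    first scaled to a common genome-wide total: ``target_total`` if given,
    otherwise the mean of the raw totals (which requires materializing the
    input; pass a list, or supply ``target_total`` to stream a generator).
    """
    if normalize and target_total is None:
        background_tracks = list(background_tracks)
        if len(background_tracks) < 2:
            raise ValueError("ensemble requires at least 2 tracks")
        target_total = float(
            np.mean([t.total() for t in background_tracks])
        )
    # Welford's streaming mean/variance: numerically stable (identical tracks
    # give exactly zero variance) at one track of memory
    layout = None
    mean: dict[str, np.ndarray] = {}
    m2: dict[str, np.ndarray] = {}
    n = 0
    for track in background_tracks:
        if layout is None:
            layout = track.layout
            mean = {c: np.zeros(length) for c, length in layout}
            m2 = {c: np.zeros(length) for c, length in layout}
        elif track.layout != layout:
            raise ValueError("ensemble tracks must share a layout")
        if normalize:
            track = normalize_by_coverage(track, target_total)
        n += 1
        for c, _ in layout:
            delta = track[c] - mean[c]
            mean[c] += delta / n
            m2[c] += delta * (track[c] - mean[c])
    if layout is None or n < 2:
        raise ValueError("ensemble requires at least 2 tracks")
    mu = mean
    sigma = {c: np.sqrt(m2[c] / (n - 1)) for c, _ in layout}
    return BackgroundEnsemble(
        layout=layout,
        mask=mask.mask_arrays(layout),
        mu=mu,
        sigma=sigma,
        n_tracks=n,
        target_total=float(target_total) if target_total is not None else 0.0,
    )


def zscore_track(
    sample_track_normalized: DenseTrack, ensemble: BackgroundEnsemble
) -> DenseTrack:
    """Per-base z = (x - mu) / sigma inside the mask; 0 elsewhere and where
    the background is constant (sigma = 0)."""
    if sample_track_normalized.layout != ensemble.layout:
        raise ValueError("sample layout does not match ensemble layout")
    out: dict[str, np.ndarray] = {}
    for c, _ in ensemble.layout:
        x = sample_track_normalized[c]
        ok = ensemble.mask[c] & (ensemble.sigma[c] > 0)
        z = np.zeros_like(x)
        z[ok] = (x[ok] - ensemble.mu[c][ok]) / ensemble.sigma[c][ok]
        out[c] = z
    return DenseTrack(ensemble.layout, out)


def call_significant_regions(
    z_track: DenseTrack,
    sample_track: DenseTrack,
    z_cut: float = 2.0,
    merge_dist: int = 200,
    fdr: float = 0.05,
    min_coverage: float = 1.0,
) -> list[RegionCall]:
    """Call differential regions from a z-score track.

    Bases with |z| > z_cut within ``merge_dist`` bp of each other are combined
    into one region; each region's signed top z becomes a two-sided normal
    p-value; p-values are BH-corrected across all regions of this sample and
    thresholded at ``fdr``; finally regions whose maximum sample coverage is
    below ``min_coverage`` are dropped. Returned regions are sorted and
    disjoint.
    """
    candidates: list[tuple[str, int, int]] = []
    for chrom, _ in z_track.layout:
        z = z_track[chrom]
        pos = np.flatnonzero(np.abs(z) > z_cut)
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > merge_dist)
        starts = np.concatenate(([pos[0]], pos[breaks + 1]))
        ends = np.concatenate((pos[breaks] + 1, [pos[-1] + 1]))
        candidates.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    if not candidates:
        return []
    peak_z = np.empty(len(candidates))
    max_cov = np.empty(len(candidates))
    for i, (chrom, s, e) in enumerate(candidates):
        z = z_track[chrom][s:e]
        k = int(np.argmax(np.abs(z)))  # leftmost maximal |z|
        peak_z[i] = z[k]
        max_cov[i] = float(sample_track[chrom][s:e].max())
    p = 2.0 * stats.norm.sf(np.abs(peak_z))
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    out = [
        RegionCall(chrom, s, e, float(peak_z[i]), float(p[i]), float(q[i]),
                   float(max_cov[i]))
        for i, (chrom, s, e) in enumerate(candidates)
        if q[i] < fdr and max_cov[i] >= min_coverage
    ]
    return out
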