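"""Synthetic ATAC-seq fixture generator.

Emulates the statistical structure the denoising method assumes: a clean
high-coverage experiment whose Tn5 cut sites fall as a Poisson background over
the genome with multiplicatively enriched rates inside non-overlapping peak
regions, and noisy counterparts produced by binomial thinning of reads (read
pairs) or by subsampling barcoded cells. All randomness flows through a single
seeded ``numpy.random.Generator``; the same spec always yields byte-identical
output.

Not emulated: fragment-length distributions, sequence-content (Tn5) bias,
duplicates, doublets, mitochondrial contamination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import DenseTrack, GenomeLayout, Interval, IntervalSet

__all__ = [
    "SyntheticGenomeSpec",
    "ReadRecord",
    "simulate_reads",
    "thin_reads",
    "sample_cells",
    "simulate_footprint_tracks",
    "read_reads_tsv",
    "write_reads_tsv",
]


@dataclass(frozen=True)
class ReadRecord:
    """A single aligned read: half-open span, strand, optional cell barcode.

    ``pair`` groups the two mates of a read pair (or the reads of a fragment);
    pair-aware thinning keeps or drops such a group as a unit.
    """

    chrom: str
    start: int
    end: int
    strand: str
    barcode: str | None = None
    pair: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read start >= end: {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Generative description of a synthetic ATAC-seq experiment.

    Defaults are desk-scale study conditions: a couple of megabase-sized
    chromosomes, tens of peaks per chromosome a few hundred bp wide with
    ~10x rate enrichment over a Poisson background of 0.05 cut sites per bp
    (~10^5 reads over 3 Mb), read length 36 bp.

    Parameters
    ----------
    layout
        Genome over which to simulate.
    n_peaks
        Peaks per chromosome.
    peak_width
        (min, max) peak width in bp; widths drawn uniformly.
    enrichment
        Multiplicative cut-site rate inside peaks (>= 1; 1 means no signal).
    background_rate
        Background cut sites per bp.
    read_length
        Fixed read length in bp.
    n_cells
        When set, every read is assigned a barcode drawn uniformly from
        ``n_cells`` cells (aggregate single-cell mode).
    motif_width, motifs_per_peak, dip_factor
        Footprint-mode geometry: motif occurrences placed inside peaks, with
        clean coverage at the motif multiplied by ``dip_factor`` (1 = no dip,
        0 = fully protected footprint).
    seed
        Seed of the single generator that drives every stochastic step.
    """

    layout: GenomeLayout
    n_peaks: int = 60
    peak_width: tuple[int, int] = (300, 1500)
    enrichment: float = 10.0
    background_rate: float = 0.05
    read_length: int = 36
    n_cells: int | None = None
    motif_width: int = 20
    motifs_per_peak: int = 1
    dip_factor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        lo, hi = self.peak_width
        if not (0 < lo <= hi):
            raise ValueError("peak_width must satisfy 0 < min <= max")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64(self.seed))


_PLACEMENT_RETRIES = 1000


def _place_peaks(
    spec: SyntheticGenomeSpec, rng: np.random.Generator
) -> list[Interval]:
    """Rejection-sample non-overlapping peaks per chromosome; error on failure."""
    peaks: list[Interval] = []
    lo, hi = spec.peak_width
    for chrom, length in spec.layout:
        placed: list[tuple[int, int]] = []
        for _ in range(spec.n_peaks):
            for _attempt in range(_PLACEMENT_RETRIES):
                width = int(rng.integers(lo, hi + 1))
                if width >= length:
                    continue
                start = int(rng.integers(0, length - width))
                end = start + width
                if all(end <= s or start >= e for s, e in placed):
                    placed.append((start, end))
                    break
            else:
                raise RuntimeError(
                    f"could not place {spec.n_peaks} non-overlapping peaks on "
                    f"{chrom} after {_PLACEMENT_RETRIES} retries"
                )
        placed.sort()
        peaks.extend(Interval(chrom, s, e) for s, e in placed)
    return peaks


def simulate_reads(
    spec: SyntheticGenomeSpec,
) -> tuple[list[ReadRecord], IntervalSet]:
    """Simulate reads from a peak-enriched Poisson background.

    Background read starts fall as a homogeneous Poisson process at
    ``background_rate`` per bp; inside each truth peak the rate is multiplied
    by ``enrichment`` (implemented by adding an extra Poisson component with
    rate ``background_rate * (enrichment - 1)``). Strands are fair coin flips
    and read length is fixed. With ``n_cells`` set, barcodes are assigned
    uniformly.

    Returns the reads (sorted by chromosome and start) and the truth peaks.
    """
    rng = spec.rng()
    peaks = _place_peaks(spec, rng)
    peaks_by_chrom: dict[str, list[Interval]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)

    reads: list[ReadRecord] = []
    pair_counter = 0
    for chrom, length in spec.layout:
        starts_parts = []
        n_bg = rng.poisson(spec.background_rate * length)
        starts_parts.append(rng.integers(0, length, size=n_bg))
        extra_rate = spec.background_rate * (spec.enrichment - 1.0)
        for p in peaks_by_chrom.get(chrom, []):
            n_extra = rng.poisson(extra_rate * len(p))
            starts_parts.append(rng.integers(p.start, p.end, size=n_extra))
        starts = np.sort(np.concatenate(starts_parts))
        strands = rng.random(starts.size) < 0.5
        if spec.n_cells is not None:
            cells = rng.integers(0, spec.n_cells, size=starts.size)
        for i, s in enumerate(starts):
            s = int(s)
            e = min(s + spec.read_length, length)
            if e <= s:
                continue
            barcode = f"cell{int(cells[i]):05d}" if spec.n_cells is not None else None
            reads.append(
                ReadRecord(
                    chrom, s, e, "+" if strands[i] else "-",
                    barcode=barcode, pair=pair_counter,
                )
            )
            pair_counter += 1
    return reads, IntervalSet(peaks, spec.layout)


def thin_reads(
    reads: Sequence[ReadRecord],
    p: float,
    seed: int,
    pair_aware: bool = False,
) -> list[ReadRecord]:
    """Binomially thin reads: keep each read (or read pair) with probability p.

    With ``pair_aware``, reads sharing a ``pair`` id are kept or dropped as a
    unit, so pairs are never split; reads with ``pair=None`` are independent.
    """
    if not (0 < p <= 1):
        raise ValueError(f"thinning probability must be in (0, 1], got {p}")
    rng = np.random.Generator(np.random.PCG64(seed))
    if p == 1:
        return list(reads)
    if not pair_aware:
        keep = rng.random(len(reads)) < p
        return [r for r, k in zip(reads, keep) if k]
    # one coin per pair id (in first-appearance order), singletons independent
    decisions: dict[int, bool] = {}
    kept: list[ReadRecord] = []
    for r in reads:
        if r.pair is None:
            if rng.random() < p:
                kept.append(r)
            continue
        if r.pair not in decisions:
            decisions[r.pair] = bool(rng.random() < p)
        if decisions[r.pair]:
            kept.append(r)
    return kept


def sample_cells(
    reads: Sequence[ReadRecord], n_cells: int, seed: int
) -> list[ReadRecord]:
    """Subsample barcodes without replacement; return all and only their reads."""
    barcodes = sorted({r.barcode for r in reads if r.barcode is not None})
    if len(barcodes) < n_cells:
        raise ValueError(
            f"requested {n_cells} cells but only {len(barcodes)} distinct barcodes"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    chosen = set(rng.choice(barcodes, size=n_cells, replace=False).tolist())
    return [r for r in reads if r.barcode in chosen]


def write_reads_tsv(reads: Sequence[ReadRecord], path) -> None:
    """Write reads as BED-like TSV: chrom, start, end, strand[, barcode]."""
    has_barcode = any(r.barcode is not None for r in reads)
    with open(path, "w") as fh:
        for r in reads:
            cols = [r.chrom, str(r.start), str(r.end), r.strand]
            if has_barcode:
                cols.append(r.barcode if r.barcode is not None else ".")
            fh.write("\t".join(cols) + "\n")


def read_reads_tsv(path) -> list[ReadRecord]:
    """Read the TSV written by :func:`write_reads_tsv`."""
    reads: list[ReadRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected chrom/start/end/strand")
            barcode = parts[4] if len(parts) > 4 and parts[4] != "." else None
            reads.append(
                ReadRecord(parts[0], int(parts[1]), int(parts[2]), parts[3], barcode)
            )
    return reads


def simulate_footprint_tracks(
    spec: SyntheticGenomeSpec, peak_height: float = 10.0
) -> tuple[DenseTrack, IntervalSet, IntervalSet]:
    """Build a clean coverage track with protein-binding footprints.

    Peaks are flat plateaus of ``peak_height``; each peak carries
    ``motifs_per_peak`` motif occurrences of width ``motif_width`` placed
    uniformly inside it (alternating strand assignment chosen by coin flip),
    where the coverage is multiplied by ``dip_factor`` — the dip in cut-site
    density characteristic of a bound factor protecting its motif.

    Returns (clean track, forward-motif intervals, reverse-motif intervals).
    """
    lo, _hi = spec.peak_width
    if spec.motif_width >= lo:
        raise ValueError("motif width must be smaller than the minimum peak width")
    if not (0 <= spec.dip_factor <= 1):
        raise ValueError("dip_factor must be in [0, 1]")
    rng = spec.rng()
    peaks = _place_peaks(spec, rng)
    track = DenseTrack.zeros(spec.layout)
    fwd: list[Interval] = []
    rev: list[Interval] = []
    for p in peaks:
        track[p.chrom][p.start : p.end] = peak_height
    for p in peaks:
        for _ in range(spec.motifs_per_peak):
            m_start = int(rng.integers(p.start, p.end - spec.motif_width + 1))
            m_end = m_start + spec.motif_width
            track[p.chrom][m_start:m_end] = peak_height * spec.dip_factor
            (fwd if rng.random() < 0.5 else rev).append(
                Interval(p.chrom, m_start, m_end)
            )
    return track, IntervalSet(fwd, spec.layout), IntervalSet(rev, spec.layout)
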