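"""Core genomic containers and text-format I/O.

Coordinates are 0-based half-open everywhere (native BED/bedGraph convention);
any 1-based display is formatting only. Tracks are dense per-chromosome float
arrays; intervals are half-open records validated against a :class:`GenomeLayout`.

bedGraph is the canonical on-disk track format. bigWig reading is available
through the same interface when ``pyBigWig`` is installed (optional extra).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "DenseTrack",
    "Interval",
    "IntervalSet",
    "read_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_bigwig",
    "read_bed",
    "write_bed",
]


class GenomicIOError(ValueError):
    """Malformed genomic input (bad coordinates, duplicate chromosomes, ...)."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered set of chromosomes with lengths; defines iteration order everywhere.

    Parameters
    ----------
    chroms
        Sequence of ``(name, length_bp)`` pairs. Names must be unique and
        lengths positive. Order is preserved and meaningful: every track and
        interval writer iterates chromosomes in this order.
    """

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.chroms:
            raise GenomicIOError("no chromosomes in layout")
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GenomicIOError(f"duplicate chromosome name(s): {dupes}")
        for name, length in self.chroms:
            if int(length) < 1:
                raise GenomicIOError(f"non-positive length for {name}: {length}")
        object.__setattr__(
            self, "chroms", tuple((str(n), int(length)) for n, length in self.chroms)
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chroms)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chroms:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chroms)


class DenseTrack:
    """Per-base float values over a :class:`GenomeLayout` (one array per chromosome)."""

    def __init__(self, layout: GenomeLayout, data: dict[str, np.ndarray] | None = None):
        self.layout = layout
        if data is None:
            data = {name: np.zeros(length, dtype=np.float64) for name, length in layout}
        else:
            data = {c: np.asarray(v, dtype=np.float64) for c, v in data.items()}
            if set(data) != set(layout.names):
                raise GenomicIOError("track chromosomes do not match layout")
            for name, length in layout:
                if data[name].shape != (length,):
                    raise GenomicIOError(
                        f"array length {data[name].shape} != chrom length {length} for {name}"
                    )
                if not np.all(np.isfinite(data[name])):
                    raise GenomicIOError(f"non-finite values in track for {name}")
        self.data = data

    @classmethod
    def zeros(cls, layout: GenomeLayout) -> "DenseTrack":
        return cls(layout)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "DenseTrack":
        return DenseTrack(self.layout, {c: v.copy() for c, v in self.data.items()})

    def scaled(self, factor: float) -> "DenseTrack":
        return DenseTrack(self.layout, {c: v * factor for c, v in self.data.items()})

    def flatten(self) -> np.ndarray:
        """All values concatenated in layout order."""
        return np.concatenate([self.data[name] for name, _ in self.layout])


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval with optional name/score and summit annotation."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    summit: int | None = None  # absolute position of leftmost maximum, if called

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenomicIOError(
                f"start >= end for {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise GenomicIOError(f"negative start for {self.chrom}:{self.start}")

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Collection of half-open intervals tied to a layout (order preserved)."""

    def __init__(self, records: Iterable[Interval], layout: GenomeLayout | None = None):
        self.records = list(records)
        self.layout = layout
        if layout is not None:
            for rec in self.records:
                if rec.chrom not in layout:
                    raise GenomicIOError(f"chromosome {rec.chrom!r} not in layout")
                if rec.end > layout.length_of(rec.chrom):
                    raise GenomicIOError(
                        f"interval {rec.chrom}:{rec.start}-{rec.end} beyond chromosome end"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.records)

    def __getitem__(self, i: int) -> Interval:
        return self.records[i]

    def total_bp(self) -> int:
        return sum(len(r) for r in self.records)

    def sorted(self) -> "IntervalSet":
        if self.layout is not None:
            order = {name: i for i, name in enumerate(self.layout.names)}
            key = lambda r: (order[r.chrom], r.start, r.end)  # noqa: E731
        else:
            key = lambda r: (r.chrom, r.start, r.end)  # noqa: E731
        return IntervalSet(sorted(self.records, key=key), self.layout)

    def merged(self) -> "IntervalSet":
        """Union of intervals: overlapping or adjacent records coalesced."""
        out: list[Interval] = []
        by_chrom: dict[str, list[Interval]] = {}
        for r in self.sorted():
            by_chrom.setdefault(r.chrom, []).append(r)
        chrom_order = (
            self.layout.names if self.layout is not None else sorted(by_chrom)
        )
        for chrom in chrom_order:
            cur_s = cur_e = None
            for r in by_chrom.get(chrom, []):
                if cur_s is None:
                    cur_s, cur_e = r.start, r.end
                elif r.start <= cur_e:
                    cur_e = max(cur_e, r.end)
                else:
                    out.append(Interval(chrom, cur_s, cur_e))
                    cur_s, cur_e = r.start, r.end
            if cur_s is not None:
                out.append(Interval(chrom, cur_s, cur_e))
        return IntervalSet(out, self.layout)

    def mask_arrays(self, layout: GenomeLayout | None = None) -> dict[str, np.ndarray]:
        """Boolean per-base membership arrays, one per chromosome."""
        layout = layout or self.layout
        if layout is None:
            raise GenomicIOError("layout required to rasterize intervals")
        masks = {name: np.zeros(length, dtype=bool) for name, length in layout}
        for r in self.records:
            masks[r.chrom][r.start : r.end] = True
        return masks


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Parse a UCSC-style chrom.sizes file (name, length) into a layout."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GenomicIOError(f"{path}:{lineno}: expected 'name length'")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise GenomicIOError(f"{path}:{lineno}: non-integer length") from exc
            if length < 1:
                raise GenomicIOError(f"{path}:{lineno}: non-positive length")
            if name in seen:
                raise GenomicIOError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise GenomicIOError(f"{path}: no chromosomes")
    return GenomeLayout(tuple(chroms))


# ---------------------------------------------------------------------------
# bedGraph


def _format_value(v: float) -> str:
    # shortest round-trippable decimal; integers rendered without exponent/point
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def read_bedgraph(path: str | Path, layout: GenomeLayout) -> DenseTrack:
    """Read a 4-column bedGraph into a dense track.

    Intervals may appear in any order but must not overlap; uncovered bases
    are zero.
    """
    track = DenseTrack.zeros(layout)
    covered = {name: np.zeros(length, dtype=bool) for name, length in layout}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GenomicIOError(f"{path}:{lineno}: expected 4 columns")
            chrom, s, e, v = parts[0], parts[1], parts[2], parts[3]
            if chrom not in layout:
                raise GenomicIOError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise GenomicIOError(f"{path}:{lineno}: malformed line") from exc
            if not (0 <= start < end <= layout.length_of(chrom)):
                raise GenomicIOError(
                    f"{path}:{lineno}: interval {start}-{end} outside chromosome"
                )
            if covered[chrom][start:end].any():
                raise GenomicIOError(f"{path}:{lineno}: overlapping intervals")
            covered[chrom][start:end] = True
            track[chrom][start:end] = value
    return track


def write_bedgraph(track: DenseTrack, path: str | Path, omit_zero: bool = True) -> None:
    """Write a dense track as run-length-encoded bedGraph lines.

    Maximal runs of equal value become single lines, in layout order then by
    start. With ``omit_zero`` (default) zero runs are skipped.
    """
    with open(path, "w") as fh:
        for name, _length in track.layout:
            values = track[name]
            if values.size == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(values[1:] != values[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if omit_zero and v == 0:
                    continue
                fh.write(f"{name}\t{s}\t{e}\t{_format_value(float(v))}\n")


def read_bigwig(path: str | Path, layout: GenomeLayout) -> DenseTrack:
    """Read a bigWig file into a dense track (requires pyBigWig)."""
    try:
        import pyBigWig  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("bigWig support requires the pyBigWig package") from exc
    track = DenseTrack.zeros(layout)
    with pyBigWig.open(str(path)) as bw:  # pragma: no cover - optional dependency
        for name, length in layout:
            vals = np.nan_to_num(
                np.asarray(bw.values(name, 0, length), dtype=np.float64)
            )
            track[name][:] = vals
    return track


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Read a BED3+ file; optional name (col 4) and score (col 5) are preserved."""
    records: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise GenomicIOError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise GenomicIOError(f"{path}:{lineno}: malformed coordinates") from exc
            if start >= end:
                raise GenomicIOError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else None
            score = None
            if len(parts) > 4:
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise GenomicIOError(f"{path}:{lineno}: non-numeric score") from exc
            records.append(Interval(chrom, start, end, name=name, score=score))
    return IntervalSet(records, layout)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write intervals as BED; name/score columns included when any record has them."""
    has_name = any(r.name is not None for r in intervals)
    has_score = any(r.score is not None for r in intervals)
    with open(path, "w") as fh:
        for r in intervals:
            cols = [r.chrom, str(r.start), str(r.end)]
            if has_name or has_score:
                cols.append(r.name if r.name is not None else ".")
            if has_score:
                cols.append(_format_value(float(r.score)) if r.score is not None else "0")
            fh.write("\t".join(cols) + "\n")
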