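"""Coordinate system and exact interval arithmetic for genomic tracks.

All coordinates are 0-based half-open ([start, end), BED convention) and
strand-free.  A :class:`SegmentTrack` is a set of disjoint intervals on a
shared :class:`GenomeLayout`; overlapping or abutting intervals are merged at
construction so that every statistic downstream depends only on the set of
covered bases.  The arithmetic here (merge, subtract, intersect, overlap in
base pairs) is exact integer arithmetic — it is validated elsewhere against a
per-base boolean-array oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoordinateError


# ---------------------------------------------------------------------------
# Layout and interval types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with integer lengths; the coordinate universe."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate chromosome names in layout: {names}")
        for n, l in chroms:
            if l <= 0:
                raise ConfigurationError(f"chromosome {n!r} has non-positive length {l}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for n, l in self.chromosomes:
            if n == chrom:
                return l
        raise CoordinateError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _check_bounds(iv: GenomicInterval, layout: GenomeLayout) -> None:
    if iv.chrom not in layout:
        raise CoordinateError(f"interval on unknown chromosome {iv.chrom!r}")
    if iv.end > layout.length(iv.chrom):
        raise CoordinateError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {layout.length(iv.chrom)}"
        )


# ---------------------------------------------------------------------------
# Low-level array kernels (canonical = sorted, pairwise disjoint)
# ---------------------------------------------------------------------------


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping *and abutting* intervals into a canonical list."""
    if starts.size == 0:
        return starts.astype(np.int64), ends.astype(np.int64)
    order = np.argsort(starts, kind="stable")
    s = starts[order].astype(np.int64)
    e = ends[order].astype(np.int64)
    cummax = np.maximum.accumulate(e)
    keep = np.empty(s.size, dtype=bool)
    keep[0] = True
    keep[1:] = s[1:] > cummax[:-1]  # strict: end == start coalesces
    idx = np.flatnonzero(keep)
    ms = s[idx]
    me = np.empty(idx.size, dtype=np.int64)
    me[:-1] = cummax[idx[1:] - 1]
    me[-1] = cummax[-1]
    return ms, me


def _overlap_bp_arrays(sa, ea, sb, eb) -> int:
    """Overlapping base pairs between two disjoint sorted interval lists."""
    if sa.size == 0 or sb.size == 0:
        return 0
    cum = np.concatenate(([0], np.cumsum(eb - sb)))

    def cov(x: np.ndarray) -> np.ndarray:
        # total b-coverage of [0, x)
        k = np.searchsorted(sb, x, side="right")
        v = cum[k].copy()
        nz = k > 0
        v[nz] -= np.maximum(eb[k[nz] - 1] - x[nz], 0)
        return v

    return int((cov(ea) - cov(sa)).sum())


def _intersect_arrays(sa, ea, sb, eb) -> tuple[np.ndarray, np.ndarray]:
    """Intersection intervals of two disjoint sorted lists (sorted, disjoint)."""
    empty = np.empty(0, dtype=np.int64)
    if sa.size == 0 or sb.size == 0:
        return empty, empty
    i0 = np.searchsorted(eb, sa, side="right")  # first b with eb > sa
    i1 = np.searchsorted(sb, ea, side="left")   # first b with sb >= ea
    counts = i1 - i0
    counts = np.maximum(counts, 0)
    total = int(counts.sum())
    if total == 0:
        return empty, empty
    a_idx = np.repeat(np.arange(sa.size), counts)
    offsets = np.concatenate(([0], np.cumsum(counts)))[:-1]
    b_idx = np.arange(total) - np.repeat(offsets, counts) + np.repeat(i0, counts)
    s = np.maximum(sa[a_idx], sb[b_idx])
    e = np.minimum(ea[a_idx], eb[b_idx])
    good = e > s
    return s[good].astype(np.int64), e[good].astype(np.int64)


def _complement_arrays(s, e, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Gaps of a canonical interval list within [0, length)."""
    cs = np.concatenate(([0], e)).astype(np.int64)
    ce = np.concatenate((s, [length])).astype(np.int64)
    good = ce > cs
    return cs[good], ce[good]


def _points_in_arrays(pos: np.ndarray, s: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall inside the (sorted disjoint) intervals."""
    if s.size == 0 or pos.size == 0:
        return np.zeros(pos.size, dtype=bool)
    i = np.searchsorted(s, pos, side="right") - 1
    ok = i >= 0
    out = np.zeros(pos.size, dtype=bool)
    out[ok] = pos[ok] < e[i[ok]]
    return out


# ---------------------------------------------------------------------------
# SegmentTrack
# ---------------------------------------------------------------------------


class SegmentTrack:
    """Disjoint sorted intervals on a layout, carrying one label.

    Construction canonicalizes: intervals are validated against the layout,
    sorted, and overlapping/abutting intervals are merged.
    """

    __slots__ = ("layout", "label", "_by_chrom")

    def __init__(
        self,
        layout: GenomeLayout,
        intervals: Iterable[GenomicInterval] = (),
        label: str = "",
    ) -> None:
        self.layout = layout
        self.label = label
        grouped: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            _check_bounds(iv, layout)
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in grouped.items():
            arr = np.asarray(pairs, dtype=np.int64)
            by_chrom[chrom] = _merge_arrays(arr[:, 0], arr[:, 1])
        self._by_chrom = by_chrom

    @classmethod
    def _from_arrays(
        cls,
        layout: GenomeLayout,
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
        label: str = "",
    ) -> "SegmentTrack":
        """Trusted fast path: arrays must already be sorted and disjoint
        (abutting intervals are permitted and preserved)."""
        t = cls.__new__(cls)
        t.layout = layout
        t.label = label
        t._by_chrom = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in by_chrom.items()
            if len(s) > 0
        }
        return t

    # -- views -----------------------------------------------------------

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._by_chrom.get(chrom, (empty, empty))

    @property
    def intervals(self) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for chrom in self.layout.names:
            s, e = self.arrays(chrom)
            out.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(s, e))
        return out

    def covered_bp(self, chrom: str | None = None) -> int:
        if chrom is not None:
            s, e = self.arrays(chrom)
            return int((e - s).sum())
        return sum(int((e - s).sum()) for s, e in self._by_chrom.values())

    @property
    def n_intervals(self) -> int:
        return sum(len(s) for s, _ in self._by_chrom.values())

    def with_label(self, label: str) -> "SegmentTrack":
        return SegmentTrack._from_arrays(self.layout, self._by_chrom, label)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"SegmentTrack(label={self.label!r}, n={self.n_intervals}, "
            f"bp={self.covered_bp()})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentTrack):
            return NotImplemented
        if self.layout != other.layout or self.label != other.label:
            return False
        chroms = set(self._by_chrom) | set(other._by_chrom)
        for c in chroms:
            s1, e1 = self.arrays(c)
            s2, e2 = other.arrays(c)
            if not (np.array_equal(s1, s2) and np.array_equal(e1, e2)):
                return False
        return True


def _require_same_layout(a: SegmentTrack, b: SegmentTrack) -> None:
    if a.layout != b.layout:
        raise ConfigurationError("tracks are on different genome layouts")


# ---------------------------------------------------------------------------
# Point track
# ---------------------------------------------------------------------------


class PointTrack:
    """Named genomic point positions (e.g. SNPs), 0-based."""

    __slots__ = ("layout", "records")

    def __init__(
        self,
        layout: GenomeLayout,
        records: Iterable[tuple[str, str, int]],
    ) -> None:
        self.layout = layout
        recs = [(str(i), str(c), int(p)) for i, c, p in records]
        ids = [r[0] for r in recs]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate point ids")
        for pid, chrom, pos in recs:
            if chrom not in layout:
                raise CoordinateError(f"point {pid!r} on unknown chromosome {chrom!r}")
            if not (0 <= pos < layout.length(chrom)):
                raise CoordinateError(
                    f"point {pid!r} at {chrom}:{pos} outside chromosome bounds"
                )
        self.records = tuple(recs)

    def __len__(self) -> int:
        return len(self.records)

    def positions(self, chrom: str) -> np.ndarray:
        return np.asarray(
            [p for _, c, p in self.records if c == chrom], dtype=np.int64
        )


# ---------------------------------------------------------------------------
# Track-level operations
# ---------------------------------------------------------------------------


def merge_intervals(
    intervals: Iterable[GenomicInterval], layout: GenomeLayout
) -> list[GenomicInterval]:
    """Canonicalize: sorted, disjoint, abutting intervals coalesced."""
    return SegmentTrack(layout, intervals).intervals


def overlap_bp(a: SegmentTrack, b: SegmentTrack) -> int:
    """|covered(a) ∩ covered(b)| in base pairs; symmetric."""
    _require_same_layout(a, b)
    total = 0
    for chrom in a._by_chrom:
        sa, ea = a.arrays(chrom)
        sb, eb = b.arrays(chrom)
        total += _overlap_bp_arrays(sa, ea, sb, eb)
    return total


def intersect(a: SegmentTrack, b: SegmentTrack, label: str | None = None) -> SegmentTrack:
    """Track covering covered(a) ∩ covered(b)."""
    _require_same_layout(a, b)
    by_chrom = {}
    for chrom in a._by_chrom:
        sa, ea = a.arrays(chrom)
        sb, eb = b.arrays(chrom)
        s, e = _intersect_arrays(sa, ea, sb, eb)
        if s.size:
            by_chrom[chrom] = (s, e)
    return SegmentTrack._from_arrays(
        a.layout, by_chrom, a.label if label is None else label
    )


def subtract(a: SegmentTrack, b: SegmentTrack, label: str | None = None) -> SegmentTrack:
    """Track covering covered(a) \\ covered(b)."""
    _require_same_layout(a, b)
    by_chrom = {}
    for chrom in a._by_chrom:
        sa, ea = a.arrays(chrom)
        sb, eb = b.arrays(chrom)
        L = a.layout.length(chrom)
        cs, ce = _complement_arrays(sb, eb, L)
        s, e = _intersect_arrays(sa, ea, cs, ce)
        if s.size:
            by_chrom[chrom] = (s, e)
    return SegmentTrack._from_arrays(
        a.layout, by_chrom, a.label if label is None else label
    )


def complement(a: SegmentTrack, label: str = "") -> SegmentTrack:
    """Track covering every base of the layout not covered by ``a``."""
    by_chrom = {}
    for chrom, L in a.layout.chromosomes:
        s, e = a.arrays(chrom)
        cs, ce = _complement_arrays(s, e, L)
        if cs.size:
            by_chrom[chrom] = (cs, ce)
    return SegmentTrack._from_arrays(a.layout, by_chrom, label)


def restrict(
    track: SegmentTrack, bin_intervals: Sequence[GenomicInterval]
) -> SegmentTrack:
    """Track covering covered(track) ∩ covered(bin_intervals)."""
    bin_track = SegmentTrack(track.layout, bin_intervals)
    return intersect(track, bin_track, label=track.label)


def count_points_in_track(points: PointTrack, state: SegmentTrack) -> int:
    """Number of points whose base lies inside the track (half-open test)."""
    if points.layout != state.layout:
        raise ConfigurationError("point track and segment track layouts differ")
    n = 0
    for chrom in state._by_chrom:
        pos = points.positions(chrom)
        s, e = state.arrays(chrom)
        n += int(_points_in_arrays(pos, s, e).sum())
    return n


# ---------------------------------------------------------------------------
# Bin partitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinPartition:
    """Named, pairwise-disjoint analysis bins (whole genome or chromosome arms)."""

    bins: tuple[tuple[str, tuple[GenomicInterval, ...]], ...]

    def __post_init__(self) -> None:
        ids = [b for b, _ in self.bins]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate bin ids: {ids}")

    def __iter__(self) -> Iterator[tuple[str, tuple[GenomicInterval, ...]]]:
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)

    @classmethod
    def whole_genome(cls, layout: GenomeLayout, bin_id: str = "genome") -> "BinPartition":
        ivs = tuple(GenomicInterval(c, 0, l) for c, l in layout.chromosomes)
        return cls(bins=((bin_id, ivs),))


def partition_arms(layout: GenomeLayout, cytobands: pd.DataFrame) -> BinPartition:
    """One bin per chromosome arm from a UCSC-style cytoband table.

    The p-arm is [0, first q-band start); the q-arm runs to the chromosome
    end.  Chromosomes with no annotated p bands (acrocentric) yield a single
    q bin and vice versa.
    """
    required = {"chrom", "start", "end", "band"}
    if not required.issubset(cytobands.columns):
        raise ConfigurationError(
            f"cytoband table must have columns {sorted(required)}"
        )
    bins: list[tuple[str, tuple[GenomicInterval, ...]]] = []
    for chrom, length in layout.chromosomes:
        rows = cytobands[cytobands["chrom"] == chrom]
        if rows.empty:
            raise ConfigurationError(
                f"chromosome {chrom!r} present in layout but absent from cytobands"
            )
        bands = rows["band"].astype(str)
        has_p = bands.str.startswith("p").any()
        has_q = bands.str.startswith("q").any()
        if has_p and has_q:
            boundary = int(rows.loc[bands.str.startswith("q"), "start"].min())
            if not (0 < boundary <= length):
                raise ConfigurationError(
                    f"centromere boundary {boundary} outside {chrom} bounds"
                )
            bins.append((f"{chrom}p", (GenomicInterval(chrom, 0, boundary),)))
            if boundary < length:
                bins.append((f"{chrom}q", (GenomicInterval(chrom, boundary, length),)))
        elif has_q:
            bins.append((f"{chrom}q", (GenomicInterval(chrom, 0, length),)))
        elif has_p:
            bins.append((f"{chrom}p", (GenomicInterval(chrom, 0, length),)))
        else:
            raise ConfigurationError(f"no p or q bands annotated for {chrom!r}")
    return BinPartition(bins=tuple(bins))
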