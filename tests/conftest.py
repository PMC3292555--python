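"""Shared fixtures and per-base boolean-array oracles.

The oracles realize tracks as boolean arrays over every base of a small
genome, so set operations and overlap counts can be checked exhaustively
against an implementation-independent ground truth.
"""

from __future__ import annotations

import numpy as np
import pytest

from chromenrich import GenomeLayout, GenomicInterval, SegmentTrack


@pytest.fixture
def layout_1kb() -> GenomeLayout:
    return GenomeLayout(chromosomes=(("chrA", 1000),))


@pytest.fixture
def layout_2chrom() -> GenomeLayout:
    return GenomeLayout(chromosomes=(("chrA", 1000), ("chrB", 600)))


def per_base(track: SegmentTrack, chrom: str) -> np.ndarray:
    """Boolean coverage array over every base of one chromosome."""
    arr = np.zeros(track.layout.length(chrom), dtype=bool)
    for iv in track.intervals:
        if iv.chrom == chrom:
            arr[iv.start : iv.end] = True
    return arr


def per_base_of_intervals(intervals, length: int, chrom: str) -> np.ndarray:
    arr = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            arr[iv.start : iv.end] = True
    return arr


def random_intervals(rng: np.random.Generator, chrom: str, length: int, n: int):
    """n random (possibly overlapping) intervals on one chromosome."""
    starts = rng.integers(0, length - 1, size=n)
    widths = rng.integers(1, max(2, length // 10), size=n)
    return [
        GenomicInterval(chrom, int(s), int(min(s + w, length)))
        for s, w in zip(starts, widths)
        if min(s + w, length) > s
    ]


def random_track(
    rng: np.random.Generator, layout: GenomeLayout, max_n: int = 12, label: str = ""
) -> SegmentTrack:
    ivs = []
    for chrom, length in layout.chromosomes:
        n = int(rng.integers(0, max_n + 1))
        ivs.extend(random_intervals(rng, chrom, length, n))
    return SegmentTrack(layout, ivs, label=label)
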