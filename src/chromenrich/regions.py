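"""Build query regions as fixed genetic-width windows around lead SNPs.

A lead SNP's physical position is mapped to genetic (centimorgan) coordinates
by linear interpolation on a monotone genetic map, a window of the requested
genetic width is centred there, and the window edges are mapped back to
physical coordinates.  Plateaus of the map (zero local recombination) are
resolved to the outermost physical positions, so the built region is the
widest physical interval consistent with the genetic window.  Edges whose cM
target falls outside the map domain are truncated at the map's terminal knot
and the region is clipped to chromosome bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ExtrapolationError, ValidationError
from .genome import GenomeLayout, GenomicInterval


@dataclass(frozen=True)
class GeneticMap:
    """Per-chromosome knots (pos bp strictly increasing, cM non-decreasing)."""

    knots: tuple[tuple[str, tuple[tuple[int, float], ...]], ...]

    def __post_init__(self) -> None:
        for chrom, pts in self.knots:
            if len(pts) < 2:
                raise ValidationError(f"genetic map for {chrom!r} needs >= 2 knots")
            pos = np.asarray([p for p, _ in pts])
            cm = np.asarray([c for _, c in pts])
            if not np.all(np.diff(pos) > 0):
                raise ValidationError(f"map positions not strictly increasing on {chrom!r}")
            if not np.all(np.diff(cm) >= 0):
                raise ValidationError(f"map cM not non-decreasing on {chrom!r}")

    @classmethod
    def from_dict(cls, d: dict[str, list[tuple[int, float]]]) -> "GeneticMap":
        return cls(
            knots=tuple(
                (c, tuple((int(p), float(m)) for p, m in pts)) for c, pts in d.items()
            )
        )

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        for c, pts in self.knots:
            if c == chrom:
                pos = np.asarray([p for p, _ in pts], dtype=np.int64)
                cm = np.asarray([m for _, m in pts], dtype=float)
                return pos, cm
        raise ValidationError(f"no genetic map for chromosome {chrom!r}")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.knots)


def interpolate_cm(pos: int, gmap: GeneticMap, chrom: str) -> float:
    """Genetic position of a physical position; exact at knots, no extrapolation."""
    p, cm = gmap.chrom_arrays(chrom)
    if not (p[0] <= pos <= p[-1]):
        raise ExtrapolationError(
            f"position {chrom}:{pos} outside map domain [{p[0]}, {p[-1]}]"
        )
    return float(np.interp(pos, p, cm))


def _inverse_left(t: float, pos: np.ndarray, cm: np.ndarray) -> int:
    """Leftmost physical position whose cM is >= t (t within [cm0, cmN])."""
    i = int(np.searchsorted(cm, t, side="left"))
    if i == 0:
        return int(pos[0])
    if i == cm.size:
        return int(pos[-1])
    # cm[i-1] < t <= cm[i]; strictly increasing on this segment
    frac = (t - cm[i - 1]) / (cm[i] - cm[i - 1])
    return int(round(pos[i - 1] + frac * (pos[i] - pos[i - 1])))


def _inverse_right(t: float, pos: np.ndarray, cm: np.ndarray) -> int:
    """Rightmost physical position whose cM is <= t (t within [cm0, cmN])."""
    j = int(np.searchsorted(cm, t, side="right")) - 1
    if j < 0:
        return int(pos[0])
    if j == cm.size - 1:
        return int(pos[-1])
    # cm[j] <= t < cm[j+1]
    frac = (t - cm[j]) / (cm[j + 1] - cm[j])
    return int(round(pos[j] + frac * (pos[j + 1] - pos[j])))


def build_region(
    lead_pos: int,
    width_cm: float,
    gmap: GeneticMap,
    chrom: str,
    layout: GenomeLayout,
) -> GenomicInterval:
    """Physical interval of genetic width ``width_cm`` centred on the lead SNP.

    The region always contains the lead; within plateaus the widest physical
    extent is taken; edges are clipped at chromosome bounds, never wrapped.
    """
    if width_cm <= 0:
        raise ValidationError("width_cm must be positive")
    pos, cm = gmap.chrom_arrays(chrom)
    centre = interpolate_cm(lead_pos, gmap, chrom)  # validates the domain
    lo_t = centre - width_cm / 2.0
    hi_t = centre + width_cm / 2.0
    left = int(pos[0]) if lo_t < cm[0] else _inverse_left(lo_t, pos, cm)
    chrom_len = layout.length(chrom)
    right = int(pos[-1]) if hi_t > cm[-1] else _inverse_right(hi_t, pos, cm)
    left = max(0, min(left, lead_pos))
    right = min(chrom_len, max(right, lead_pos + 1))
    return GenomicInterval(chrom, left, right)
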