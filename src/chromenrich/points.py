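"""Point-in-chromatin-state tests (do SNPs land in a state more than chance?).

The observed statistic is the number of points whose base lies inside the
state track.  The null model mirrors the region-overlap null: the points stay
fixed while the chromatin track is randomized per chromosome with its segment
and gap length multisets preserved.  Enrichment is the observed count over
the mean null count; on large genomes this converges to the ratio of the
in-state point fraction to the state's genome coverage fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, PreconditionError, UndefinedRatioError
from .genome import (
    GenomicInterval,
    PointTrack,
    SegmentTrack,
    _points_in_arrays,
    count_points_in_track,
)
from .enrichment import (
    NullModelConfig,
    _permute_segments,
    _region_segments,
    _substream,
    mc_pvalue,
)


@dataclass
class PointOverlapResult:
    """Count, percentage, enrichment and p-value for one state track."""

    track_label: str
    n_points: int
    n_in_state: int
    percentage: float
    enrichment: float
    null_mean: float
    null_sd: float
    p_value: float
    n_null_samples: int


def point_percentage(n_in_state: int, n_points: int) -> float:
    """100 * n_in_state / n_points, reported to two decimals."""
    if n_points <= 0:
        raise PreconditionError("n_points must be positive")
    if not (0 <= n_in_state <= n_points):
        raise PreconditionError("need 0 <= n_in_state <= n_points")
    return round(100.0 * n_in_state / n_points, 2)


def point_overlap_test(
    points: PointTrack,
    state: SegmentTrack,
    config: NullModelConfig | None = None,
) -> PointOverlapResult:
    """Monte Carlo test of the point count against the randomized-track null."""
    config = config or NullModelConfig()
    if points.layout != state.layout:
        raise ConfigurationError("point track and state track layouts differ")
    if len(points) == 0:
        raise PreconditionError("point track is empty")
    observed = count_points_in_track(points, state)
    regions = [GenomicInterval(c, 0, l) for c, l in state.layout.chromosomes]
    pre = []
    for r in regions:
        s, e = _region_segments(state, r)
        if s.size == 0:
            continue
        pos = points.positions(r.chrom)
        pre.append((r.start, r.end, s, e, pos))
    rng = _substream(config.seed, state.label, "points")
    samples = np.zeros(config.n_samples, dtype=np.int64)
    for i in range(config.n_samples):
        tot = 0
        for lo, hi, s, e, pos in pre:
            ns, ne = _permute_segments(s, e, lo, hi, rng)
            tot += int(_points_in_arrays(pos, ns, ne).sum())
        samples[i] = tot
    null_mean = float(samples.mean())
    if null_mean == 0:
        raise UndefinedRatioError(
            "null mean point count is zero; enrichment undefined"
        )
    return PointOverlapResult(
        track_label=state.label,
        n_points=len(points),
        n_in_state=observed,
        percentage=point_percentage(observed, len(points)),
        enrichment=observed / null_mean,
        null_mean=null_mean,
        null_sd=float(samples.std(ddof=1)) if samples.size > 1 else 0.0,
        p_value=mc_pvalue(observed, samples),
        n_null_samples=config.n_samples,
    )
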