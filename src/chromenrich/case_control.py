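"""Differential (case vs. control cell type) overlap analysis.

To compare the same chromatin state between two cell types, bases present in
both cell types' tracks are removed; what remains is labelled *case*
(cell-type-specific to the case cell) or *control*.  The test statistic is
the base-pair overlap between case-labelled intervals and the query track;
its null distribution comes from uniformly permuting the case/control labels
over the fixed interval positions, preserving the number of case labels.
The fold enrichment difference is the ratio of the two classes' query-overlap
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, PreconditionError, UndefinedRatioError
from .genome import GenomeLayout, GenomicInterval, SegmentTrack, subtract
from .enrichment import NullModelConfig, OverlapTestResult, _substream, mc_pvalue

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class LabeledIntervalSet:
    """Pairwise-disjoint intervals, each carrying a case or control label."""

    layout: GenomeLayout
    intervals: tuple[GenomicInterval, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.labels):
            raise ConfigurationError("intervals and labels differ in length")
        bad = set(self.labels) - {CASE, CONTROL}
        if bad:
            raise ConfigurationError(f"unknown labels: {sorted(bad)}")
        # disjointness: merged coverage must equal the sum of lengths
        merged = SegmentTrack(self.layout, self.intervals)
        total = sum(len(iv) for iv in self.intervals)
        if merged.covered_bp() != total:
            raise ConfigurationError("labeled intervals are not pairwise disjoint")

    def class_bp(self, label: str) -> int:
        return sum(len(iv) for iv, l in zip(self.intervals, self.labels) if l == label)

    def class_track(self, label: str) -> SegmentTrack:
        ivs = [iv for iv, l in zip(self.intervals, self.labels) if l == label]
        return SegmentTrack(self.layout, ivs, label=label)


def build_differential_tracks(
    case_state: SegmentTrack, control_state: SegmentTrack
) -> LabeledIntervalSet:
    """Remove shared bases; label remaining intervals by their cell type."""
    if case_state.layout != control_state.layout:
        raise ConfigurationError("case and control tracks on different layouts")
    case_only = subtract(case_state, control_state)
    control_only = subtract(control_state, case_state)
    pairs = [(iv, CASE) for iv in case_only.intervals]
    pairs += [(iv, CONTROL) for iv in control_only.intervals]
    pairs.sort(key=lambda p: (p[0].chrom, p[0].start))
    return LabeledIntervalSet(
        layout=case_state.layout,
        intervals=tuple(p[0] for p in pairs),
        labels=tuple(p[1] for p in pairs),
    )


def _per_interval_overlap(labeled: LabeledIntervalSet, query: SegmentTrack) -> np.ndarray:
    """Query-overlap bp of each labelled interval, in interval order."""
    out = np.zeros(len(labeled.intervals), dtype=np.int64)
    cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i, iv in enumerate(labeled.intervals):
        if iv.chrom not in cache:
            qs, qe = query.arrays(iv.chrom)
            cum = np.concatenate(([0], np.cumsum(qe - qs)))
            cache[iv.chrom] = (qs, qe, cum)
        qs, qe, cum = cache[iv.chrom]
        if qs.size == 0:
            continue

        def cov(x: int) -> int:
            k = int(np.searchsorted(qs, x, side="right"))
            v = int(cum[k])
            if k > 0:
                v -= max(int(qe[k - 1]) - x, 0)
            return v

        out[i] = cov(iv.end) - cov(iv.start)
    return out


def fold_enrichment_difference(labeled: LabeledIntervalSet, query: SegmentTrack) -> float:
    """(case overlap / case bp) / (control overlap / control bp)."""
    if query.layout != labeled.layout:
        raise ConfigurationError("query and labeled set on different layouts")
    case_bp = labeled.class_bp(CASE)
    control_bp = labeled.class_bp(CONTROL)
    if case_bp == 0 or control_bp == 0:
        raise UndefinedRatioError("both label classes need positive total bp")
    ov = _per_interval_overlap(labeled, query)
    is_case = np.asarray([l == CASE for l in labeled.labels])
    case_ov = int(ov[is_case].sum())
    control_ov = int(ov[~is_case].sum())
    if control_ov == 0:
        raise UndefinedRatioError(
            "control intervals have zero query overlap; fold difference undefined"
        )
    return (case_ov / case_bp) / (control_ov / control_bp)


def case_control_test(
    labeled: LabeledIntervalSet,
    query: SegmentTrack,
    config: NullModelConfig | None = None,
) -> OverlapTestResult:
    """Label-permutation test of case-vs-control query overlap.

    Interval positions never move; each Monte Carlo sample redraws which
    intervals carry the case label (uniformly over arrangements with the
    observed case count) and recomputes the case overlap.
    """
    config = config or NullModelConfig()
    if query.layout != labeled.layout:
        raise ConfigurationError("query and labeled set on different layouts")
    labels = np.asarray(labeled.labels)
    n = labels.size
    if n < 2:
        raise PreconditionError("need at least two labelled intervals")
    is_case = labels == CASE
    n_case = int(is_case.sum())
    if n_case == 0 or n_case == n:
        raise PreconditionError("both case and control labels must be present")
    ov = _per_interval_overlap(labeled, query).astype(np.int64)
    observed = int(ov[is_case].sum())
    rng = _substream(config.seed, "case-control", query.label)
    samples = np.empty(config.n_samples, dtype=np.int64)
    for i in range(config.n_samples):
        idx = rng.permutation(n)[:n_case]
        samples[i] = ov[idx].sum()
    return OverlapTestResult(
        track_label=CASE,
        bin_id="genome",
        observed=float(observed),
        enrichment=fold_enrichment_difference(labeled, query),
        null_mean=float(samples.mean()),
        null_sd=float(samples.std(ddof=1)) if samples.size > 1 else 0.0,
        p_value=mc_pvalue(observed, samples),
        n_null_samples=config.n_samples,
    )
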