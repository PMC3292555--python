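"""Synthetic chromatin-state, query-region and SNP tracks with known truth.

The generator emulates the structure of a cell type's chromatin-state
segmentation: each chromosome is a sequence of state-labelled segments
separated by unlabelled background gaps, with geometric (memoryless) segment
lengths around per-state means and per-state target genome fractions.  Query
regions are placed with a controllable enrichment factor toward one target
state: the per-base rate of region *starts* inside the target state is
``enrichment_factor`` times the outside rate, and a factor of 1 reduces
exactly to uniform placement.  Points (SNPs) land inside the target state
with probability ``multiplier`` times its coverage fraction.

Because the permutation null preserves whatever lengths it is given, the
validity of the downstream tests does not depend on the realism of the
geometric length model; the generator's job is controllable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .genome import GenomeLayout, GenomicInterval, PointTrack, SegmentTrack, complement
from .regions import GeneticMap


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateSpec:
    label: str
    mean_length: float  # bp
    fraction: float     # target genome fraction


@dataclass(frozen=True)
class QuerySpec:
    # region width is kept on the order of the target state's segment length:
    # the planted enrichment acts on region *starts*, so regions much wider
    # than the target segments would dilute it out of the coverage statistic
    n_regions: int = 200
    mean_width: float = 2_000.0
    enrichment_factor: float = 3.0
    target_state: str = "SE"


@dataclass(frozen=True)
class PointSpec:
    n_points: int = 452
    multiplier: float = 5.0
    target_state: str = "SE"


# Default palette: a scaled-down analogue of an 11-state segmentation
# (promoters/enhancers short and rare, heterochromatin long and abundant).
_DEFAULT_STATES = (
    StateSpec("AP", 1_000, 0.010),
    StateSpec("WP", 1_000, 0.015),
    StateSpec("PP", 1_000, 0.003),
    StateSpec("SE", 1_200, 0.015),
    StateSpec("WE", 1_500, 0.030),
    StateSpec("PR", 10_000, 0.040),
    StateSpec("H", 20_000, 0.550),
    StateSpec("I", 1_000, 0.010),
    StateSpec("ST", 5_000, 0.030),
    StateSpec("WT", 10_000, 0.150),
    StateSpec("RepCNV", 3_000, 0.020),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full ground-truth description of one synthetic dataset."""

    layout: GenomeLayout = field(
        default_factory=lambda: GenomeLayout(
            chromosomes=(
                ("chr1", 14_000_000),
                ("chr2", 12_000_000),
                ("chr3", 12_000_000),
                ("chr4", 10_000_000),
            )
        )
    )
    states: tuple[StateSpec, ...] = _DEFAULT_STATES
    query: QuerySpec = QuerySpec()
    points: PointSpec = PointSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        frac_sum = sum(s.fraction for s in self.states)
        if frac_sum > 1.0 + 1e-9:
            raise ConfigurationError(f"state fractions sum to {frac_sum:.3f} > 1")
        for s in self.states:
            if s.fraction < 0:
                raise ConfigurationError(f"negative fraction for state {s.label!r}")
            if s.mean_length <= 0:
                raise ConfigurationError(f"non-positive mean length for {s.label!r}")
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate state labels")
        if self.query.enrichment_factor < 0:
            raise ConfigurationError("enrichment_factor must be >= 0")
        if self.points.multiplier < 0:
            raise ConfigurationError("point multiplier must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs: dict = {}
        if "layout" in d:
            kwargs["layout"] = GenomeLayout(
                chromosomes=tuple((str(k), int(v)) for k, v in d["layout"].items())
            )
        if "states" in d:
            kwargs["states"] = tuple(
                StateSpec(s["label"], float(s["mean_length"]), float(s["fraction"]))
                for s in d["states"]
            )
        if "query" in d:
            kwargs["query"] = QuerySpec(**d["query"])
        if "points" in d:
            kwargs["points"] = PointSpec(**d["points"])
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Chromatin simulation
# ---------------------------------------------------------------------------


def _geometric(rng: np.random.Generator, mean: float) -> int:
    """Geometric length (support >= 1) with the given mean."""
    p = min(1.0, 1.0 / max(mean, 1.0))
    return int(rng.geometric(p))


def simulate_chromatin(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, SegmentTrack]:
    """One segmentation: disjoint per-state tracks separated by background.

    Per chromosome the walk alternates a background gap with a state segment;
    the state is chosen with probability proportional to fraction/mean_length
    and the mean gap is solved so each state's expected realized genome
    fraction equals its target.
    """
    active = [s for s in config.states if s.fraction > 0]
    out: dict[str, list[GenomicInterval]] = {s.label: [] for s in config.states}
    if active:
        f_tot = sum(s.fraction for s in active)
        weights = np.asarray([s.fraction / s.mean_length for s in active])
        w_sum = weights.sum()
        probs = weights / w_sum
        gap_mean = (1.0 - f_tot) / w_sum  # may be 0 when fractions sum to 1
        for chrom, length in config.layout.chromosomes:
            pos = 0
            while pos < length:
                if gap_mean > 0:
                    pos += _geometric(rng, gap_mean)
                if pos >= length:
                    break
                k = int(rng.choice(len(active), p=probs))
                seg = _geometric(rng, active[k].mean_length)
                out[active[k].label].append(
                    GenomicInterval(chrom, pos, min(pos + seg, length))
                )
                pos += seg
    return {
        s.label: SegmentTrack(config.layout, out[s.label], label=s.label)
        for s in config.states
    }


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------


def _track_cumulative(track: SegmentTrack):
    """Flattened (chrom, start, end) blocks with a global cumulative bp scale."""
    blocks = []
    for chrom in track.layout.names:
        s, e = track.arrays(chrom)
        for a, b in zip(s, e):
            blocks.append((chrom, int(a), int(b)))
    lens = np.asarray([b - a for _, a, b in blocks], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(lens)))
    return blocks, cum


def _uniform_in_track(track: SegmentTrack, n: int, rng) -> list[tuple[str, int]]:
    """n positions uniform over the track's covered bases."""
    blocks, cum = _track_cumulative(track)
    total = int(cum[-1])
    if total == 0:
        raise ConfigurationError("cannot sample from an empty track")
    u = rng.integers(0, total, size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    return [
        (blocks[i][0], blocks[i][1] + int(u[j] - cum[i]))
        for j, i in enumerate(idx)
    ]


def _genome_track(layout: GenomeLayout) -> SegmentTrack:
    return SegmentTrack(
        layout, [GenomicInterval(c, 0, l) for c, l in layout.chromosomes]
    )


# ---------------------------------------------------------------------------
# Query regions and points
# ---------------------------------------------------------------------------


def simulate_query(
    config: SimulationConfig,
    states: dict[str, SegmentTrack],
    rng: np.random.Generator,
    label: str = "query_regions",
) -> SegmentTrack:
    """Query regions with a planted start-rate enrichment toward one state."""
    spec = config.query
    if spec.target_state not in states:
        raise ConfigurationError(f"unknown target state {spec.target_state!r}")
    target = states[spec.target_state]
    layout = config.layout
    genome = _genome_track(layout)
    C = target.covered_bp() / layout.total_bp
    ef = spec.enrichment_factor
    starts: list[tuple[str, int]] = []
    if ef >= 1.0:
        # mixture giving an in-state/outside start-rate ratio of exactly ef
        p_in = (ef - 1.0) * C / (1.0 + (ef - 1.0) * C)
        for _ in range(spec.n_regions):
            if target.covered_bp() > 0 and rng.random() < p_in:
                starts.extend(_uniform_in_track(target, 1, rng))
            else:
                starts.extend(_uniform_in_track(genome, 1, rng))
    else:
        # thin uniform starts inside the target by rejection (ef = 0: never)
        while len(starts) < spec.n_regions:
            (chrom, pos), = _uniform_in_track(genome, 1, rng)
            s, e = target.arrays(chrom)
            in_target = bool(
                s.size and (i := int(np.searchsorted(s, pos, "right")) - 1) >= 0
                and pos < e[i]
            )
            if in_target and rng.random() >= ef:
                continue
            starts.append((chrom, pos))
    intervals = []
    for chrom, pos in starts:
        w = _geometric(rng, spec.mean_width)
        end = min(pos + w, layout.length(chrom))
        intervals.append(GenomicInterval(chrom, pos, end))
    return SegmentTrack(layout, intervals, label=label)


def simulate_points(
    config: SimulationConfig,
    states: dict[str, SegmentTrack],
    rng: np.random.Generator,
    id_prefix: str = "snp",
) -> PointTrack:
    """Points landing in the target state with probability multiplier x coverage."""
    spec = config.points
    if spec.target_state not in states:
        raise ConfigurationError(f"unknown target state {spec.target_state!r}")
    target = states[spec.target_state]
    layout = config.layout
    C = target.covered_bp() / layout.total_bp
    p_in = spec.multiplier * C
    if p_in > 1.0 + 1e-12:
        raise ConfigurationError(
            f"multiplier x coverage fraction = {p_in:.3f} exceeds 1"
        )
    p_in = min(p_in, 1.0)
    outside = complement(target)
    records = []
    for i in range(spec.n_points):
        if rng.random() < p_in:
            (chrom, pos), = _uniform_in_track(target, 1, rng)
        else:
            (chrom, pos), = _uniform_in_track(outside, 1, rng)
        records.append((f"{id_prefix}{i + 1:05d}", chrom, pos))
    return PointTrack(layout, records)


# ---------------------------------------------------------------------------
# Genome annotation scaffolding (cytobands, genetic map, lead SNPs)
# ---------------------------------------------------------------------------


def simulate_cytobands(
    layout: GenomeLayout,
    p_arm_fraction: float = 0.45,
    acrocentric: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Minimal cytoband table: one p and one q band per chromosome.

    Chromosomes named in ``acrocentric`` get a single q band (no p arm).
    """
    rows = []
    for chrom, length in layout.chromosomes:
        if chrom in acrocentric:
            rows.append((chrom, 0, length, "q11", "gneg"))
        else:
            boundary = int(round(p_arm_fraction * length))
            rows.append((chrom, 0, boundary, "p11", "gneg"))
            rows.append((chrom, boundary, length, "q11", "gpos50"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "stain"])


def simulate_genetic_map(
    layout: GenomeLayout,
    rng: np.random.Generator,
    mean_rate_cm_per_mb: float = 1.0,
    knot_spacing: int = 1_000_000,
) -> GeneticMap:
    """Piecewise-linear map with per-interval rates jittered around the mean."""
    d = {}
    for chrom, length in layout.chromosomes:
        pos = list(range(0, length, knot_spacing)) + [length]
        pos = sorted(set(pos))
        rates = rng.gamma(shape=4.0, scale=mean_rate_cm_per_mb / 4.0, size=len(pos) - 1)
        cm = np.concatenate(([0.0], np.cumsum(rates * np.diff(pos) / 1e6)))
        d[chrom] = list(zip(pos, cm))
    return GeneticMap.from_dict(d)


def simulate_leads(
    layout: GenomeLayout, n: int, rng: np.random.Generator, id_prefix: str = "rs"
) -> PointTrack:
    """Lead SNPs placed uniformly over the genome."""
    genome = _genome_track(layout)
    positions = _uniform_in_track(genome, n, rng)
    records = [
        (f"{id_prefix}{i + 1:04d}", chrom, pos)
        for i, (chrom, pos) in enumerate(positions)
    ]
    return PointTrack(layout, records)
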