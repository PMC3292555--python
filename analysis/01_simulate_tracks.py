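"""Simulate the study dataset: an 11-state chromatin segmentation for a
"case" (B-like) and a "control" cell type on a 48 Mb four-chromosome genome,
query regions planted with 3x enrichment toward strong enhancers (SE),
452 SNPs concentrated 5x in SE, plus cytobands, a genetic map and lead SNPs.

Also demonstrates genetic-window construction: 0.25 cM regions are built
around the simulated lead SNPs with the simulated recombination map.

Writes everything as plain text under results/data/.
"""

from pathlib import Path

import numpy as np

from chromenrich import (
    SegmentTrack,
    SimulationConfig,
    build_region,
    simulate_chromatin,
    simulate_cytobands,
    simulate_genetic_map,
    simulate_leads,
    simulate_points,
    simulate_query,
    track_io,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    rng = np.random.default_rng(config.seed)

    case_states = simulate_chromatin(config, rng)
    control_states = simulate_chromatin(config, rng)  # independent cell type
    query = simulate_query(config, case_states, rng)
    points = simulate_points(config, case_states, rng)
    gmap = simulate_genetic_map(config.layout, rng)
    leads = simulate_leads(config.layout, 40, rng)

    track_io.write_chrom_sizes(config.layout, OUT / "genome.chrom.sizes")
    track_io.write_cytoband(simulate_cytobands(config.layout), OUT / "cytoband.tsv")
    track_io.write_segmentation(case_states, OUT / "case_states.bed")
    track_io.write_segmentation(control_states, OUT / "control_states.bed")
    track_io.write_bed(query, OUT / "query_regions.bed")
    track_io.write_points(points, OUT / "points.tsv", base=1)
    track_io.write_points(leads, OUT / "leads.tsv", base=1)
    track_io.write_genetic_map(gmap, OUT / "genetic_map.tsv")

    built = SegmentTrack(
        config.layout,
        [
            build_region(pos, 0.25, gmap, chrom, config.layout)
            for _, chrom, pos in leads.records
        ],
        label="built_regions",
    )
    track_io.write_bed(built, OUT / "regions_0.25cM.bed")

    total = config.layout.total_bp
    print(f"seed={SEED}  genome={total:,} bp over {len(config.layout.names)} chromosomes")
    print("state  target_fraction  realized_fraction  n_segments")
    for spec in config.states:
        t = case_states[spec.label]
        print(
            f"{spec.label:>6}  {spec.fraction:15.3f}  {t.covered_bp() / total:17.4f}"
            f"  {t.n_intervals:10d}"
        )
    print(
        f"query: {query.n_intervals} regions, {query.covered_bp():,} bp "
        f"({100 * query.covered_bp() / total:.2f}% of genome), planted 3x toward SE"
    )
    print(f"points: {len(points)} SNPs, planted 5x toward SE")
    print(
        f"built {built.n_intervals} merged 0.25 cM regions "
        f"({built.covered_bp():,} bp) around {len(leads)} leads"
    )


if __name__ == "__main__":
    main()
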