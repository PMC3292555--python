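"""Differential overlap: does case-cell-specific chromatin overlap the query
more than control-cell-specific chromatin of the same state?

For each state, bases shared between the two cell types are removed, the
remaining intervals are labelled case/control, and the case-vs-query overlap
is tested by permuting the labels over the fixed interval positions.  The
fold difference is the ratio of the two classes' query-overlap proportions.

Because the query was planted toward the *case* cell's SE track, SE is
expected to show a fold difference > 1 with a small p; other states should
be close to exchangeable.

Writes results/case_control.tsv.
"""

from pathlib import Path

from chromenrich import (
    NullModelConfig,
    build_differential_tracks,
    case_control_test,
    track_io,
)
from chromenrich.cli import significance_label

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
N_SAMPLES = 2000
SEED = 17


def main() -> None:
    layout = track_io.read_chrom_sizes(DATA / "genome.chrom.sizes")
    case_states = track_io.read_segmentation(DATA / "case_states.bed", layout)
    control_states = track_io.read_segmentation(DATA / "control_states.bed", layout)
    query = track_io.read_bed(DATA / "query_regions.bed", layout, label="query_regions")
    config = NullModelConfig(n_samples=N_SAMPLES, seed=SEED)

    results = []
    print(f"n_samples={N_SAMPLES} seed={SEED}")
    print("state  case_overlap_bp  fold_difference  p_value  call")
    for label in sorted(set(case_states) & set(control_states)):
        labeled = build_differential_tracks(case_states[label], control_states[label])
        r = case_control_test(labeled, query, config)
        r.track_label = label
        r.fdr_significant = r.p_value <= 0.05
        results.append(r)
        print(
            f"{label:>6}  {int(r.observed):15,d}  {r.enrichment:15.3f}  "
            f"{track_io.format_p(r.p_value)}  {significance_label(r.p_value)}"
        )
    out = ROOT / "results" / "case_control.tsv"
    track_io.write_results(track_io.results_table(results), out)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
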