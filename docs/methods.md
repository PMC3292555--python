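# Methods

## Model and assumptions

The package treats a genome as an ordered set of named chromosomes with
integer lengths; all tracks live on this shared coordinate universe in
0-based half-open coordinates and strand is ignored throughout (every
statistic depends only on covered bases or point membership). A segment
track is canonical: sorted, pairwise disjoint, with overlapping or abutting
input intervals merged at construction, so coverage semantics are unique.

The inferential question is whether a fixed query track covers a chromatin
state's bases more than chance would allow, given the state's observed
segmentation geometry. The null model conditions on (a) the multiset of
segment lengths and (b) the multiset of inter-segment gap lengths including
the two flanks to the bin boundaries, within each contiguous analysis
region, and draws uniformly over the `n!·(n+1)!` reassemblies
gap–segment–gap–…–gap with both orders permuted independently. This is an
exact conditional (permutation) null: covered base pairs and both length
multisets are conserved in every sample, so no resampling error enters
through the track mass. The alternative reading — resampling lengths from a
fitted distribution — would only approximately preserve the empirical
distributions and is deliberately not implemented.

Two structural consequences are worth knowing. First, the null's
effective sample space depends on the geometry: a track with near-equal
gaps (e.g. a periodic fixture) has few distinguishable arrangements, and
p-values against such tracks are correspondingly coarse. Second, when a
zero-length flank gap is permuted into the interior, two segments abut; the
randomized track keeps them as distinct segments rather than merging,
because merging would change the segment-length multiset that the null is
defined to conserve. Abutting segments are handled correctly by every
consumer (overlap, counting, coverage).

One-sidedness: the p-value counts null samples with overlap **≥** observed
(ties extreme), floored at 1/N, so enrichment is tested directly and
depletion surfaces as p near 1 alongside an enrichment ratio below 1. No
two-sided or depletion-specific test is offered.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 20,000 | Monte Carlo null samples; p-floor = 1/N = 0.00005 |
| `seed` | 0 | master seed; per-(track, bin) substreams derived via CRC-keyed `SeedSequence`, so results are order-independent and bit-reproducible |
| `fdr_q` | 0.10 | Benjamini–Hochberg level across retained bins, applied separately per state track |
| `width_cm` | 0.25 | genetic width of query windows around lead SNPs |
| `alpha` / `alpha_loose` | 0.05 / 0.10 | report labels: YES (p ≤ α), Maybe (α < p ≤ α_loose), NO — the three-way presentation is cosmetic; the TSV carries exact p-values |

Analysis bins are either whole chromosomes ("global") or chromosome arms
derived from a cytoband table (p-arm = [0, first q-band start)); acrocentric
chromosomes with no annotated p bands yield a single q bin. Arms with zero
query coverage are excluded from local testing rather than reported as
p = 1, and the FDR is computed over the retained arms only.

## Design choices where the design was open

- **FDR grouping.** The BH step-up is applied across bins within one state
  track (not pooled across states). Pooling is a defensible alternative;
  per-track matches the way per-state significance columns are usually
  read, and the choice is isolated in `local_overlap_test`.
- **Label permutation granularity.** The case/control test permutes labels
  over *intervals*, not base pairs, so interval-length heterogeneity is part
  of the null. Genome-wide label counts are preserved; per-chromosome counts
  are not constrained.
- **Undefined ratios.** A ratio with a zero denominator (empty reference in
  a bin, query absent from a state's complement, zero control overlap) is
  never reported as infinity: the global test raises a typed error, while
  the local test keeps the bin's p-value and reports enrichment as NaN,
  since a defined permutation p does not require a defined ratio.
- **Point-test null.** The chromatin track is randomized and the points stay
  fixed, mirroring the region test; the point-count enrichment uses the
  Monte Carlo null mean as denominator. On large genomes this converges to
  the analytic ratio (in-state point fraction over coverage fraction); the
  agreement is property-tested at 5%.
- **Genetic-map inversion.** Window edges are found by inverting the
  piecewise-linear map; inside zero-recombination plateaus the outermost
  physical positions are taken (maximal region). Edges whose cM target
  leaves the map domain are truncated at the terminal knot, then clipped to
  chromosome bounds; positions outside the map's physical domain are a hard
  extrapolation error.

## The synthetic-data generator

`simulate_chromatin` emulates the *structure* of a chromatin-state
segmentation — alternating background gaps and state segments with
geometric (memoryless) lengths, state picked per cycle with probability
proportional to fraction/mean-length, and the mean gap solved in closed
form so each state's expected realized genome fraction equals its target.
It does not attempt real chromatin grammar (no state-transition structure,
no empirical length distributions); because the null conditions on whatever
lengths it is given, test validity does not depend on that realism. What
passing tests therefore show is that the *statistics* behave as claimed on
tracks with controlled truth — not that real segmentations satisfy the
generator's assumptions.

`simulate_query` plants enrichment on region **starts**: the in-state
per-base start rate is `enrichment_factor` times the outside rate (mixture
construction for factors ≥ 1, rejection thinning below 1; factor 1 is
exactly uniform, factor 0 never starts in-state). A start-rate plant only
survives into the *coverage* statistic when regions are not much wider than
the target segments; the demo defaults (200 regions × 2 kb against ~1.2 kb
enhancer segments on 48 Mb) are chosen accordingly. `simulate_points` places
each point in the target state with probability multiplier × coverage
fraction (error if that exceeds 1), else uniformly outside.

## Numerical and degenerate-input conventions

- All interval arithmetic is exact integer arithmetic; kernels are verified
  against per-base boolean-array oracles on small genomes (≥1,000 random
  cases) in the test suite.
- p-values are printed in decimal notation with at least five decimals.
- Readers reject out-of-bounds coordinates; nothing is clamped. Point files
  must declare `#base=0` or `#base=1`; there is no guessing.
- A single-segment bin randomizes to itself; an empty track randomizes to
  an empty track; `n_samples ≥ 1` is enforced.

## Problem sizes used by the test suite

Calibration and power checks run at desk scale, sized by a pre-run power
analysis: type-I calibration uses 500 replicates of a 2 Mb chromosome
(state fraction 0.10, 30 regions, N = 200; expected rejection ≈ 11/201
from the discrete one-sided convention); power/recovery uses 100 replicates
of a 10 Mb chromosome with a 3× plant (300 regions × 500 bp over 5 kb
segments, N = 1,000), and the case/control power check uses 800 regions
× 400 bp over 2 kb segments targeted at the case-specific track. The
detection criterion (p ≤ 0.01 in ≥90% of replicates) and the effect size
are fixed properties being verified; the free design parameters were sized
so the experiment has the power the criterion asserts.

## Known limitations

- The local analysis offers no case/control variant; differential tests are
  genome-wide only.
- No analytic approximation to the null is provided; everything is Monte
  Carlo, so runtime scales with N × segments.
- LD expansion of SNP lists is out of scope; point tracks arrive
  pre-expanded.
- The enrichment ratio is undefined (NaN/error) in bins where the query
  misses the state's complement entirely; extremely small bins are better
  merged upstream.
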