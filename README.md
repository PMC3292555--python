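# chromenrich

Monte Carlo overlap-enrichment statistics between genomic interval tracks —
built for asking whether disease-associated regions or SNPs co-localize with
chromatin-state segmentations (ChromHMM-style BED tracks) in a given cell
type, and whether that co-localization is cell-type specific.

It is aimed at regulatory-genomics analysts who have: a chromatin-state
segmentation per cell type (BED4, one state label per interval), a query
track of regions (e.g. GWAS loci as fixed genetic-width windows around lead
SNPs) or a list of SNP positions, and genome layout files (chrom.sizes,
cytobands, optionally a genetic map).

## The statistics

**Enrichment ratio.** For a state track S and query track Q inside an
analysis bin B, with `cov(X, Y)` the fraction of X's bases covered by Y:

```
enrichment(S, Q; B) = cov(S ∩ B, Q) / cov(B \ S, Q)
```

i.e. the coverage proportion of the state divided by that of its complement.
Ratio 1 means the query is indifferent to the state; >1 enrichment, <1
depletion.

**Length-preserving randomization null.** The query stays fixed; the state's
segments are relocated within each bin (each chromosome for genome-wide
tests, each chromosome arm for local tests) by independently permuting the
empirical multiset of segment lengths and the multiset of the n+1
inter-segment gap lengths (flanks included). Every null sample conserves
both multisets — and therefore the covered base pairs — exactly. The test
statistic is the overlap in base pairs; with N null samples the one-sided
Monte Carlo p-value is

```
p = max(#{samples ≥ observed}, 1) / N
```

so ties count as extreme and the smallest reportable p at the default
N = 20,000 is 0.00005. Local (chromosome-arm) tests drop arms with no query
coverage and control a Benjamini–Hochberg FDR (default 10%) across the
retained arms, per state track.

**Case/control differential test.** To compare one state between two cell
types, bases present in both tracks are removed; the remainder is labelled
case (cell-type specific to the case cell) or control. The observed
statistic is the case-vs-query overlap in bp; the null permutes the
case/control labels over the fixed interval positions. The fold enrichment
difference is `(case overlap / case bp) / (control overlap / control bp)`.

**Point (SNP) test.** Counts points whose base lies inside the state
(half-open coordinates), against the same randomized-track null with the
points fixed; enrichment is the observed count over the mean null count.

All coordinates are 0-based half-open (BED convention) and strand-free.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on a
simulated dataset with known ground truth — a 48 Mb four-chromosome genome
carrying an 11-state segmentation for two cell types, 200 query regions
planted with 3× start-rate enrichment toward the strong-enhancer (SE) state
of the *case* cell type, and 452 SNPs planted 5× toward SE:

```
python analysis/01_simulate_tracks.py
python analysis/02_global_enrichment.py
python analysis/03_arm_level_enrichment.py
python analysis/04_case_control.py
python analysis/05_snp_overlap.py
```

`02_global_enrichment.py` prints, among the 11 states (N = 2,000, seed 17):

```
state  observed_bp  enrichment  p_value  call
   SE       16,065       2.944  0.00150  YES
   WE       12,076       1.131  0.32200  NO
    H      190,029       0.912  0.72450  NO
```

The planted 3× factor is recovered (2.944) and detected; unrelated states
sit near ratio 1. `04_case_control.py` shows the signal is specific to the
case cell type (SE fold difference 14.88, p = 0.00050, all other states
null), and `05_snp_overlap.py` finds 42/452 SNPs (9.29%) in SE, enrichment
5.97 at p = 0.00050, while the large heterochromatic state collects 52% of
SNPs in absolute terms at enrichment ≈ 0.95 — absolute counts and
enrichment deliberately disagree. The arm-level analysis reports no single
significant arm at a 10% FDR: the planted signal is homogeneous, so it is
visible globally but too thin within any one arm — the intended contrast
between the global and local scales.

The same analyses are available as a CLI on your own files:

```
chromenrich overlap-global --states states.bed --query regions.bed \
    --layout genome.chrom.sizes --n-samples 20000 --seed 1 --out results/
chromenrich build-regions --leads leads.tsv --map genetic_map.tsv \
    --layout genome.chrom.sizes --width-cm 0.25 --out regions.bed
```

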