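# Methods

## The mapping model

A bulked-segregant analysis compares pooled allele frequencies between two
groups of recombinant inbred lines selected from the phenotypic extremes
of a cross. Because RILs are homozygous, a pool of n lines is a sample of
n parental alleles per locus; under the null hypothesis that a region is
unlinked to the trait, each pooled line carries the CB4856 allele with
probability ½ independently, so the low- and high-bulk line-equivalents

    l = l̄ · n_l ,   h = h̄ · n_h

(l̄, h̄ = mean CB4856 read frequencies over the SNPs of a 300-kb window)
are modelled as Binomial(n_l, ½) and Binomial(n_h, ½). The window
statistic is the base-10 log-odds ratio

    LOD(w) = log10( (h/(n_h − h)) / (l/(n_l − l)) ),

positive when the high bulk is CB4856-enriched. A QTL is declared where
the statistic exceeds a genome-wide two-tailed threshold derived from that
null; runs of adjacent significant same-sign windows are merged into one
signed interval whose peak is the member window with the largest |LOD|.

### Null model interpretation

The sampling unit of the null is the pooled *line*, not the sequencing
read: read-sampling noise at ~25× depth, averaged over the ~15–30 SNPs of
a window, is an order of magnitude smaller than the line-sampling noise
(window-mean read noise SD ≈ 0.02 versus binomial SD ≈ 0.11 for n = 22),
so the line-level Bernoulli null captures the dominant variance component.
A read-level null would be much narrower and anti-conservative.

### Thresholds

Two constructions are provided and agree:

- `null_threshold_mc` — simulate the null (default 10⁶ trials) and take
  the order statistics at ceil(α/2 · trials) from each tail. This is the
  procedure the pipeline runs by default.
- `null_threshold_exact` — enumerate all (n_l+1)(n_h+1) outcomes with
  their binomial probabilities and choose the smallest (largest) support
  value whose outer tail mass is ≤ α/2. Conservative by construction; the
  discreteness of the support means the achieved two-tailed mass for the
  22/24 design is 0.0481 rather than 0.0500.

Both use the same boundary policy for the statistic: the raw formula is
infinite when a pool is fixed (l ∈ {0, n_l} or h ∈ {0, n_h}), so l and h
are clamped 0.5 line-equivalents from the boundary before evaluation.
Interior values are untouched, so everywhere the formula is finite the
statistic equals it exactly; the fixed-pool outcome has null probability
≈ 2·2⁻²², far below any tail of interest, so thresholds are insensitive to
the clamp value. The threshold is the unadjusted α = 0.05 two-tailed cut
of the per-window null (no multiplicity correction over windows); a
window-level Bonferroni variant can be had by passing a smaller α.

### Filters and frequencies

SNPs are kept when genotype quality is ≥ 40 in *both* pools and when the
per-pool depth — always the sum of that sample's allelic depths (AD), so
the filter is self-consistent with the frequency ratio — is at least the
pool's line count (22 low, 24 high; equality passes). Records missing GQ
in a sample are treated as GQ = 0 and hence removed. Window means are
unweighted across SNPs; windows tile each chromosome from position 1 and
empty windows are omitted (significant runs may bridge them, but not
emitted non-significant windows unless `max_gap > 0`).

### LOESS curves

Per-chromosome fitted frequency curves use locally weighted linear
regression with tricube weights over the span·n nearest neighbours
(span 0.1), via statsmodels' lowess. They are reporting artifacts only;
QTL inference never consults them.

## The simulator

The generator reproduces the experimental design stage by stage, at the
study's stated conditions, which are its defaults:

| parameter | default | why |
|---|---|---|
| chromosomes | 6 (15.1, 15.3, 13.8, 17.5, 20.9, 17.7 Mb) | approximate *C. elegans* I–X sizes |
| genetic length | 50 cM each | canonical ~50 cM *C. elegans* chromosomes |
| SNP spacing | 1 per 10 kb (~10,000 genome-wide) | dense two-strain discriminating panel at desk scale |
| RILs | 116, selfed 10 generations | panel size of the mapped cross |
| bulks | 22 low / 24 high | pool sizes n_l, n_h of the design |
| phenotype | baseline 12 cells, per-animal SD 1.5, 80 animals/line | line means average 80 scored animals |
| QTLs | II +0.8, III +0.8, X +0.4, V −0.5 cells (CB4856 allele) | positive effects sum to the ~2-cell parental gap; V carries the opposite-sign locus |
| sequencing | Poisson depth, mean 25×; base error 10⁻³; GQ 60 | pooled whole-genome coverage of the study |
| forced regions | I:0–3 Mb, IV:0–5 Mb, V:5–15 Mb all-reference | introgressed/incompatible tracts fixed in every line |

Meiosis draws a Poisson crossover count with mean genetic-length/100 (no
interference) and places breakpoints uniformly on the physical axis
(linear cM↔bp map). Each RIL is one independent lineage: the F1
heterozygote selfed G times (the F1→F2 selfing counts as generation 1, so
residual heterozygosity decays as (1/2)^G, ≈ 0.1 % at G = 10); any
remaining heterozygous interval is fixed to one ancestry by a fair coin.
Bulk selection takes the n_l smallest and n_h largest line means, ties
broken by line id for determinism. Forced regions model marker-selected
introgressions and the parental incompatibility region as all-reference
tracts overwritten in every line; their coordinates are placeholders
(the true tract boundaries are not published) and configurable.

What the simulator does *not* emulate: sequence-level reads (no FASTQ,
alignment or variant-calling artifacts), GC/mappability bias in depth,
correlated genotyping error along the genome, crossover interference, and
marker-assisted cross bookkeeping. Passing tests therefore validate the
statistical machinery under the design's sampling model, not robustness
to real-data artifacts upstream of the VCF.

## Numerical and design choices

- **Exact-threshold tie policy**: support values are rounded to 12
  decimals before aggregation so algebraically equal statistics from
  different (l, h) pairs pool their probability mass.
- **MC quantile definition**: tail order statistics at ceil(α/2·trials),
  matching the exact construction's ≤ α/2 guarantee; for the 22/24 design
  the 10⁶-trial thresholds land on the same support atom as the exact ones.
- **Degenerate inputs**: an empty (header-only) VCF maps to an empty QTL
  table and a success exit; zero read totals in a pool raise, since they
  can only occur if filtering was skipped.
- **GT emission**: pooled samples are not diploid, so written genotypes
  are 0/0 or 1/1 only when the pool's reads are pure, else missing; all
  downstream computation uses AD.
- **Peak ties** go to the leftmost window; **bulk relabelling** (low↔high
  with their sizes) negates every statistic and flips interval signs, a
  property the test suite checks end to end.

## Problem sizes

Tests and the calibration script run the study-sized panel (116 lines,
~10,000 SNPs, 336 non-empty windows) directly; repeated-seed checks use
10 replicate simulations, and the null calibration uses 10⁶ threshold
trials plus 10⁵ fresh draws. A full simulate-and-map run takes well under
a second on one core.

## Known limitations

- Adjacent 300-kb windows are ~0.9 cM apart, so their pooled ancestry is
  strongly correlated (≈ 0.96 between neighbouring window counts in a
  RIL panel). The per-window significance level is exact in the marginal
  sense, but threshold excursions arrive in long same-sign runs: even a
  null genome can yield called intervals many windows wide. Interval
  *count* is therefore not a calibrated false-positive measure; the
  per-window exceedance fraction is.
- The log-odds statistic has no interval-width or effect-size estimate;
  peaks of weak QTLs on long chromosomes localise poorly (the simulated
  X-linked +0.4-cell effect peaks megabases from truth in some seeds).
- Real-mode input must already be polarised so ALT = CB4856-like allele;
  the package does not infer parental origin.
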