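# Methods

## Statistical model

### Randomization tests (intersect / closest)

The null hypothesis is that the input regions are an arbitrary same-size
draw from a background universe of regions. Each of N randomizations
(default 100, the smallest count at which the Z-score stabilises in the
stability analysis below; configurable upward) draws |input| records from
the background *without replacement* — the background is treated as the
finite universe the input was selected from, so a null set is a subset of
it, and draws are independent across randomizations. The test statistic is

- **intersect**: the number of regions with ≥ 1 qualifying target overlap.
  A region overlapping several targets counts once. With `ov_fraction` set,
  a hit requires a single target sharing ≥ ceil(ov_fraction × region
  length) nt — the fraction is measured against the *input* region's
  length, since the option gates which input regions count as hits.
- **closest**: the arithmetic mean of per-region distances to the nearest
  target feature. Overlap counts as 0 nt unless `exclude_ov` removes
  overlapping targets from a region's candidates. Touching intervals
  ([0,100) then [100,200)) are 0 nt apart. `exclude_upstream` /
  `exclude_downstream` drop candidates 5′/3′ of the region relative to its
  strand (for unknown-strand input, upstream = lower coordinates). Regions
  with no candidate on their chromosome are dropped from the mean with a
  warning rather than erroring — real peak files routinely cover
  chromosome subsets.

The observed statistic is standardised against the null sample:
`Z = (real − mean) / sd` with the sample (n−1) standard deviation — the
unbiased choice for a finite Monte-Carlo sample; at ≥ 100 draws the
difference from the population form is negligible. The p-value is the
exact two-tailed Gaussian tail `2·Φ(−|Z|)` computed via the complementary
survival function, which stays finite to |Z| ≈ 38 (beyond which the
double-precision tail underflows to 0). A degenerate null (sd = 0) yields
Z = 0, p = 1 when the observation equals the null mean and a signed
infinity with p = 0 otherwise, each with a warning.

Orientation modes filter target candidates by strand relative to each
input region: `concordant` (same strand), `discordant` (opposite),
`strandless` (ignored). Both sides must carry known strands in the
stranded modes. Backgrounds generated without strand information receive
uniform random strands when a stranded mode requires them.

AT/GC-content and length tests compare the input's mean AT fraction, mean
GC fraction and mean region length against the null sets' means — the null
statistic is the per-set mean, matching the mean-based observed statistic.
Ambiguity codes (N etc.) are excluded from both the AT and GC numerators
but kept in the denominator, so AT + GC + ambiguous = 1. These tests are
target-independent; the null sets drawn once per run are shared across all
targets and all test types, so rows of one run are correlated in the same
way repeated use of one randomization batch would be.

No multiple-testing correction is applied across rows — the output mirrors
raw per-row p-values; an optional Benjamini–Hochberg helper
(`regionenrich.benjamini_hochberg`) is provided but off by default.

### Matched background generation

When no biologically meaningful background exists, `--generate_bg` builds
one per randomization: each region's chromosome is drawn from the input's
empirical chromosome frequencies, its length resampled (with replacement)
from the input's empirical lengths, and its start placed uniformly on
[0, chrom_length − length], rejecting placements that intersect the
exclusion mask (bounded retries, then an explicit placement error). A
fresh set of size |input| is generated per randomization rather than
sampling one large pool — this maximises null diversity and is equivalent
in expectation. The generator replicates chromosome frequency and length
only; it is *not* GC-matched or gap-aware.

### Genomic localization

Gene-structure categories are derived from a GTF: the TSS window is
[TSS − halfwidth, TSS + halfwidth) (default halfwidth 200 nt) and the
promoter spans `promoter_span` nt (default 2000) immediately upstream of
the TSS window, both strand-aware and clipped at chromosome bounds; UTRs
and exons come from the annotation, introns are the gene body minus exons,
and intergenic is the complement. The window defaults are the conventional
ChIP-seq annotation choices and are CLI-configurable. Classification is
single-label by highest precedence (TSS > promoter > 5′UTR > 3′UTR > exon
> intron > intergenic) so counts partition the region set and per-category
Z-scores are comparable; a multi-label mode is available. A custom
annotation BED (column 4 = category) replaces the GTF-derived categories.
The analysis is intersect-mode only.

### Ranked enrichment

Scores are min-max scaled to [0,1] (a constant score vector maps to all
0.5 with a warning). The scaled relative rank Ri ∈ [0,1] is the region's
position in the direction-sorted score order (0 = top). The weight

    Wi = Di·α + (1−Ri)·(1−α),   α ∈ [0,1] (default 0.5)

combines the overlap fraction Di (overlapping nt against the merged
target union ÷ region length; intersect variant) or the proximity
1 − scaled distance (closest variant) with the rank. The adjusted score is

    Si′ = Si·((1−w) + w·(1−Wi))   (ascending)
    Si′ = Si·((1−w) + w·Wi)       (descending)

with weighting strength w ∈ [0,1], default 0. At w = 0 the adjusted score
equals the scaled score, whose ordering is bit-identical to the raw score
ordering (min-max scaling is strictly monotone). Sorting is stable with
ties broken by the record order of the interval set handed to the test.

The walk rises 1/Nh at hits (Di > 0) and falls 1/Nm at misses, so it
terminates at 0 exactly; ES is the maximum |excursion|, taken at the
earliest attaining rank (deterministic single-pass argmax). Leading
regions are ranks ≤ peak for positive enrichment (the peak contributed the
final increment, so it belongs to the set) and ranks > peak for negative.
The permutation p is the plain fraction of score-shuffles whose |ES|
reaches the observed |ES| — no +1 correction, so p = 0 is possible and is
annotated "< 1/T" in the CLI summary. Each permutation re-runs the entire
pipeline (scaling, Ri, Wi, Si′, sort, walk) on the shuffled scores.
Permutations consume per-permutation child seeds spawned from the master
seed, so results are identical for every `workers` setting; `workers > 1`
distributes permutations via joblib.

The closest variant orders the per-region nearest-target distances by the
score ranking and forms the normalized cumulative curve
S_real(i) = Σ_{j≤i} D_j / Σ_j D_j, which ends at exactly 1. T shuffles of
the distance-to-rank assignment give an ensemble whose mean is the
expectation curve; ES is the maximum |S_real − ⟨S_shuffle⟩|, signed by the
deviation at the peak. A two-sample Kolmogorov–Smirnov test between the
two curves' value sequences supplies the p-value. Note the caveat: both
curves are deterministic given the data, so the KS p reflects an effective
sample size of N points per curve rather than a conventional two-sample
setting; it is reported as designed, not reinterpreted. All distances zero
(every region overlapping) is a degenerate error advising pre-filtering.
Positive enrichment (real curve above the mean) means top-ranked regions
are *far* from targets; leading regions are the ranks after the peak for
positive deviations, before and including it for negative ones.

## Synthetic benchmark generators

The generators in `regionenrich.synthetic` place regions in disjoint slots
on a 5 × 10 Mb synthetic genome (default region length 200 nt), which
guarantees mutual non-overlap within each file and exact control of the
engineered quantities; every generator asserts its engineered properties
before returning, and every fixture is bit-identical regenerable from its
parameters and seed.

- **Overlap benchmark** (defaults 500 input / 2000 background / 5000
  target): exactly 125 input regions overlap a target by half a region
  length; the background is the input plus 1500 non-overlapping extras, so
  the input overlaps at 25% against the background's 6.25%. The
  hypergeometric expectation for a 500-of-2000 null draw is 31.25
  overlaps, SD ≈ 4.7, placing Z near 20.
- **Proximity benchmark**: each input region sits at an integer gap
  sampled from N(1000, 200²) nt (truncated to [1, 4799] so its assigned
  target is provably its nearest feature and nothing overlaps) from a
  distinct target; background extras use N(1400, 600²). The null mean
  distance is ≈ 1300 nt; the analytic SD of a 500-of-2000 sampled mean
  under these mixtures is ≈ 21 nt, so Z concentrates near −14.
- **Ranked benchmarks**: 100 regions, 25 overlapping with scores
  N(5, 3²) and 75 non-overlapping with N(6, 3²) (intersect variant); 35
  near (100 ± 50 nt) / 65 far (150 ± 50 nt) with the same score split
  (closest variant). The score separation is mild — the large-N drift
  bound on the walk is max_s Φ((s−5)/3) − Φ((s−6)/3) ≈ 0.13 — so replicate
  ES values centre near 0.26 with SD ≈ 0.09 and single draws reaching 0.4
  are unexceptional.
- **Ratio sweep**: input overlap fixed at 25% while engineered background
  extras set the background overlap percentage to 25/ratio. Because the
  background contains the input, its overlap percentage cannot exceed
  81.25%, bounding achievable ratios below by ≈ 0.31; the default sweep
  spans 1/3 to 4.

What the generators deliberately do not emulate: realistic peak width or
GC distributions, chromosome-end effects, clustered/correlated peak
placement, or assembly gaps. Passing tests therefore demonstrate the
statistics' correctness and calibration under clean exchangeable nulls,
not robustness to the positional biases of real chromatin data — for real
data the background file choice carries that burden.

## Numerical conventions and edge cases

- Coordinates: 0-based half-open everywhere; GTF (1-based closed)
  converted on read. Zero-length intervals are rejected.
- Chromosome names are taken literally; zero shared names between input
  and target triggers a warning, not an error.
- Duplicate identical records are retained — counts reflect the file as
  given.
- Sorting of interval sets is total and deterministic ((chrom, start, end,
  name, strand)); BED `track`/`browser`/`#` lines are skipped.
- Equidistant left/right closest candidates tie harmlessly (the distance
  is identical); the implementation reports the left gap first.
- Master seed → per-randomization/per-permutation child seeds via
  `numpy.random.SeedSequence.spawn`; outputs are byte-identical across
  repeated seeded runs and worker counts.
- Overlap/closest primitives use per-chromosome sorted arrays with
  prefix-maximum end bounds (binary search per query); the test suite
  cross-checks them against a brute-force all-pairs oracle
  (property-based) and against `bedtools intersect -u` / `closest -d`
  (whose distance convention differs by 1 for non-overlapping pairs:
  bedtools reports gap + 1, this package reports the nearest-edge gap).

## Known limitations

- The Gaussian conversion of Z assumes an approximately normal null; for
  very small backgrounds or extreme overlap counts the empirical null is
  discrete and skewed, and the tail p-values inherit that approximation.
- The closest-mode KS p-value has the interpretive caveat above.
- The matched background replicates chromosome frequency and length only.
- Localization precedence is a modelling choice; regions spanning multiple
  categories are assigned to the highest-precedence one.
- Test-suite and benchmark problem sizes (e.g. 20-replicate Z panels,
  50-replicate ES panels, T = 1000 permutations) were chosen to make the
  Monte-Carlo noise small relative to the asserted bands while keeping the
  default suite fast.
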