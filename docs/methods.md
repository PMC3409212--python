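# Methods

`cnakit` analyzes cohorts of tumor copy-number profiles: per-probe absolute
copy numbers (diploid = 2.0) are quality-controlled, centered, segmented,
classified into five aberration bins, and summarized at cohort level as
recurrent regions, focal peaks, group differences, dosage–expression
concordance, co-occurrence networks, and survival associations.  This note
records the models, the defaults, and the numerical choices behind each
stage, and what the synthetic cohorts used in the test suite do and do not
establish about real data.

## Coordinates and scales

Internal coordinates are 0-based half-open on chromosomes 1–22, X, Y;
SEG and probe-matrix files are 1-based (SEG end inclusive), BED is 0-based
half-open.  Conversion happens once, at the I/O boundary.  Copy number is
carried in absolute copies because every classification threshold is defined
on that scale; SEG files holding log2 ratios are converted at read time via
CN = 2·2^log2ratio.

## Sample QC (MAPD)

MAPD is the median over consecutive same-chromosome probe pairs of
|cn[i+1] − cn[i]|.  Genuine copy-number steps contribute only a handful of
pairs, so MAPD tracks probe-level noise rather than genomic instability.
Samples with MAPD > 0.6 are removed (`mapd_cutoff`).  MAPD is computed on
raw centered values; an optional running-median smoother (window 5, odd) is
available but not applied before QC.

## Centering

A profile is anchored by the mode of its per-probe value density (Gaussian-
smoothed histogram, bandwidth 0.1 copies, grid at bandwidth/4): the mode is
shifted to 2.0.  The mode rather than mean/median is used because aneuploid
genomes can hold well under half of their probes at the true diploid level
while diploidy remains the largest single cluster.  If a normal-tissue
baseline cohort is supplied, each probe is first divided by the normal-cohort
median at that probe and rescaled to copies, removing probe-specific
affinity.

## Segmentation (CBS)

Each chromosome is segmented independently by recursive binary splitting.
At each step the circular two-sample statistic

T = max over arcs (i,j] of |mean(arc) − mean(rest)| / (σ̂·sqrt(1/k + 1/(n−k)))

is maximized exhaustively over all arcs (O(n²), JIT-compiled with a pure
numpy fallback).  The noise scale σ̂ comes from consecutive differences:
the lower quartile of |Δ| divided by 0.45049 (the 0.25 quantile of a
half-normal with scale σ√2), floored at half the median-based estimate.
The quartile form tolerates up to 75% of differences being true steps
(heavily rearranged genomes); the floor prevents collapse on short
intervals where low order statistics of a handful of differences are
biased toward zero.

A split is accepted at p ≤ alpha (default 1e-6) under a hybrid rule:

1. Bonferroni bound over all n(n−1)/2 candidate arcs on the Gaussian tail of
   T; if the bound is ≤ alpha the split is accepted.
2. When alpha is below the resolution any permutation test could reach
   (alpha < 1/(n_perm+1), as with the defaults alpha = 1e-6 and
   n_perm = 10,000), the bound alone decides — a permutation estimate can
   never certify p ≤ 1e-6 at feasible permutation counts.
3. Otherwise, a within-interval permutation test with early stopping
   supplies the p-value.

The bound is conservative, so a split it accepts would also be accepted by
an exhaustive permutation test; splits it rejects at step 2 are the price of
demanding 1e-6.  Empirically (test suite), 1000 null chromosomes of 200
probes at noise sd 0.15 produce zero splits, while planted steps of one copy
are localized within ±2 probes.

Adjacent segments with mean difference < `merge_tol` (0.3 copies) are merged
afterwards; chromosomes with fewer than `min_probes` (3) probes return a
single segment.  Segment boundaries fall midway between flanking probes, and
chromosome ends are taken from the genome table so segments tile each
chromosome.  An optional rank transform of the probe values before the
statistic is available (`cbs_rank`); it defaults off because when one
copy-number level holds most of a chromosome, ranking spreads that level's
ranks across the whole band, inflating the within-level spread and blunting
sensitivity to short events at very small alpha (in pilot runs it
undercounted per-tumor events by roughly 45%).

## Five-bin classification and event counting

Segment means map to: amplified (> 3.8 copies), gained (2.3, 3.8], unchanged
[1.7, 2.3], deleted [0.5, 1.7), homozygously deleted (< 0.5).  Boundary
values resolve toward no-call: 1.7 and 2.3 are unchanged; 3.8 is gained;
0.5 is deleted.  A CNA *event* is a maximal run of adjacent same-direction
non-neutral segments on one chromosome (gained+amplified merge; likewise the
deletion bins), so a focally re-amplified region inside a gained arm counts
once.  Sex chromosomes are excluded from event counts by default
(config-switchable), matching their exclusion from clustering.

## Frequency tracks, MCRs and STAC significance

The marker grid defaults to the probe grid.  Per marker, the gain (loss)
fraction is the proportion of samples whose covering segment is gained or
amplified (deleted or homozygously deleted); markers uncovered by a sample's
segmentation count as unchanged and are logged.

Minimal common regions: within each maximal run of markers at or above
`mcr_min_freq` (10%), the peak marker's carrier set is extended in both
directions for as long as every carrier remains aberrant — the minimal
region shared by the largest set of overlapping events.  Significance uses
the interval-placement permutation logic: per permutation, every sample's
directed aberration intervals are re-placed uniformly among valid
non-wrapping positions (lengths preserved; per-sample coverage capped at 1),
and a region's p is the fraction of permutations whose *maximum* marker
frequency anywhere on the chromosome reaches the observed peak count — a
chromosome-wide max-statistic correction.  The frequency statistic is
implemented; the footprint statistic is not (the frequency is the quantity
the downstream tables report).  Per-sample interval-length lists are sorted
before the permutation draws so p-values are exactly invariant to sample
order.  Note that near-chromosome-length events are nearly invariant under
re-placement, so arm-level recurrences carry little evidence under this
null by construction; it is focal recurrence that the test resolves.

## Focal peaks (G-scores)

The focal component of a sample's marker-level profile is its copy number
minus the chromosome-arm median: broad events vanish; focal amplification
amplitude is the positive part, focal deletion amplitude the negative part
(both in copies, scored symmetrically).  The G-score at a marker is the sum
of one direction's amplitude over samples.  The null shifts each sample's
amplitude vector circularly within each chromosome by an independent uniform
offset; the empirical p at a marker is the probability that the score at a
random marker of such a shifted cohort reaches its G.  Because the random
marker is uniform and shifts are uniform and independent across samples,
that null score is distributed as the sum over samples of one uniformly
drawn marker value per chromosome — sampled directly (100 draws per nominal
permutation) without materializing shifted genomes.  Q-values are
Benjamini–Hochberg over markers; `gistic_q` = 0.25.

Peaks are called by iterative peel-off: take the genome-wide G maximum among
q < cutoff markers; trim by leave-one-out (remove the single top-contributing
sample and keep the surrounding markers still significant without it);
annotate genes overlapping the trimmed interval; zero the carriers'
amplitude across the significant run; repeat until nothing passes.  Each
round strictly reduces remaining amplitude mass, so the loop terminates.
This is a deliberate desk-scale reduction of full GISTIC2: no arbitrated
broad/focal decomposition, no gene-level variant, no wide-peak confidence
intervals — the semantics kept are recurrence × amplitude with focal
emphasis and FDR control.

## Group comparisons, burden and clustering

Per-marker two-group comparison: a two-sided Fisher exact test on the 2×2
carrier table plus the frequency-difference rule (> 15 percentage points).
Both rules are required for the `significant` flag and are independently
toggleable; no multiple-testing correction is applied to the flag (a BH
column is emitted alongside).  The 15 is percentage points, not relative
percent.  Burden differences use Welch's unequal-variance t-test (the group
spreads differ severalfold).  Clustering is complete-linkage agglomerative
on Euclidean distance over gene-level copy number (configurable to
1 − Pearson), sex-chromosome genes excluded (enforced, not silently
dropped), tree cut at `cluster_k` = 3; samples are sorted by id before
linkage so the assignment is order-invariant.  Cluster–label enrichment is
a per-(cluster, level) two-sided Fisher test with pairwise exclusion of
missing labels.

## Gene-level copy number and cis concordance

A gene's copy number per sample is the *unweighted* mean of the mean copy
numbers of all segments overlapping the gene body (an overlap-length
weighted variant exists behind a flag); genes with no covering segment are
missing.  Cis concordance of a gene's mRNA with its own copy number is
summarized per aberration class on per-gene centered expression, with two
statistics: a Jonckheere–Terpstra trend test across the ordered classes
(normal approximation, ties counted half in J; the no-ties variance is used,
adequate for continuous expression) and the Spearman correlation between
numeric copy number and expression.  Genes with fewer than two classes of
at least two samples are flagged untestable.  The trend-test choice is an
implementation decision — any monotone-trend test would serve — and is
isolated behind the concordance interface.

## Pathway enrichment

Gene sets are filtered to 10–500 members after intersection with the
universe.  Per set: overlap k, two-sided Fisher exact p, and fold enrichment
(k/|hits|)/(|set∩universe|/|universe|).  The permutation FDR replaces every
set by a random same-size draw from the universe in each of `perm_fdr_n`
(100) permutations: FDR(s) = mean permuted count of sets with p′ ≤ p(s)
divided by the observed count with p ≤ p(s), clipped at 1.  This plug-in
estimator is one concrete reading of a permutation FDR at fixed set sizes;
it is seed-controlled and documented here because other readings exist.

## Correlation networks

Pearson correlation between all gene pairs (pairwise-complete, pairs with
fewer than 3 shared observations or constant genes are missing).  The edge
graph keeps |r| ≥ 0.3, optionally restricted to inter-chromosome (unlinked)
pairs; hub structure is summarized by the OLS slope of log(count) against
log(degree) over nonzero histogram bins — an operational summary, not a
formal power-law fit.  The randomization null shuffles sample labels
independently per chromosome: within-chromosome (linkage-driven)
correlations are left exactly invariant while cross-chromosome structure is
destroyed; observed vs null inter-chromosome degree distributions are
compared by a two-sample Kolmogorov–Smirnov test.

## Survival scans

Every recurrent region (MCR or focal peak) defines carriers — samples whose
class at the region matches its direction — and each region × endpoint
(OS, RFS) × stage stratum (II, III, combined) is tested with the standard
two-group log-rank statistic (via lifelines), direction read from the sign
of observed-minus-expected carrier events.  Unadjusted p at 0.01 drives the
`significant` flag, mirroring the single-test convention of the tables the
scan feeds; a BH column is emitted beside it because a genome-wide scan is
heavily multiple and readers should see both.

## The synthetic cohort generator

The generator produces cohorts with the statistical structure the analysis
assumes, with ground truth recorded, so every stage is testable end to end.

**Genome.** A miniature genome with human build-36 chromosome and centromere
proportions scaled by 1/20 (~154 Mb, ~3,000 probes at the default 50 kb
spacing).  This keeps arm-level versus focal geometry while letting a
300-sample cohort simulate and segment in a few seconds; the scale and probe
spacing are configurable.

**Study conditions (defaults).**  The MSS arm plants recurrent events at
fixed cohort frequencies: gains of 20q (72.5%), 13q (51.0%), chromosome 7
(41.8%), 8q (33.1%) at 3.0 copies, and losses of chromosome 18 (58.6%), 4q
(26%), 21q (21.6%) at 1.0 copies.  Mixed cohorts add focal deletions at
scaled 16q23.1 (24.2% of MSI, 7.1% of MSS), 20q11.1 (24.4% / 8.9%) and
3p14.2 (24.3% of stage III, 3.3% of stage II) loci, 600 kb wide.  Cohort
sizes default to 269 MSS / 33 MSI with a 239:30 stage III:II split among
MSS.

**Burden.**  Per tumor, the total event count is negative binomial matched
to the group's moments (MSS 33.2 ± 17.6, MSI 10.2 ± 6.5; Poisson when the
requested variance is at or below the mean).  Planted events count toward
the total; the background count is the remainder (floored at 0), so planted
recurrences are part of, not on top of, the stated burden.  A planted
expectation exceeding the burden mean is rejected.

**Background events.**  Random arm placements, lengths log-uniform between a
400 kb floor (8 probes — the smallest event the default segmentation
resolves comfortably) and the whole arm, direction ±1 copy.  Background
events are placed with no overlap and a 3-probe neutral gap to any other
event of the sample, and never touch a planted locus *in any sample*.  Both
choices are deliberate departures from purely uniform placement: the first
makes the realized per-tumor event count exactly recoverable as merged
same-direction segment runs, and the second keeps a planted cohort
frequency recoverable as the realized carrier fraction rather than carrier
fraction plus background hits.  Overlapping planted events (a focal deletion
inside a gained arm) add in copy number, floored at zero.

**Carriers.**  Independent Bernoulli per event within the event's group
restriction; a Gaussian-copula variant draws carrier indicators with
requested pairwise correlations while preserving the marginals (events
planted as carrier when the latent normal falls below the frequency
quantile).

**Expression.**  Per gene (synthetic models every 500 kb):
expr = intercept + slope·CN + noise, with the true CN taken from the
noiseless event stack at the gene midpoint (defaults: slope 0.5, noise sd
0.3).

**Survival.**  Exponential event times with per-sample hazard
h0·∏HR(event carried); censoring uniform over an 84-month follow-up window;
defaults h0 = 0.013/month (≈ 40% observed events) and a protective OS
hazard ratio of 0.5 (RFS 0.7) attached to the 20q gain.  The
BRAF-mutant-like expression label is drawn at 5% among 20q-gain carriers
and 55% among non-carriers, giving clusters defined by chromosome-20 status
a strongly enriched label, with BRAF mutation more frequent inside the
labelled group.

**What passing tests do and do not show.**  The generator's noise is
homoscedastic Gaussian per probe (sd 0.15); real degraded-tissue arrays have
heavier tails, GC/wave trends and probe-specific affinity, none of which
are emulated (the rank-transform option and the normal-baseline correction
exist for such data but are unexercised by the defaults).  Events are clonal
(no subclonal fractions), breakpoints are clean, and background events avoid
each other — so recovery results demonstrate the correctness of the
statistics and bookkeeping under the declared model, not robustness to
array artifacts.

## Problem sizes used in the checks

The acceptance script and test suite run at the cohort sizes of the default
study conditions: 269 MSS and 33 MSI samples, 10 seeded cohorts per burden
and arm-frequency estimate, 20 for the focal-locus frequencies.  Calibration
suites use 1000 null chromosomes (segmentation), 200 null chromosomes at
1000 permutations (recurrence), 200 broad-only cohorts (focal peaks) and
500 null replicates (log-rank).  The differential-frequency detection check
evaluates its majority claim over 150 seeded runs, segmenting only the two
locus-bearing chromosomes per run — the detection statistic is unchanged by
ignoring chromosomes it never reads.

## Known limitations

* The STAC-style frequency null cannot certify arm-level recurrence (see
  above); an arm-aware null is out of scope.
* The hybrid CBS p-value is conservative below permutation resolution;
  alpha values between ~1e-4 and 0.2 mix bound and permutation decisions.
* The peel-off trim is a single leave-one-out step, not a confidence
  interval; reported peak intervals are point estimates.
* The permutation FDR for pathway enrichment is a plug-in estimator and can
  exceed BH-style estimates on small set collections.
* No GC/wave correction, no allele-specific analysis, no ploidy correction
  beyond modal centering, no Cox modelling or covariate adjustment.
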