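# cnakit

Cohort-scale analysis of somatic copy-number aberrations (CNAs) in tumor
genomes — built for studies like stage-II/III colorectal cancer cohorts
profiled on copy-number arrays, where the questions are: which regions are
recurrently gained or lost, which focal amplicons and deletions rise above
the broad background, how aberration burden and specific loci differ between
clinical groups (microsatellite-instable vs stable, stage II vs III), whether
DNA dosage drives mRNA expression in cis, which unlinked loci co-occur more
often than chance, and which regions associate with survival.

## What it computes

Starting from per-probe absolute copy numbers (diploid = 2.0):

1. **QC** — median absolute pairwise difference (MAPD); samples > 0.6 removed.
2. **Centering** — the modal copy-number of each profile is anchored at 2.0
   (optionally after dividing by a normal-tissue baseline).
3. **Segmentation** — circular binary segmentation: recursive maximization of
   the arc statistic T = |mean(arc) − mean(rest)| / (σ̂·√(1/k + 1/(n−k)))
   with a robust consecutive-difference noise scale σ̂, split accepted at
   p ≤ 1e-6.
4. **Classification** — five bins in copies: amplified (> 3.8), gained
   (2.3, 3.8], unchanged [1.7, 2.3], deleted [0.5, 1.7), homozygously
   deleted (< 0.5); per-tumor CNA events are merged same-direction runs.
5. **Recurrence** — minimal common regions (plateau of the gain/loss
   frequency track above 10%) with interval-placement permutation p-values
   (chromosome-wide max-statistic correction, cutoff 0.01).
6. **Focal peaks** — per-marker G-score G(m) = Σ_samples amplitude_s(m) on
   the arm-median-subtracted focal component, circular-shift permutation
   null, Benjamini–Hochberg q < 0.25, iterative peel-off peak calling.
7. **Group comparison** — per-marker Fisher exact test plus a > 15
   percentage-point frequency-difference rule; Welch t-test on CNA burden;
   complete-linkage hierarchical clustering (sex chromosomes excluded) with
   cluster–label enrichment.
8. **Dosage–expression** — gene-level copy number (unweighted mean over
   overlapping segments), per-class expression summaries, Jonckheere–Terpstra
   trend and Spearman correlation; pathway over-representation with a
   100-permutation FDR over 10–500-member gene sets.
9. **Networks** — genome-wide gene–gene Pearson correlation, |r| ≥ 0.3 edge
   graphs restricted to unlinked (inter-chromosome) pairs, degree
   distributions, and a per-chromosome sample-shuffling null compared by a
   Kolmogorov–Smirnov test.
10. **Survival** — Kaplan–Meier / log-rank scans of every recurrent region
    against OS and RFS, per stage stratum, at p < 0.01.

A synthetic-cohort generator (`cnakit.simulate`) plants all of this
structure — group-specific burdens, arm events at fixed frequencies, focal
deletions, dosage slopes, survival hazards — with recorded ground truth, so
the whole pipeline is testable without access to patient data.

## Worked example

```python
from cnakit import CohortAnalysis, CohortSpec, simulate_cohort

sim = simulate_cohort(CohortSpec.default_combined(n_mss=60, n_msi=12), seed=5)
analysis = CohortAnalysis.from_simulation(sim)
results = analysis.fit(seed=1)
print(results.summary())
```

```
Cohort copy-number analysis
=============================
samples: 72 (0 failed MAPD QC)
segments: 5915
events/tumor: mean 31.3 sd 17.7
burden MSS_vs_MSI: 35.7±15.9 vs 9.8±7.3 (Welch t=8.81, p=1.8e-10)
MCRs: 87 (4 at STAC p<0.01)
focal peaks (q<0.25): 0
comparison MSI_vs_MSS_gain: 391 significant markers
comparison MSI_vs_MSS_loss: 83 significant markers
comparison III_vs_II_gain: 0 significant markers
comparison III_vs_II_loss: 1 significant markers
clusters: 1:4, 2:67, 3:1
cis concordance: 280 testable genes
network: max degree 96, log-log slope -0.63
survival associations at p<0.01: 2
```

Reading this: the microsatellite-stable arm carries ~3.5× the aberration
burden of the instable arm (Welch p ≈ 2e-10); 87 recurrent regions clear the
10% frequency floor, of which 4 focal ones clear the placement-permutation
test (arm-length events carry little evidence under that null — see
`docs/methods.md`); the marker-level comparisons flag the planted
group-restricted differences; clustering splits the cohort on its dominant
arm-level patterns; and the survival scan flags the protective 20q-linked
regions.  `results` also carries every table as a DataFrame
(`results.mcr_table`, `results.peak_table`, `results.survival_table`, …).

The same run from the shell:

```bash
cna simulate --preset combined --n-mss 60 --n-msi 12 --seed 5 --out cohort/
cna run-all cohort/ --seed 1 --out results/
```

writes the cohort as plain tab-delimited files (probe matrix, clinical
table, expression, BED gene models) and the results directory with one
table per stage plus a `manifest.json` recording config, seed and row
counts.  Reruns with the same seed are byte-identical.

## Layout

```
src/cnakit/
  genome.py        coordinates, miniature genome, arm tables
  io.py            SEG / BED / GMT / matrix / clinical readers and writers
  qc.py            MAPD, centering, smoothing
  segmentation.py  circular binary segmentation
  calling.py       five-bin classification, event counts, frequency tracks
  recurrence.py    minimal common regions + placement permutation test
  gistic.py        focal component, G-scores, peel-off peaks
  compare.py       group comparisons, burden test, clustering, enrichment
  dosage.py        gene-level CN, cis concordance, pathway enrichment
  network.py       correlation graphs, degree distributions, null model
  survival.py      log-rank scans and Kaplan–Meier curves
  simulate.py      synthetic cohorts with ground truth
  model.py         CohortAnalysis / CohortResults facade
  pipeline.py      staged runner writing result tables
  cli.py           `cna` command-line interface
```

`docs/methods.md` documents the statistical model behind every stage, all
defaults, and the generator's assumptions and limitations.
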