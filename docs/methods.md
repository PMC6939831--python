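# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, and the known limits of what the synthetic
experiments demonstrate.

## Data model and coordinate conventions

Genotypes are held as a samples × sites matrix of alt-allele dosages
{0, 1, 2} with a single MISSING sentinel; only biallelic
single-nucleotide records are ingested (indels and multiallelic records
are counted and skipped) because every estimator downstream assumes a
well-defined dosage. Half-calls (`./1`) become MISSING: their dosage is
ambiguous. All in-memory coordinates are 1-based inclusive (the
VCF/GFF3 convention); BED's 0-based half-open convention is converted at
the file boundary and nowhere else. Chromosome names are matched by
exact string equality — mismatches are reported, never guessed.

## Variant filtering

A site is kept iff its missing fraction is ≤ 0.10 and its minor-allele
frequency among non-missing dosages is ≥ 0.10. Both cut-offs are the
standard stringency for population scans of this design and are
configurable (`filter_variants(max_missing=, min_maf=)`). The MAF rule
uses ≥ at the boundary: a site at exactly 10% passes.

## Windowed statistics

Windows tile each chromosome from position 1 in steps of `step`
(default: the window size, i.e. non-overlapping 5-kb windows); the final
partial window is kept and flagged. Windows with fewer than
`min_sites = 3` variants are reported but excluded from percentile
thresholds — single-SNP windows produce extreme, uninformative values.

**π.** Per-site diversity is the unbiased pairwise estimator
2ra/(c(c−1)); the window value divides the sum over variant sites by the
*full window length in base pairs*, so "per site" means per bp and
monomorphic positions contribute zero. The alternative (dividing by the
number of variant sites) changes the scale of ROD's inputs but not ROD
itself when both groups are observed at the same sites; the per-bp
convention is the one under which π is a diversity density comparable
across windows. A site where a group has fewer than two non-missing
alleles is skipped for that group's π.

**F_ST.** Weir & Cockerham's (1984) two-population estimator with
observed heterozygosity, combined across sites as a ratio of summed
variance components Σa/Σ(a+b+c) — the "ratio of averages", which is the
convention of the common VCF tooling and is much less noisy than
averaging per-site ratios. Negative window values are reported
unclamped so that the empirical percentile is well defined; values are
capped above at 1. Sites where either group has fewer than two
non-missing genotypes are skipped (the estimator needs n̄ > 1). Hudson's
estimator (Bhatia et al. formulation) is available behind the same
interface for sensitivity analyses.

**ROD.** 1 − π_fw/π_mig, undefined (NA) when π_mig = 0. Range (−∞, 1];
positive values mean the freshwater group lost diversity.

## Sweep selection

Thresholds are the empirical 0.95-quantiles (linear interpolation
between order statistics, the "type 7" rule) of F_ST and ROD over
eligible windows — both thresholds from the same window set. Selection
is the strict intersection: fst > thr_fst AND rod > thr_rod; windows
with undefined ROD are never selected. Selected windows merge into
regions when their gap is ≤ `max_gap` (default 0, i.e. adjacency only:
the reported regions are exactly the selected windows). A gene is a
candidate when it overlaps a region by ≥ 1 bp (configurable).

## Population grouping

The 1-IBS distance between two samples is the mean of |dosage_i −
dosage_j|/2 over the sites where both are observed, normalized by that
pair's own non-missing count (per-pair renormalization, matching PLINK's
"flat-missing" behaviour). A pair sharing zero observed sites is an
error, not a guess. Neighbor joining is the classic Saitou–Nei
agglomeration with Q(i,j) = (n−2)d(i,j) − r_i − r_j, ties broken by the
lowest active-index pair, negative branch lengths clamped to zero with
the deficit logged, and a final degree-3 hub join. The two-group call
removes the longest internal edge (ties: the edge whose smaller side is
larger, then lexicographic) and returns the induced leaf bipartition;
the smaller side is labelled freshwater because residents are the
minority phenotype in this design. A user-supplied grouping always
overrides the inferred one downstream.

## Effect classification

A variant in a CDS is translated in its codon with ref and alt base
(reverse-complemented on the minus strand; codon phase from the
cumulative CDS length in 5′→3′ transcription order): equal amino acids →
synonymous. Inside a gene but outside CDS → intronic; within `flank`
bp (default 5,000) 5′ of the gene start, strand-aware, → upstream, the
3′ counterpart → downstream; otherwise intergenic. When several genes
apply the most severe class wins (coding > intronic > up/downstream >
intergenic), ties going to the nearest gene. The flank default is a
conventional promoter-scale distance; it is configurable and logged.
Only the standard nuclear codon table is supported; an ambiguity base in
the codon excludes the variant with a warning, and a gene whose CDS
length is not a multiple of 3 is excluded with a warning.

## Tests of association and enrichment

The per-SNP test is the two-sided Fisher exact test on the 2×2 table of
(group × {ref, alt}) allele counts, two-sidedness by point-probability
ordering (every same-margin table whose probability is ≤ the observed
one, with 1e-12 relative slack for floating-point ties). Raw p-values
drive the default flag (p < 0.01); Benjamini–Hochberg q-values are
reported alongside for users who prefer FDR control. Term enrichment
uses the 1-df χ² without continuity correction when all expected counts
are ≥ 5 and the Fisher exact test otherwise, per the GOstat convention;
enrichment flags default to raw p < 0.05, again with q-values reported.

## Phenotype analyses

Otolith Sr:Ca (×1000) water classes: freshwater ≤ 3.0 < brackish ≤ 7.0
< seawater, boundary values falling to the lower class per the interval
notation. The life-history rule smooths the core→edge transect with a
3-point running median (endpoints unsmoothed) and calls "migratory" iff
some run of ≥ `min_run = 3` consecutive points is non-freshwater — a
run-length operationalization of "constant" vs "alternating" colour
patterns that rejects single-point excursions; min_run is configurable.

qPCR relative expression is 2^−ΔΔCт with the calibrator centring on the
arithmetic mean of ΔCt (equivalently the geometric mean of RQ, which is
therefore exactly 1 in the calibrator group). Group comparisons use a
pooled-variance Student t-test by default (Welch available); DEG flags
require fold > 2 AND p < 0.05, with the t-test computed on log2(x+1).

## Synthetic cohorts

The generator draws site positions uniformly (deduplicated), ancestral
frequencies p ~ Uniform(0.05, 0.95), and per-population frequencies from
the Balding–Nichols Beta distribution with dispersion F — closed-form
expectations make the realized differentiation checkable (the
Weir–Cockerham estimator targets F when both populations drift with that
F). Defaults mirror the study design the package addresses: 85
migratory + 11 freshwater samples, background F = 0.02, one SNP per
200 bp, 3% missingness, two 500-kb chromosomes each carrying one 25-kb
sweep. Inside sweeps the freshwater population gets strong drift
(F = 0.6) and its minor-allele frequency is multiplied by 0.1 — a
marginal-frequency distortion producing the sweep signature (low π_fw,
high F_ST and ROD) without simulating hitchhiking dynamics. What the
generator deliberately omits: linkage disequilibrium, demography,
realistic allele-frequency spectra, sequencing error, and genotyping
bias. Passing recovery tests therefore shows the *scan logic* is sound
at the planted effect sizes, not that real data of this species would
yield comparable power.

All draws come from one integer-seeded NumPy generator in a fixed
order; fixed config + seed reproduces outputs byte-identically across
platforms. The pipeline driver derives per-stage seeds by hashing
(master seed, stage name), so single stages re-run reproducibly.

## Numerical choices and problem sizes

Percentiles use NumPy's default (type 7) interpolation. Fisher p-values
are sums of scipy hypergeometric pmf values with a cached pmf per margin
family. NJ tie-breaks and the longest-edge tie-breaks are deterministic
as described so trees and splits are stable across runs. The test suite
validates π against pair enumeration (≤ 8 samples × ≤ 50 sites), F_ST
against an independent scalar textbook implementation (200 random small
datasets, 1e-12), Fisher against exact integer enumeration (all 2×2
tables with N ≤ 60, 1e-10), and NJ against path-distance reconstruction
on 100 random additive matrices (1e-9) plus topology agreement with
scikit-bio's implementation; recovery experiments use 20 cohorts at the
default design (≈ 5,000 SNPs each), which keeps the whole suite under
half a minute while leaving the Monte-Carlo acceptance margins wide.

## Known limitations

- The scan assumes exactly two groups; no hierarchical structure.
- No haplotype statistics (iHS/XP-EHH), Tajima's D, or LD pruning.
- The effect classifier covers point substitutions only (no splice
  sites, UTRs, frameshifts or multi-nucleotide variants), and term maps
  are taken as given (no ontology graph propagation).
- The two-group tree split is a heuristic stand-in for expert judgment;
  with weak divergence the longest internal edge need not separate the
  populations — recovery at the default effect sizes is near-perfect,
  but this is a property of the planted divergence.
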