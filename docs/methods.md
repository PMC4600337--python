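# Methods

This note documents the models, parameter choices and numerical conventions
behind `hydromap`, in the order the pipeline runs them.

## Synthetic founder populations

The generator (`hydromap.simulate`) emulates a closed, inbred breed in
which a recessive lethal allele descends from a single founder haplotype.

**Haplotype model.** One chromosome carries `n_markers` evenly spaced
biallelic markers (default 1,000 at 44 kb, the genome-wide density of a
~54k equine SNP chip). Background alternative-allele frequencies are drawn
uniformly on [0.05, 0.5], so unlinked markers pass a 5% MAF filter by
design. One founder haplotype is fixed; the disease allele exists only on
it (background frequency 0 at the disease marker).

**Descent segments.** The distance from the disease locus to the nearest
ancestral recombination on a founder-descended chromosome is modelled as
memoryless: each side of a founder segment extends by an independent
exponential draw with mean `case_ibd_length_mean_bp`. A case carries two
such segments; their intersection — the case's homozygous-by-descent (HBD)
segment — is therefore exponential on each side with half that mean, and
its expected total length equals `case_ibd_length_mean_bp` exactly (the
parameter is defined as the mean HBD segment length; the default 10.5 Mb
matches the homozygosity extent typical of a recent founder mutation in a
closed studbook). Obligate carriers carry exactly one founder segment;
each control chromosome carries one with probability `carrier_frequency`
(default 0.17, a realistic carrier rate in a heavily bottlenecked breed),
and control draws are rejected until at most one chromosome is
founder-derived, so no control is homozygous for the disease allele.
Segment endpoints snap to marker positions; every case's HBD interval
contains the disease locus by construction.

**Noise.** Genotyping error applies symmetric single-step flips
(hom→het; het→either hom with equal probability) at rate 0.001 per
genotype — the order of duplicate-discordance rates reported for Infinium
BeadChips — and missingness is independent at rate 0.004 (a ~99.6% mean
call rate). Both are configurable.

**Pileups.** Read support at a site is Poisson(depth) coverage with
Binomial(coverage, f) alternative reads, f = e, 0.5, 1−e for genotype
codes 0/1/2 at base-error rate e; supporting observations fall in the
first 25 bases of a 75 bp read with probability 25/75; mean supporting
base quality is Normal(35, 2) clipped to [2, 42]. Default depth 216×
mirrors deep targeted resequencing.

**What the generator does not model:** population LD beyond the founder
segment (background markers are in linkage equilibrium), allele-frequency
spectra skewed by ascertainment, batch or plate artefacts in genotyping,
mapping artefacts or strand bias in pileups, X-linked inheritance, and the
actual pedigree of any breed. Passing tests therefore demonstrate the
*procedures* behave correctly under a faithful caricature of founder-effect
data, not that any real cohort would give identical numbers.

## Quality control

Markers failing MAF < 0.05 or call rate < 0.90 are removed first
(assessed on all samples and phenotype classes jointly), then samples with
call rate < 0.90 on the retained markers. Comparisons are strict, so a
marker at exactly the threshold passes. The marker-then-sample order is a
convention choice and is fixed so results are reproducible; with the high
call rates typical of array data the order does not change the outcome.
A filter pass that removes every marker or every sample raises an error
rather than returning an empty matrix.

## Association scan

Per marker, missing genotypes are excluded (complete-case per marker) and
obligate carriers are excluded from the 2×3 table (the phenotype label
alone controls inclusion). Columns — and rows — with zero total are
dropped and the degrees of freedom reduced, rather than applying
continuity corrections; a table left with fewer than two nonzero rows or
columns is reported as degenerate with p = 1. The exact-test path
enumerates all 2×3 tables with the observed margins and sums multivariate
hypergeometric probabilities not exceeding the observed table's
(probability-ordering convention, log-gamma arithmetic, a 1e-9 log-scale
tolerance for ties); enumeration is bounded to table totals ≤ 500, beyond
which the χ² path is recommended. The recessive-pattern flag is true iff
all non-missing cases occupy a single homozygote column that contains no
control.

## Shared-homozygosity mapping

Rules, applied uniformly: heterozygous markers terminate runs; missing
genotypes are tolerated inside a run or region but can neither start nor
end one; sharing across cases requires the identical homozygous allele at
each marker (the shared allele may differ between markers — it follows the
shared haplotype); a control shares a region only when homozygous for the
region's allele at every marker, with any missing genotype disqualifying
that control (a conservative choice, since a control's sharing status
should not be inferred from unobserved genotypes). Regions span at least
`min_markers` (default 3) markers; boundaries are the first and last
qualifying marker positions with no extension into inter-marker gaps, and
all coordinates are 1-based inclusive. Ranking is (cases sharing
descending, controls sharing ascending, length descending), ties broken by
start coordinate.

**Known limitation.** Strict IBS sharing makes the *top-ranked* region
sensitive to isolated hom→het miscalls: a single miscalled genotype in any
case splits the founder region into fragments, all typically shared by
zero controls, and the length tie-break may then rank a fragment that
excludes the causal locus first. Across simulated cohorts at the default
error rate the locus falls in the top-ranked region in roughly 94% of
runs (and in *some* reported zero-control region essentially always).
Model-based autozygosity callers (HMMs with a genotyping-error emission)
are the standard remedy and are deliberately out of scope here.

## Variant calling and concordance

The five discovery rules (unique reads ≥3, first-25-bases support ≥1,
coverage ≥10, mean base quality ≥20, alternative fraction ≥15%) are all
inclusive and evaluated per sample; a site becomes a candidate variant
when any sample passes all five. Genotypes come from the alternative
fraction with a heterozygote band of [0.15, 0.85] (inclusive): below →
hom-ref, inside → het, above → hom-alt. The band is a documented
convention — the discovery rules say nothing about genotype assignment —
and only the site-adequacy rules (coverage, base quality) gate genotyping,
since a confident hom-ref genotype needs no variant support. A case
without a genotype fails concordance outright (with a distinct reason
code) instead of being ignored; a control no-call is treated as
non-homozygous. Only biallelic substitutions are handled.

CDS annotation uses the standard genetic code (codon index
⌈position/3⌉); for stop gains the truncation is
`protein_length − codon_index + 1` residues, with the protein length
inferred from the CDS (terminal stop excluded) when not supplied.

## LD and carrier screening

The default r² estimator runs EM on the two-locus genotype table:
haplotype frequencies initialize at allele-frequency products and iterate
the double-heterozygote phase split until the largest relative change
falls below 1e-8 (cap 1,000 iterations); r² is clamped to [0, 1].
Squared Pearson correlation of genotype codes is retained as a fast
cross-check; the two agree within 0.05 on random-mating panels. Because
phase is genuinely unobserved, the EM estimate differs from direct
counting on the phased truth by sampling noise even at the optimum, so
accuracy is assessed as the mean absolute difference over replicate
panels (≈0.007 at n = 500). Reported percentages and frequencies are
rounded half-up to the printed precision in reports only, never
internally.

## Pipeline and problem sizes

The pipeline runs QC → scan → shared homozygosity (searched only within
±15 Mb of the strongest significant marker, mirroring the practice of
examining the associated region) → pileup calling over the top region →
concordance → LD, and records the package version, seed and all
thresholds in every output header; identical seeds give byte-identical
outputs. Test and acceptance runs use 1,000-marker chromosomes, 20
replicate cohorts for recovery rates, 200 label permutations × 50 markers
for type-I calibration, 80 replicate panels of 500 diploids for LD
accuracy and 1,000 replicate screens of 865 animals — sizes chosen so the
whole suite completes in well under a minute while keeping Monte Carlo
error comfortably inside the asserted tolerances.
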