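# hydromap

Homozygosity mapping and recessive-variant filtering for founder populations.

`hydromap` re-implements, as a tested and reusable pipeline, the classic
strategy for localizing a recessive lethal defect in a closed, inbred
population (the motivating setting is congenital hydrocephalus in a horse
breed with a strong founder effect): SNP-array genotype QC, a genotypic
χ² genome-wide association scan, shared-homozygosity (identical-by-state)
mapping across cases, a rule-based pileup variant caller with a recessive
case/control concordance filter, coding-consequence annotation, pairwise LD
r², and carrier-screen allele-frequency estimation. A synthetic
founder-population generator makes every stage testable without animal data.

It is aimed at quantitative geneticists and veterinary genomics groups who
want the individual stages as library functions (or a small CLI) rather than
a monolithic GWAS suite.

## The statistics at the core

* **Genotypic association.** For each marker a 2×3 case/control ×
  {AA, AB, BB} table is tested with the Pearson statistic
  χ² = Σ (O−E)²/E, df = (r−1)(c−1) after dropping empty columns.
  Genome-wide significance uses the Bonferroni level α/n. Because a fully
  penetrant recessive locus empties cells, an exact test over 2×3 tables
  (multivariate hypergeometric enumeration with fixed margins,
  probability-ordering two-sided p) is provided as the small-sample
  alternative.
* **Shared homozygosity.** In an inbred population, cases are autozygous
  for the segment carrying the causal allele. The mapper reports maximal
  runs of consecutive markers at which every case is homozygous for the
  identical allele, counts controls sharing each run, and ranks regions by
  (cases sharing ↓, controls sharing ↑, length ↓).
* **Caller rules.** A candidate substitution is considered in a sample only
  when supported by ≥3 unique reads, seen ≥1× within the first 25 bases of
  a read, at raw coverage ≥10×, mean supporting base quality ≥20 and
  alternative-allele fraction ≥15% (all comparisons inclusive). A variant
  fits the recessive model iff every case is homozygous-alternative and no
  control is (heterozygous carrier controls are allowed).
* **LD and screening.** r² = D²/(p_A(1−p_A)p_B(1−p_B)) with two-locus
  haplotype frequencies estimated by EM over double-heterozygote phase
  ambiguity; carrier screens give the allele frequency
  (n_het + 2·n_homalt)/(2·n).

See `docs/methods.md` for the model behind the synthetic populations and
all numerical conventions.

## Worked example

Run the whole pipeline on a simulated founder cohort (13 cases, 69
controls, 17 obligate-carrier dams, 1,000 markers at 44 kb spacing, a
recessive lethal allele at marker 501):

```sh
$ hydromap run-all --seed 5 --out-dir demo_out
top region: 1:21912000-22440000
concordant variants: 1
```

`demo_out/summary.tsv` (abridged):

```text
n_markers_in              1000
n_markers_qc              971
bonferroni_threshold      5.14933e-05
n_significant             36
top_marker                SNP00501
top_marker_p              2.57676e-18
top_region                1:21912000-22440000
top_region_controls_sharing  0
n_variants_called         13
n_concordant              1
concordant_variant        1:22044000 C>G
truth_locus_in_top_region True
```

Reading: QC kept 971/1000 markers; the scan's strongest marker (SNP00501,
p ≈ 2.6×10⁻¹⁸, far below the Bonferroni level of 0.05/971) sits at the
simulated disease locus; all 13 cases share one homozygous region
(21.91–22.44 Mb) that no control shares; of the 13 candidate substitutions
called from pileups across that region, exactly one — the simulated causal
variant at 22,044,000 — fits the recessive case/control model. The exit
status is 0 because at least one concordant variant survived.

Individual stages are available as subcommands (`simulate`, `qc`, `gwas`,
`roh`, `call`, `concordance`, `annotate`, `ld`, `screen`), e.g. a carrier
screen of 865 animals with 147 heterozygotes:

```sh
$ hydromap screen --homref 718 --het 147 --homalt 0
carriers        17.0%
allele_frequency        0.085
```

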