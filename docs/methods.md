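# Methods

## Problem and model

`chtrio` implements a genome-wide survey procedure for *compound
heterozygous* (CH) and *homozygous alternate* (HA) variants in parent–child
trio cohorts, under an autosomal-recessive disease model. A CH variant is a
pair of alternate alleles at different loci of the same gene carried on
opposite homologous chromosomes (*in trans*), so that both gene copies are
affected; an HA variant affects both copies at a single locus. Detecting CH
variants requires knowing the parental origin of each allele, i.e. phasing.

The pipeline stages are:

1. **Trio preprocessing** (`chtrio.preprocess`). For each trio: keep exactly
   the sites where the proband carries ≥ 1 alternate allele (parents'
   genotypes at those sites are kept regardless of value); remove duplicated
   or multiallelic positions and non-autosomal records; remove sites where
   both parents' genotypes are fully missing; remove Mendelian-inconsistent
   sites. Steps are applied in this fixed order, are idempotent, and delete
   sites for the trio at hand only. An attrition ledger records the
   per-sample count after each step.
2. **Phasing by transmission** (`chtrio.phasing`). A deterministic,
   pedigree-only phaser: a heterozygous child is phased exactly when the
   parental genotypes force the origin of both alleles; homozygous children
   phase trivially. When child and both parents are all heterozygous the
   site is `unphased_ambiguous`; missing parental data that leave the
   orientation unforced give `unphased_missing`; an untransmissible triplet
   is `mendelian_error` (exactly the error set of the Mendelian classifier).
   This is a conservative replacement for statistical reference-panel
   phasing: it phases fewer sites (no population information is used), and
   every site it does phase is certain under Mendelian transmission.
   Unphased sites are invisible to CH detection, which makes the CH calls a
   deterministic, high-confidence subset of what panel-based phasing would
   allow. A REF/ALT orientation-restoration utility undoes allele swaps
   introduced by external phasing tools (swap back and complement genotype
   codes; idempotent).
3. **Classification** (`chtrio.engine`). A CH call requires five criteria:
   (1) both alleles HIGH impact severity; (2) both alleles CADD ≥ 15;
   (3) neither parent homozygous-alternate at either site (an allele
   tolerated homozygously by a healthy parent is unlikely damaging);
   (4) neither parent carries the same two alternate alleles in trans;
   (5) at least one allele with MAF ≤ 5% (gnomAD prioritised over 1000
   Genomes) — one common allele is tolerated, since a damaging common
   allele that is harmless heterozygously may matter opposite a rare
   damaging partner. HA calls require a child 1/1 genotype passing impact /
   CADD / MAF, with neither parent 1/1. For unrelated (control) samples the
   parental criteria are skipped. All comparisons are inclusive exactly as
   stated (CADD ≥ 15, MAF ≤ 0.05).
4. **Background filtering** (`chtrio.background`). Per-gene CH (or HA)
   prevalence in a phased healthy control cohort; disease-cohort calls in
   genes whose prevalence reaches 1% are excluded (strictly-below retains).
   The prevalence denominator defaults to the number of control samples
   carrying ≥ 1 call of that kind anywhere (`calling_samples`), with
   `all_samples` available.
5. **Summaries** (`chtrio.summary`) and **enrichment**
   (`chtrio.enrichment`), described below.

## Numerical and semantic choices

* **Absent annotations.** A missing MAF is treated as frequency 0 (absence
  from population databases implies rarity); a missing CADD score fails the
  deleteriousness criterion (positive evidence is required). The asymmetry
  is deliberate and conservative.
* **Parental trans check (criterion 4).** Parental haplotypes are
  reconstructed from transmission: the transmitted haplotype carries the
  alleles the child inherited at both sites, assuming no recombination
  within a gene. When missing parental alleles block the reconstruction the
  pair is *not* excluded and the call carries a `parent_phase_ambiguous`
  audit flag.
* **Multi-gene sites** participate independently in every annotated gene.
* **Counting** is always over distinct (sample, gene) pairs; multiple calls
  in one gene never double-count.
* **Rounding** is half-up to one decimal for every reported percent and
  mean (this reproduces all published worked-example values; banker's
  rounding does not).
* **Percent increase** (unique-CH tables) is the number of samples (genes)
  with a CH call but no HA call, divided by the filtered HA sample (gene)
  count; undefined when that baseline is zero.
* **Mendelian classification with missing data** enumerates all completions
  of the missing alleles: consistent if all completions are transmissible,
  error if none is, undetermined otherwise. Undetermined sites are kept.
* **Duplicate positions** means same (chrom, pos) regardless of alleles;
  both records are removed, as required by downstream phasing tools.

## Over-representation analysis

Each pathway gene set is tested with the hypergeometric upper tail
P(X ≥ k) for k candidate genes in a pathway of size K, n candidates, and a
universe of N genes (default universe: the union of all pathway genes;
overridable). Only pathways with k ≥ 1 and 2 ≤ K ≤ 500 are tested.
Adjustment across pathways uses Benjamini–Hochberg (via statsmodels);
q-values use Storey's π₀ estimated on the λ grid 0.05…0.95 with a cubic
smoother evaluated at λ = 0.95, falling back to BH for fewer than two
p-values. Pathways are retained when adjusted p ≤ 0.05 **and** q ≤ 0.2.
Exact replication of the R `qvalue` package internals is not attempted;
both measures are always reported side by side.

## Synthetic cohort generator

`chtrio.simulate` generates the study conditions the pipeline assumes:

* genes: non-overlapping 50 kb intervals across autosomes 1–22 (default 80
  genes), with Poisson-distributed site counts (mean 6, minimum 2);
* allele frequencies: Beta(0.2, 2) scaled to (0, 0.5] — a strongly
  rare-shifted site-frequency spectrum;
* annotations: 15% HIGH-impact sites; CADD drawn from a two-component
  normal mixture (40% at mean 25 sd 6, 60% at mean 8 sd 3, clipped at 0) so
  both sides of the threshold 15 are exercised; two population frequencies
  that may disagree (the second scaled by U(0.5, 1.5)); each annotation
  absent with probability 0.05 to exercise absent-value semantics;
* trios (default 30): parental haplotypes drawn per site, children receive
  one whole parental haplotype per gene (no recombination within genes);
  genotyping error 10⁻³ and missingness 2·10⁻³ per genotype; children are
  written unphased — phasing is the pipeline's job;
* controls (default 200): two phased haplotypes per sample, no pedigree;
* planted events with a truth table: trans CH pairs constructed to be
  phaseable (each parent heterozygous at exactly one of the two sites), a
  configurable fraction made deliberately unphaseable (all three members
  heterozygous at both sites — flagged not detectable), cis decoys (both
  ALTs on one transmitted haplotype), and HA events (both parents
  heterozygous donors). Default per-trio planting rates: CH 0.3, cis 0.2,
  HA 0.3, unphaseable fraction 0.15. Each event claims an unused gene.
* an optional background-gene scenario (off by default): one gene receives
  a qualifying trans pair in a chosen fraction of controls plus one genuine
  trio CH event, so the control-prevalence filter has a planted positive.

Planted sites are exempted from the noise model so the truth table's
expected-detectable flag is exact. One global seed drives five independent
sub-streams (gene models, trios, planting, controls, noise); identical
configurations reproduce byte-identical cohorts.

**What the generator does not emulate:** linkage disequilibrium,
recombination, mutation-rate heterogeneity, sequence context, relatedness
among controls, population structure, or realistic gene-length and
annotation correlations. Passing recovery tests therefore demonstrates the
correctness of the classification logic under the stated model, not
calibrated performance on real sequencing data.

## Validation strategy

* The Mendelian classifier and the transmission phaser are checked against
  exhaustive gamete-enumeration oracles over all 27 complete genotype
  triplets and all partially-missing triplets.
* The CH engine is checked against a brute-force reference (enumerate all
  site pairs, test each criterion naively) on 1,000 random trio-genes of
  ≤ 12 sites, and against planted-event truth over 10 seeds (sensitivity
  1.0 on detectable events, zero calls on cis decoys).
* The hypergeometric tail is checked against exhaustive enumeration of all
  urns with N ≤ 12; BH against the textbook step-up formula.
* The summary module reproduces, from the packaged published per-disease
  counts, every cross-disease statistic those counts imply (pooled carrier
  percentages, per-disease means, all 14 percent-increase values, the
  70.7% preprocessing retention).

Problem sizes in the test suite and acceptance script (12–30 trios, 40–220
genes, ≤ 250 controls) were chosen so the full validation runs in seconds
while every code path — including the background filter's positive case —
is exercised.

## Known limitations

* Transmission-only phasing cannot orient triple-heterozygous sites, so CH
  pairs involving such sites are systematically invisible; panel-based
  phasing would recover a superset.
* Control-cohort prevalence with the `calling_samples` denominator is
  unstable when few controls carry calls (small synthetic cohorts); the
  `all_samples` mode is provided for that regime.
* The GDA/VDA association filter and gene-list overlaps consume externally
  provided tables; no lookups are performed.
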