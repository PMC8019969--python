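# chtrio

Genome-wide surveys of **compound-heterozygous (CH)** and
**homozygous-alternate (HA)** variants in parent–child trio cohorts.

Under an autosomal-recessive model, disease can arise when both copies of a
gene are damaged. This happens either at a single locus (an HA genotype,
`1/1`) or — easily missed — through a *compound heterozygote*: two
different damaging alleles in the same gene, one on each homologous
chromosome (*in trans*). Detecting the second pattern requires phasing,
i.e. knowing which parent contributed each allele, which is why CH variants
are routinely overlooked in genome-wide studies. `chtrio` provides a
tested, reusable implementation of the whole survey procedure for trio
cohorts: preprocessing, pedigree-based phasing, classification, healthy-
population background filtering, cohort statistics and pathway
over-representation, plus a synthetic-cohort generator with planted events
for validation.

## The classifier

Given a preprocessed, transmission-phased trio, a CH call is an unordered
pair of sites (a, b) in one gene with the child's ALT alleles on opposite
haplotypes, such that

1. both alleles are annotated **HIGH** impact severity;
2. both alleles have scaled CADD ≥ 15;
3. neither parent is homozygous-alternate at either site;
4. neither parent carries the same two ALT alleles in trans;
5. min(MAF(a), MAF(b)) ≤ 5 % — one common allele is tolerated
   (gnomAD frequency is prioritised over 1000 Genomes).

An HA call is a child `1/1` site passing impact/CADD/MAF where neither
parent is also `1/1`. For unrelated control samples the parental criteria
(3–4) are skipped. Gene-level background filtering then removes disease-
cohort calls in genes where controls carry a CH (or HA) call at ≥ 1 %
prevalence. See `docs/methods.md` for the full model, the phasing rules and
all numerical conventions.

## Worked example

Pooling the published per-disease counts of a seven-cohort pediatric trio
survey (two cancers, five structural birth defects; packaged with the
library) reproduces its cross-disease statistics:

```bash
$ chtrio worked-example
n_diseases	7
mean_genes_ch_initial	10.9
mean_genes_ch_filtered	5.1
mean_genes_ha_initial	45.0
mean_genes_ha_filtered	35.6
mean_percent_samples_ch_initial	9.5
mean_percent_samples_ch_filtered	3.3
mean_percent_samples_ha_initial	22.2
mean_percent_samples_ha_filtered	17.2
pooled_percent_samples_ch_initial	9.0
pooled_percent_samples_ch_filtered	2.6
pooled_percent_samples_ha_initial	23.3
pooled_percent_samples_ha_filtered	16.2
```

Read: after background filtering, 2.6 % of all probands pooled across the
seven cohorts carry a potentially damaging CH variant and 16.2 % an HA
variant; a disease cohort has on average 5.1 genes with a CH variant and
35.6 with an HA variant.

The same survey runs end to end on a synthetic cohort:

```python
from chtrio.simulate import SimulationConfig, simulate_cohort
from chtrio.pipeline import run_survey

sim = simulate_cohort(SimulationConfig(seed=1, background_gene_control_fraction=0.05))
res = run_survey(sim.trio_cohort, sim.pedigree, sim.control_cohort, disease="synthetic")
print(len(res.trio_result.ch_calls), len(res.ch_filtered))
```

which with this seed prints `4 3`: the 30-trio cohort yields 4 CH calls
(every planted detectable event is among them, and no cis decoy is), and
the control-cohort background filter removes the one call in the gene
planted to be CH-common in controls, leaving 3.

The same stages are available as CLI subcommands
(`chtrio simulate-cohort / preprocess / phase / identify-ch / identify-ha /
identify-ch-unrelated / background / filter / summarize / attrition /
enrich / overlap / associations`), exchanging plain VCF and TSV files.

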