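# gemini-loh

Tumors frequently lose one allele at heterozygous loci (loss of
heterozygosity, LOH). When the locus sits in a *pan-essential* gene, the
tumor is left depending on a single allele that normal tissue still
carries in duplicate — so an allele-specific reagent (a CRISPR guide
whose PAM exists only on the retained allele, an allele-selective RNAi
trigger, or an allele-discriminating small molecule) can in principle
kill tumor cells while sparing normal ones. `gemini-loh` is a pipeline
for discovering and prioritizing this class of targets from population
variant catalogs, tumor allelic copy-number segments, and
gene-essentiality screens. It is written for computational cancer
biologists who want to rebuild, stress-test, or extend the target
compendium on their own cohorts, and it ships a synthetic-cohort
generator so the whole pipeline is testable without any external
downloads.

## The analysis

**Common-variant catalog.** Variants are kept when they PASS upstream
filters, fall in one of 14 targetable consequence classes (coding plus
UTR), and have folded minor allele frequency ≥ 0.01. Heterozygosity at a
locus is the Hardy–Weinberg expectation 2*pq* at its MAF.

**LOH calling.** Per-sample allelic copy-number segments (ABSOLUTE-style
integer major/minor alleles) are transformed into per-gene calls by
maximal-overlap assignment. A gene has undergone LOH when its minor
allele count is zero on an autosome; LOH is *copy-loss* when the
gene-level log2 relative copy number is ≤ −0.1 and *copy-neutral*
otherwise.

**Essential genes.** Candidates are nominated at < 10% FDR in any of
three haploid loss-of-function screens (two CRISPR screens consumed as
q-values; a gene-trap screen scored here by an exact one-sided binomial
test of sense-insertion depletion with Benjamini–Hochberg correction),
then filtered on cell-line evidence of tolerated loss, on mean CERES
knockout dependency (genes with mean > −0.4 excluded), rescued when
cell-line data are missing, and purged of Tier-1 tumor suppressors.

**Allele-specific CRISPR.** A variant is an allele-specific PAM site
when one allele completes an NGG or NAG *S. pyogenes* PAM and the other
does not, at some trinucleotide placement on either strand. The guide is
the 20 nt immediately 5′ of the polymorphic PAM on the sensitive allele.

**Prioritization.** Each (variant, essential gene) pair is scored with
the theoretical yearly US patient reach

    Π = κ · χ · λ · 0.5

(κ = 1,735,350 new US cancer cases/year; χ = 2*pq* heterozygosity;
λ = pan-cancer LOH rate of the gene; 0.5 = probability the lost allele
is the right one), an RNAi dependency class (median DEMETER2 ≤ −0.5),
and a 0–7 druggability composite (ligand-bound structure;
druggable/tractable structure; ≥ 90th ligand-druggability percentile;
EC number; variant in/near a surface pocket; charge-altering;
cysteine-introducing).

## Worked example

The two headline per-locus numbers, from the Python API:

```python
>>> from gemini_loh import heterozygosity, patients_per_year
>>> heterozygosity(0.177)          # 2pq at MAF 0.177
0.291342
>>> patients_per_year(1_735_350, heterozygosity(0.177), 0.09)
22751
```

A MAF of 0.177 means ~29% of people are heterozygous at the locus; with
a 9% pan-cancer LOH rate, roughly 22,751 new US patients per year would
be theoretically targetable there.

A complete synthetic run from the shell (YAML config holding paths,
thresholds, and simulation parameters):

```bash
gemini-loh simulate   --config cfg.yaml   # writes VCF/BED/FASTA/TSV/CSV inputs
gemini-loh catalog    --config cfg.yaml
gemini-loh essential  --config cfg.yaml
gemini-loh loh        --config cfg.yaml
gemini-loh crispr     --config cfg.yaml
gemini-loh compendium --config cfg.yaml
gemini-loh report     --config cfg.yaml
```

With 40 genes, two tumor types (30 samples each, planted LOH rates 0.21
and 0.09), seed 7, the `report` step prints:

```json
{
  "copy_neutral_share": 0.30277777777777776,
  "mean_sample_loh_fraction": 0.15,
  "median_patients_per_year": 47333.0,
  "n_target_genes": 7,
  "n_targets": 14,
  "pam_allele_specific_fraction": 0.2857142857142857,
  "per_type_mean_loh_fraction": {
    "LUAD": 0.20833333333333334,
    "PAAD": 0.09166666666666666
  },
  "strong_dependency_fraction": 1.0
}
```

The per-type LOH fractions recover the planted 0.21/0.09 rates, the
copy-neutral share recovers the planted 0.28, and every compendium row
is a common variant in a gene that survived the essentiality cascade.

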