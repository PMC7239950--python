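# Methods

## Model and procedure

The pipeline identifies allele-specific cancer targets: common germline
variants in pan-essential genes whose heterozygosity is lost in tumors.
Its stages are independent filters and joins, each with an explicit
contract:

1. **Catalog.** A variant survives iff it PASSes upstream quality
   filters, its consequence class is one of the 14 targetable classes,
   and its folded minor allele frequency (MAF) is ≥ `maf_min`
   (inclusive). Folding (AF > 0.5 → 1 − AF) happens at read time, so
   all downstream math sees MAF; heterozygosity is the Hardy–Weinberg
   expectation 2pq, which assumes random mating and no inbreeding at
   the locus — an approximation to observed genotype frequencies.
2. **LOH.** A gene-level call inherits the overlapping segment with
   maximal overlap (ties to the leftmost segment start). LOH means
   minor allele copy number 0 on an autosome; sex chromosomes are
   carried through with class `none` (hemizygosity in males makes
   allelic calls there unreliable), so gene counts still reconcile.
   Copy-loss vs copy-neutral is split at gene-level log2 relative
   copy number ≤ −0.1, the boundary belonging to copy-loss. Genes with
   no overlapping segment get no call and are excluded from every
   denominator rather than counted as non-LOH, which avoids deflating
   rates on sparse cohorts.
3. **Essentiality cascade.** Nomination requires q < 0.10 (strict) in
   at least one of three screens. The gene-trap screen is scored by the
   exact lower-tail binomial P(X ≤ sense | n, 0.5) — a one-sided
   sense-depletion test, since only sense insertions disrupt the gene —
   with Benjamini–Hochberg correction across tested genes (genes with
   zero insertions are not tested). Cell-line exclusion criteria are
   evaluated with strict counts (> 2 homozygous-deletion lines, > 5
   low-expression lines, or ≥ 1 line with both conditions in the *same*
   line). The CERES filter excludes genes whose mean score over
   non-missing cell lines is > −0.4 (a mean of exactly −0.4 is
   retained); genes with no CERES data cannot demonstrate dependency
   and are excluded unless rescued. The rescue rule applies only to
   genes lacking cell-line copy-number/expression data and requires
   ≥ 2 screens passed plus mean CERES < −0.4. Tier-1 tumor suppressors
   and genes without tumor copy-number characterization are removed
   last.
4. **Allele-specific PAM.** For SNVs, every trinucleotide placement
   (position × strand) overlapping the variant base is compared between
   the two allele sequences; the variant is allele-specific iff some
   placement is a PAM (NGG or NAG) in exactly one allele and all
   discriminating placements favour the same allele. Because NAG counts
   as a PAM, NGG↔NAG substitutions are not allele-specific, and
   N-position substitutions never are. Variants where each allele gains
   a PAM at a *different* placement are reported not-specific but
   logged, since a single placement may still discriminate. For indels
   the allele sequences differ in length, so the comparison is
   presence/absence of any PAM overlapping the edited interval ± 2 nt.
   The guide is the 20 nt immediately 5′ of the PAM on the sensitive
   allele; the default 61-nt variant-anchored window guarantees the
   protospacer fits on either strand.
5. **Compendium.** One row per (common variant, final-essential gene)
   pair. LOH rates annotate rows — a gene never observed with LOH gets
   rate 0 — but never filter them. The patient estimate
   Π = round(κ·χ·λ·0.5) is recomputed from each row's own stored χ and
   λ, never cached.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `maf_min` | 0.01 | common-variant MAF threshold (inclusive) |
| `fdr` | 0.10 | per-screen nomination threshold (strict) |
| `ceres_cut` | −0.4 | mean CERES above this excludes a gene |
| `demeter2_cut` | −0.5 | median DEMETER2 at/below this is a strong dependency |
| `log2_loss_cut` | −0.1 | copy-loss/copy-neutral boundary (≤ is loss) |
| `kappa` | 1,735,350 | new US cancer cases per year |
| motifs | NGG, NAG | S. pyogenes PAM set |

All are configurable through the YAML pipeline config and are defaults
of the corresponding functions; none is hard-coded in stage logic.

## Design choices

- **Per-gene transformation rule.** How segments become gene calls is
  underdetermined (overlap, midpoint, containment are all defensible);
  we use maximal overlap with a deterministic leftmost tie-break as the
  least surprising rule, and cover the tie explicitly in tests.
- **Histidine is counted positively charged** in the charge-change
  criterion (conventional physiological-pH classification); this makes
  proline→histidine a charge-altering substitution.
- **Dependency boundary.** Median DEMETER2 of exactly −0.5 is classified
  strong (≤, inclusive).
- **Enrichment test.** The strong-dependency enrichment is an exact
  one-sided binomial test of the subset proportion against the
  background proportion taken as fixed; with background n two orders of
  magnitude larger than the subset, the error from treating it as known
  is negligible.
- **Multi-allelic sites** are treated as independent ref/alt records.
- **Cysteine criterion** is an XOR: exactly one allele carries a
  cysteine at the affected residues, so deletions removing a cysteine
  also qualify (one allele has it, the other does not).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not the biology of real genomes. Genes are laid out non-overlapping on
22 synthetic autosomes; each gene gets one covering segment per sample
plus neutral flanking segments (split-segment and tie cases are covered
by dedicated fixtures instead). Per tumor type, gene-level LOH is
Bernoulli with the planted rate; LOH events are copy-neutral
(major 2, log2 > −0.1) with the planted share, else copy-loss (major 1,
log2 ≤ −0.1). Variant MAFs are uniform on [`maf_low`, `maf_high`] with
configurable sub-threshold and non-PASS decoys; each variant's 61-nt
context is constructed so its allele-specific-PAM status matches a
planted Bernoulli(`pam_overlap_fraction`) flag, by rejection sampling
for SNVs and by a PAM-free A/T background (PAM carried by the edited
bases) for planted-specific indels. Gene-trap counts are
Binomial(n, p_sense) with p_sense = 0.5 for null genes — the equal-
probability null of the orientation test — and p_sense = 0.5·e^(−1.5·effect)
for planted essentials; CRISPR screen q-values are Uniform(0,1) for
nulls and Beta(1, 1 + 50·effect) for essentials (reducing to the null
at effect 0); CERES and DEMETER2 scores are Normal(−effect, 0.15/0.2).
Configurable null-gene subsets trigger each cell-line exclusion rule,
and a missing-data subset exercises the rescue path.

Defaults are the validation study conditions: 4 tumor types × 500
samples with planted LOH rates {0.45, 0.21, 0.09, 0.01} spanning the
observed per-type range, copy-neutral share 0.28, PAM-overlap fraction
0.23, 1000 genes with 100 planted essential at effect 0.8, and 25 cell
lines per screen matrix (a scaled-down panel; the analysis only
consumes means and medians across lines, which are well estimated at
this width). LOH parameter-recovery checks run on 25 genes — per-type
rate estimates then average 500 × 25 Bernoulli draws, so the 3-s.e.
bound computed at n = 500 is conservative.

What passing these tests shows: the estimators are unbiased for the
generative model and every filter boundary behaves as specified. What
they do not show: robustness to features of real data the generator
omits — linkage between variants, segment boundaries that split genes,
purity/ploidy miscalibration upstream of the integer allelic calls,
MAF spectra that are not uniform, and correlated screen noise.

## Numerical notes

- Exact binomial tails via `scipy.stats.binom` / `binomtest`; BH via
  `statsmodels` `multipletests`, verified against a brute-force step-up
  on m ≤ 20 instances.
- The Yates-corrected χ² clamps |O − E| − 0.5 at 0, so a table equal to
  its expecteds scores exactly 0.
- Welch (unequal-variance) one-sided t-tests are used for the MAF and
  LOH-rate comparisons; degenerate zero-variance inputs raise rather
  than returning NaN.
- Π is rounded half-away-from-zero to the nearest integer for
  reporting.
- All generators derive independent substreams from one seed
  (`numpy` `default_rng([seed, stream])`); the full pipeline is
  byte-deterministic under a fixed seed.

## Limitations

- Consequence classes are taken from the input annotation; the package
  does not predict them from sequence.
- Observed-genotype heterozygosity (as opposed to 2pq) is not computed;
  population-level deviations from Hardy–Weinberg are invisible here.
- Guide design covers S. pyogenes NGG/NAG only; no off-target or
  efficacy scoring.
- The druggability composite consumes annotation tables (canSAR-style
  plus manual pocket scores); the package does not re-derive structural
  druggability.
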