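# Methods

This note documents the models and procedures implemented in `chicap`, the
parameters that matter, and the choices made where the design was open.

## Problem setting

A childhood cancer predisposition (ChiCaP) syndrome is a germline condition
that raises a child's cancer risk. Given paired germline and tumor
sequencing plus a standardized phenotype form, the pipeline answers, per
child: (i) is there a reportable germline finding, (ii) does the tumor
corroborate it (second hit, mutational burden, mutational signature), and
(iii) what does that imply for the family (sibling surveillance); and, per
cohort: prevalence, diagnostic yield, and the association between clinical
criteria and molecular diagnoses.

## Germline reporting gate

Variant pathogenicity (ACMG-style P/LP/VUS/LB/B labels) is an *input*; the
package implements only the downstream reporting logic:

* a variant must fall in a panel gene (single-interval footprint, 1-based
  inclusive coordinates; containment is `start <= pos <= end`);
* only P/LP variants are candidates;
* the genotype must fit the gene's inheritance model. AD genes report any
  qualifying genotype. AR genes report homozygotes and compound-heterozygous
  pairs in which both alleles are P/LP; a lone heterozygote is suppressed
  unless the gene is also an autosomal dominant, highly penetrant,
  adult-onset predisposition gene (the `adult_onset_dominant_exception`
  flag, e.g. PMS2, ATM, BRCA2 in the demo panel). XL genes report
  hemizygous males; heterozygous females are reported with an explicit
  `carrier_or_affected=ambiguous` annotation.

Unphased compound-heterozygous pairs are assumed in trans when both alleles
are P/LP, following clinical convention; the decision carries an
`assumed_in_trans` note rather than silently asserting phase.

**Mosaicism.** A heterozygous call with blood allele fraction below
`mosaic_af_threshold` is flagged as possibly mosaic. No published numeric
rule exists for this; the default 0.30 reflects the lower edge of the
expected binomial scatter of a constitutional heterozygote at ~30-40x
genome coverage, and is configurable.

**Parental origin.** De novo requires confirmed absence in both parents;
a single unavailable parent yields `unknown`. If both parents carry a
variant the child has on one allele, origin cannot be resolved without
phasing; `maternal` is returned as a documented tie-break with a warning.

## Somatic integration

**High-confidence filter.** A somatic call passes when tumor depth > 10,
normal depth > 10, tumor alt-allele depth > 3, and tumor allele fraction
> 0.05 — all strict inequalities. The per-sample depth threshold is applied
to tumor and normal alike.

**TMB.** High-confidence somatic SNV count (INDELs excluded) divided by the
genome size in Mb. The default denominator is the full hg19 assembly length,
3,095.69 Mb; a non-N effective length can be configured instead. TMB is in
mutations/Mb, and hypermutation is TMB strictly greater than 10/Mb.

**Second-hit classification** for a germline finding in a tumor-suppressor
gene, in priority order:

1. `inconclusive` when the genome-wide somatic call set has fewer than
   `min_informative_somatic_calls` entries (default 1, i.e. an empty call
   set) — a tumor sample that produced no somatic calls is more likely
   non-representative than truly hit-free;
2. `second_mutation` when a passing somatic SNV/INDEL falls in the gene's
   footprint (no pathogenicity filter on the somatic hit; an optional
   consequence filter is deliberately out of scope);
3. `structural_variant` when an SV disrupts the gene or a copy-number loss
   segment overlaps it;
4. `cn_loh` when the germline allele's tumor VAF strictly exceeds 0.70 with
   no non-neutral copy-number segment over the gene, or when a copy-neutral
   segment with |BAF - 0.5| > 0.2 covers it;
5. `none` otherwise.

The priority (sequence evidence > structural > allelic imbalance) reflects
directness of evidence when several channels co-occur, and is configurable.
The 0.2 BAF deviation defining a CN-LOH segment is a configuration default:
a pure-tumor CN-LOH segment has BAF near 0 or 1, and 0.2 tolerates
substantial normal-cell admixture while staying away from noise around 0.5.

## Signature refitting

Somatic SNVs are binned into the canonical 96 trinucleotide channels
(pyrimidine-strand convention; purine-reference records are
reverse-complemented). Refitting solves min ‖c − S·w‖₂ subject to w ≥ 0 by
NNLS against a reference signature matrix, then prunes backward: at each
step the retained signature whose removal (followed by refit) costs the
least reconstruction cosine similarity is dropped if that cost is below
`pruning_tolerance` (default 0.01), ties broken by signature name. This
deterministic heuristic approximates the sparse-assignment behavior of the
standard COSMIC refitting tools, whose internals are not published in
sufficient detail to clone; proportions are the final weights normalized
over survivors.

Etiology flags sum retained proportions over fixed signature groups — MMR
deficiency {SBS6, SBS14, SBS15, SBS20, SBS21, SBS26, SBS44}, POLE
proofreading {SBS10a, SBS10b, SBS28}, UV {SBS7a–d} — and flag the etiology
at ≥ 0.10 aggregate proportion (inclusive; configurable).

**Concordance.** A germline finding is corroborated (`concordant`) by a
genetic second hit, or by hypermutation together with the etiology flag
matching the germline gene's pathway (MMR gene ↔ MMRd, POLE ↔ POLE, NER
gene ↔ UV). With an inconclusive second-hit analysis and no signature data
the call is `not_evaluable`; otherwise `discordant`.

## Criteria form and cohort statistics

Four criteria (family history, multiple primaries, ≥1 non-cancer feature,
predisposition-associated malignancy type) are scored per child. A section
not completed scores `missing` and leaves the evaluable denominator — this
reproduces the varying per-criterion denominators seen in real cohort
tables. The malignancy-type criterion derives from the diagnosis and is
never missing. The malignancy list and feature vocabulary are
configuration; the shipped defaults contain the tumor types most strongly
associated with predisposition (retinoblastoma, high-grade astrocytoma,
Wilms/renal tumors, SHH medulloblastoma, pleuropulmonary blastoma,
adrenocortical carcinoma).

Confidence intervals for proportions are exact Clopper–Pearson, computed
from Beta quantiles (lower = Beta(x, n−x+1) at α/2, 0 when x = 0; upper =
Beta(x+1, n−x) at 1−α/2, 1 when x = n); a Wilson interval is available
behind a flag. Displayed percentages use round-half-up to the whole
percent. Unadjusted odds ratios use the 2×2 cross-product with a Woolf
logit interval and the Haldane–Anscombe 0.5 correction applied to all
cells only when some cell is zero. Adjusted odds ratios come from a
maximum-likelihood logistic fit (statsmodels GLM/binomial, IRLS, tolerance
1e-8, ≤100 iterations) of diagnosis on a binary exposure plus age, sex,
and tumor group (two-level factor). Separation is detected from diverging
coefficients or exploding standard errors and reported as a flagged result
with a (0, ∞) interval rather than an exception.

## Sibling-risk rule

For highly heritable embryonal tumors (retinoblastoma as prototype): a
germline-positive proband routes the family to genetic counselling and
cascade testing; a germline-negative proband whose tumor carries two
distinct somatic inactivating events, confirmed absent in blood, leaves
siblings at population risk and out of surveillance (13 examinations under
anesthesia avoided per sibling over four years — informational constant);
anything less keeps surveillance. CN-LOH counts as the second hit only in
the presence of a first somatic hit: for a germline-negative patient a lone
CN-LOH duplicates nothing pathogenic and does not satisfy "two somatic
hits".

## Synthetic-data generator

The generator emulates the study conditions, not real genomes:

* **Cohort**: 309 children; criterion marginals 22% family history, 3.4%
  multiple primaries, 30% with ≥1 non-cancer feature (of whom ~30% have
  two), 42% predisposition-associated malignancy; per-criterion missingness
  matching the observed denominators (290, 291, 293 of 309). Disease status
  follows a logistic link in the fulfilled-criterion indicators with
  configurable true odds ratios (defaults 2.5, 9.2, 3.9, 3.8); the
  intercept is calibrated by root-finding on the realized covariates so
  expected prevalence equals the 11.3% target. Ground truth (including the
  calibrated intercept) is returned for parameter-recovery tests.
* **Paired tumors**: each patient gets a heterozygous germline P variant in
  an AD tumor-suppressor panel gene plus somatic data engineered to a
  requested second-hit scenario — e.g. CN-LOH draws the germline allele's
  tumor VAF from a normal(0.85, 0.04) truncated to (0.70, 1] with a
  copy-neutral, BAF-deviated segment over the gene; `inconclusive` emits an
  empty somatic call set. Background somatic noise (default 40 passing
  SNVs) lives on chromosomes free of demo-panel genes. The scenario mix
  default is 8:4:2:3:2 (second mutation : CN-LOH : structural : inconclusive
  : none) over 19 patients.
* **Catalogs**: multinomial draws over S·w for a mixture w, with synthetic
  SNV records whose contexts realize the catalog; mutation-count profiles
  default to 3,000 (normal) and 50,000 (hypermutated, TMB ≈ 16/Mb).
* **Signatures**: the bundled reference set is *synthetic* — sparse peaked
  Dirichlet columns carrying familiar names (SBS1, SBS5, SBS6, SBS44,
  SBS10a, SBS28, SBS7a) so etiology grouping is exercised without
  redistributing the real COSMIC matrix. Any real reference matrix can be
  supplied as a TSV in the same layout.

What the generator does **not** emulate: read-level noise, tumor purity and
subclonality, haplotype structure, indel/doublet signatures, exome-vs-
genome channel composition, and realistic per-gene mutation spectra.
Passing tests therefore demonstrate the correctness of the decision rules
and estimators under their stated assumptions, not robustness to the messy
failure modes of real sequencing data.

## Numerical choices and problem sizes

All threshold comparisons that gate clinical categories are strict where
so defined (high-confidence filter, TMB > 10, tumor VAF > 0.70, mosaic
AF < 0.30) and inclusive for the etiology proportion (≥ 0.10). NNLS is
exact for the 96×k systems used (k ≤ 10); cosine similarity on the
reconstruction is the pruning metric. Test and acceptance workloads are
sized for interactive runs: signature parameter-recovery uses 20
replicates at 50,000 mutations; interval coverage uses 1,000 binomial
replicates at n = 300; logistic-recovery cohorts use n = 2,000. Empirical
claims in this note (interval roundings, recovery tolerances, the 14/19,
19/21, 7/9 summaries) are exactly the quantities the test suite and
`scripts/acceptance.py` compute.

## Known limitations

* Single-interval gene footprints: no exon model, so deep-intronic
  positions inside the footprint count as "affecting" the gene.
* Somatic in-gene hits are not pathogenicity-classified; a passenger SNV in
  the gene counts as a second mutation.
* The pruning heuristic can differ from the reference assignment tools on
  catalogs near decision boundaries; `pruning_tolerance` trades sparsity
  against fidelity.
* The sibling-risk rule is qualitative; residual-risk probabilities
  (gonadal mosaicism rates, detection sensitivity) are not modeled.
* No liftover: panel coordinates and variant calls must share a build.
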