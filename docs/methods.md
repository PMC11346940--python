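# Methods

## Scope and model

`adcscout` implements an in-silico discovery pipeline for antibody-drug
conjugate (ADC) development with three arms:

1. **Target arm** — a nine-stage filter cascade that reduces a gene universe
   to tumor-selective, surface-exposed target antigens.
2. **Mutation arm** — a screen for somatic mutations whose carriers show
   shifted expression of the prioritized targets within tumor cohorts.
3. **Payload arm** — a funnel over NCI-60 GI50 data that isolates highly
   potent, indication-selective cytotoxic compounds.

A final join produces target–indication–payload combinations annotated with
mutation context.

## Quasi H-score

The central summary statistic is the quasi H-score, a 0–300 proxy for
protein abundance built from the distribution of categorical staining levels
across patients:

    H = 1·(% low) + 2·(% medium) + 3·(% high)

It is 0 when no patient shows detectable staining and 300 when every patient
stains high. On the IHC side the percentages come directly from pathology
patient fractions. On the mRNA side, samples of a tumor cohort are binned by
the gene's own within-cohort quartiles (three-level scheme below) and the
same weights are applied. A gene–indication pair is *selective* when H
strictly exceeds the threshold (default 150).

A structural property worth knowing: under the three-level quartile scheme
at most 25% of samples can fall strictly below Q1, so the mRNA-derived score
is bounded below by ~175 and can never fail a 150 threshold on its own. In
practice the dual (IHC + mRNA) gate therefore removes genes that are absent
from the tumor expression matrix or whose IHC score fails, which is also the
failure mode our synthetic decoy family for that stage uses.

## Quartile categorization

Expression values are binned against their own quartiles, computed with
linear interpolation between order statistics (the common sample-quantile
default; chosen for ubiquity and determinism):

* **four-level** (normal-tissue mRNA vs IHC comparison): 0 → not detected,
  (0, Q1] → low, (Q1, Q3] → medium, > Q3 → high.
* **three-level** (tumor cohorts, hematopoietic data): < Q1 → low,
  [Q1, Q3] → medium, > Q3 → high.

Boundary ties: a value exactly at Q3 is medium in both schemes; a value
exactly at Q1 is low in the four-level scheme and medium in the three-level
scheme (whose low bin is strictly below Q1). Categorization is invariant
under positive rescaling and monotone in the value.

Quartile scopes differ by stage on purpose: stage 6a bins each gene across
its ~44 normal tissues; stage 6b bins each gene within each tumor cohort;
the HSC/MPP filter uses global quartiles over the *entire* hematopoietic
matrix (all genes × all samples) and categorizes the mean of a gene's
HSC/MPP-sample values against them.

## Cascade stages and their parameters

| stage | rule | default |
|---|---|---|
| membrane | keep predicted membrane-protein genes | annotation flag |
| protein evidence | keep genes with protein-level evidence | annotation flag |
| critical normal | drop genes stained high in any critical tissue, any cell type | 13 tissues: lung, oral mucosa, esophagus, stomach, duodenum, small intestine, colon, rectum, liver, kidney, heart muscle, skin, bone marrow |
| tumor quasi H | keep genes with H > threshold in ≥ 1 tumor type | 150, strict |
| surfaceome | intersect with in-silico surfaceome | annotation flag |
| 6a consistency | per-tissue mRNA category vs IHC category | within-one ordinal level |
| 6b dual score | some tumor type with H > threshold in both IHC and mRNA | 150, strict |
| HSC/MPP | drop genes with high hematopoietic stem/progenitor expression | global quartiles |
| evidence | drop genes meeting none of five criteria (literature, antibody, protein family, preclinical, clinical) | score = count of criteria, 0–5 |

Design choices made where the design was genuinely open:

* **"Aligned" in 6a** is not a quantitative definition; we implement both an
  `exact` policy and the default `within_one` policy (ordinal distance ≤ 1
  per overlapping tissue). Exact four-bin equality across ~44 tissues is
  brittle to binning noise, so within-one is the default; tissues present in
  only one data source are ignored, and a gene with no overlapping tissue
  fails.
* **Critical-tissue "high"** is evaluated per cell type (any high record
  disqualifies), not as a tissue-level consensus.
* **Missing IHC** for a gene × cancer falls back to the mRNA-derived score,
  both at the tumor quasi H stage and inside the dual gate.
* Genes lacking membrane annotation are removed outright, but intracellular
  annotations on isoforms do not exclude a gene that also carries a membrane
  annotation (the annotation flag is already the disjunction).

## Mutation screen

Within each tumor cohort, samples are split into carriers of a mutation in
the query gene versus wild type (samples without a call count as wild type
unless a covered-sample list is supplied, in which case uncovered samples
are excluded from both groups — mutation coverage is not universal and the
behavior must be explicit). The test is a two-sided Wilcoxon rank-sum:
exact enumeration of the permutation null (mid-ranks, so ties are handled)
for combined n ≤ 20, and the tie- and continuity-corrected normal
approximation otherwise. The effect estimator is

    log2FC = log2((mean_mut + 1) / (mean_wt + 1))

on the TPM scale — means rather than medians so continuous fold values are
attainable, with a pseudocount of 1 guarding zero means. Groups smaller than
3 are flagged untestable and excluded rather than raising.

The screening gate retains triples with p < 0.05, |log2FC| ≥ 1 and mutated
prevalence ≥ 5%, all configurable. The fold-change gate is applied to the
absolute value, since down-regulated hits are biologically meaningful and
retained. No multiple-testing correction is applied by default (raw p
against alpha); a Benjamini–Hochberg option is available.

## Payload mining

GI50 potencies are on the log10 molar scale. Replicates per (compound, cell
line) are averaged on the log scale (geometric-mean potency). Duplicate
compound names — trimmed and casefolded — are merged under the smallest NSC
id before anything else.

Two sensitivity classes are defined by inclusive ceilings: picomolar
(GI50 ≤ 1 nM, i.e. log ≤ −9) and low nanomolar (1 nM < GI50 ≤ 10 nM). A
compound *enters* a class iff at least one of its aggregated lines falls in
that class's band; the *response percentage* of a panel within a class
counts lines at or below the class ceiling, so a line killed at picomolar
dose also counts as responsive at 10 nM. This membership-by-band rule is
what keeps the three final groups (picomolar-only / low-nanomolar-only /
overlap) a genuine partition: a purely picomolar compound has no band line
in (1, 10] nM and never enters the low-nanomolar branch.

A compound qualifies when ≥ 50% of a panel's measured lines respond in at
least one of the nine panels (with the standard two-line prostate panel, a
single responsive line reaches the 50% bar, which is why the threshold is
inclusive). Failed-screen compounds are removed *after* the response screen,
matching the funnel order. Panels with no measured line are missing, not 0%.

Per-group response profiles (9-dimensional percentage vectors; missing
panels imputed as 0 for distances only) are clustered by agglomerative
Ward/Euclidean clustering, cut at k = 5 (picomolar-only) or 10 (the other
two groups); rows are pre-sorted by compound id so the partition is
input-order invariant, and groups smaller than k are cut at their size. The
picomolar-only group is clustered on the ≤ 1 nM window and the other two on
the ≤ 10 nM window, the scales their heat maps are read at.

## Combination matching

Clinically characterized payloads (Dxd, exatecan mesylate, maytansine,
monomethyl auristatin E, maytansine deriv, eribulin mesylate, by normalized
name match) contribute the panels where 100% of their measured lines respond
at ≤ 10 nM. Panels map to tumor-type codes through a shipped, overridable
table (renal→KIRC, breast→BRCA, ovarian→OV, prostate→PRAD, colon→COAD,
melanoma→SKCM, CNS→GBM+LGG, NSCLC→LUAD+LUSC, leukemia→LAML); one-to-many
mappings are allowed. The output is exactly the relational join of
target-indications, payload panels and the mapping, with all screened
associations for the (target, tumor type) attached as JSON context.

## Synthetic data: what it emulates and what it does not

The generator produces all eight input table kinds with planted structure:

* **Target arm.** Background genes get Dirichlet-distributed patient
  fractions ((2, 2, 1.5, 1) over not-detected/low/medium/high), log-normal
  (meanlog 1, sdlog 1) abundances with ~10% injected zeros, and random
  annotation flags. *Ideal* targets are constructed to survive every stage:
  membrane/evidence/surfaceome flags set, the 13 smallest of their 44 tissue
  values assigned to the critical tissues (so no critical-tissue high), IHC
  categories set equal to the mRNA-derived categories (so 6a holds), at
  least one tumor type with frac_high ≥ 55 (score ≥ 165 > 150 by
  construction), hematopoietic stem/progenitor values pinned inside the
  global interquartile band (a third of them below Q1, giving the
  medium/low label split), and ≥ 1 evidence criterion. One decoy family per
  stage flips exactly one of these properties; the dual-score decoys are
  omitted from the tumor matrix (see the bound discussed above).
* **Mutation arm.** Wild-type expression is log-normal with meanlog 4 and
  sdlog 0.5 (TPM-like magnitudes around e⁴ ≈ 55; the moderate spread keeps
  the pseudocount-1 estimator's bias and sampling error of cohort means well
  inside the ±0.3 recovery tolerance at n = 200). Carrier status is
  Bernoulli at the planted fraction and carrier expression is scaled by
  2^log2FC.
* **Payload arm.** Planted compounds receive responsive lines in 50–100% of
  a chosen panel, drawn inside their class band with a ≥ 0.05 log-unit
  margin from every boundary; replicate noise is bounded at ±0.02 so
  aggregation cannot cross a boundary. Inactive lines are N(−6, 1) floored
  at −7.8 — the floor is part of the definition of "inactive" here, since
  an unbounded tail would let background lines leak under the 10 nM cutoff
  and (with the two-line prostate panel) promote background compounds into
  the low-nanomolar group. Named payload compounds get a fully responsive
  panel each. Duplicate-name pairs and failed-screen compounds are injected
  for the dedupe and failure stages.

The generator makes no attempt to match real marginal distributions beyond
these families: no inter-gene correlation, no tissue covariance, no
cell-line-specific sensitivity structure, no mutation co-occurrence. Passing
recovery tests therefore demonstrates that the pipeline's logic is correct
under its stated assumptions — not that the thresholds are optimal for real
atlas or screening data, where binning noise, missingness and batch
structure are far richer.

Default problem sizes — 500 genes × (20 cohorts × 30 samples) for the target
arm, cohorts of 200 samples for the mutation arm, 3 000 compounds × 60 cell
lines for the payload arm — are the package's chosen desk-scale study
conditions; the planted payload group sizes default to the 33/631/65
partition with 93/1 616 failed-screen compounds.

## Numerical choices and degenerate inputs

* Quantiles: `numpy.quantile` linear interpolation throughout.
* Strict inequalities at the quasi H threshold; inclusive GI50 ceilings;
  inclusive ≥ 50% response.
* Exact rank-sum enumeration up to combined n = 20 (C(20,10) ≈ 1.8×10⁵
  assignments); two-sided p counts |W − E[W]| ≥ observed with a 10⁻¹²
  guard; the permutation null is symmetric (rank reversal), so this equals
  the doubled one-tail convention.
* Identical constant groups return log2FC = 0, p = 1, direction None.
* Empty result collections round-trip as header-only tables; an empty gene
  universe yields nine zero-count stages.
* Ward clustering with k equal to the number of profiles returns singleton
  clusters directly; labels are renumbered by first appearance after an id
  sort, making partitions deterministic and order-invariant.

## Known limitations

* The five evidence criteria are consumed as curated inputs; no literature
  mining is attempted. Gene symbols are matched case-sensitively with no
  cross-nomenclature mapping.
* Copy-number and fusion effects are outside the mutation screen; mutation
  classes (missense vs truncating) are not stratified.
* No chemical-structure or physicochemical payload modeling; the
  failed-screen flag is consumed as given.
* Figure-grade graphics are out of scope; the pipeline exports the matrices
  (quasi H tables, response profiles, cluster labels) such figures are
  drawn from.
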