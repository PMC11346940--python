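# adcscout

Tumor-selective target, payload and target–indication–payload discovery for
antibody-drug conjugates (ADCs), as a tested, reusable pipeline.

ADC development needs (1) a surface antigen that is abundant on tumor cells
but scarce on healthy tissue and (2) a cytotoxic payload potent in the
indications where the antigen is expressed. `adcscout` operationalizes both
searches over standard public-data dialects — normal-tissue IHC annotations
and per-cancer pathology patient fractions (Human Protein Atlas style),
cohort-labelled tumor expression matrices (Xena/TCGA style), somatic
mutation calls (MC3 style), hematopoietic expression profiles, surfaceome /
membrane / protein-evidence gene annotations, and NCI-60 GI50 records — and
joins the two arms into candidate combinations. A synthetic-data module
generates all input kinds with planted ground truth, so every stage is
testable without any downloads.

## The statistics at the core

**Quasi H-score.** Protein abundance per (gene, tumor type) is summarized
from the distribution of categorical staining levels over patients:

    H = 1·(% low) + 2·(% medium) + 3·(% high),   H ∈ [0, 300]

A gene is a candidate when H > 150 in at least one tumor type. An mRNA
analogue bins each cohort's samples by their own quartiles (below Q1 → low,
within [Q1, Q3] → medium, above Q3 → high) and applies the same weights.

**Target cascade.** Nine ordered filters: membrane annotation → protein-
level evidence → no high staining in 13 critical normal tissues → tumor
quasi H > 150 → surfaceome membership → normal-tissue mRNA/IHC category
consistency → quasi H > 150 in both IHC and tumor mRNA → not high on
hematopoietic stem/progenitor cells → at least one of five evidence
criteria (literature, antibody, protein family, preclinical, clinical; the
count, 0–5, ranks the survivors). Every run emits a per-stage trace with
one drop reason per removed gene.

**Mutation screen.** Per (target, mutated query gene, cohort): two-sided
Wilcoxon rank-sum on carrier vs wild-type expression (exact permutation
null for small groups), effect size `log2((mean_mut+1)/(mean_wt+1))`, gated
at p < 0.05, |log2FC| ≥ 1 and carrier prevalence ≥ 5%.

**Payload mining.** After name dedupe and replicate aggregation, compounds
are classed as picomolar (GI50 ≤ 1 nM) or low nanomolar (1–10 nM] by where
their per-line potencies fall, kept when ≥ 50% of some NCI-60 panel's lines
respond, stripped of failed screens, partitioned into picomolar-only /
low-nanomolar-only / overlap, and clustered (Ward) on their 9-panel
response profiles.

See `docs/methods.md` for the full model description, parameter defaults
and design decisions.

## Worked example

Run the whole pipeline on the default synthetic bundle (500 genes with 10
planted ideal targets and 45 stage-specific decoys; 3 000 compounds with a
planted 33/631/65 sensitivity partition):

```bash
adcscout run-all --seed 7 --out demo
```

prints

```
{"n_associations": 4, "n_combinations": 28, "n_prioritized_targets": 12,
 "n_target_indications": 83,
 "payload_group_sizes": {"low_nanomolar_only": 631, "overlap": 65, "picomolar_only": 33}}
```

Reading this: the cascade kept 12 genes — the 10 planted ideal targets plus
2 background genes that happen to satisfy every filter — holding 83
(gene, tumor type) pairs with quasi H-score > 150; the mutation screen
recovered all 4 planted carrier-expression associations; the payload funnel
reproduced the planted 33/631/65 partition exactly; and joining target
indications with the 100%-response panels of the six clinically tested
payloads yielded 28 combination records. `demo/` contains the per-stage
traces with drop reasons, the quasi H matrices, response profiles, cluster
labels, the combination table, and a deterministic run manifest; for
example:

```
target  tumor_type  nci60_panel                 payload            target_score  mutation_context
G00000  LUAD        Non-Small Cell Lung Cancer  exatecan mesylate  170.809325    []
```

Library use mirrors the CLI:

```python
from adcscout import generate_target_inputs, run_cascade, CascadeConfig

bundle = generate_target_inputs(500, seed=7)
result = run_cascade(
    bundle.annotations, bundle.normal_ihc, bundle.pathology,
    bundle.tumor, bundle.normal_mrna, bundle.hema,
    CascadeConfig(hsc_mpp_samples=bundle.hsc_mpp_samples),
)
print(result.trace.counts)       # nine (stage, survivor-count) pairs
print(result.prioritized)        # final target list
```

Real data drops in through the `inputs:` section of the YAML config (see
`adcscout run-all --help`); the file dialects are documented in
`src/adcscout/io.py`.

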