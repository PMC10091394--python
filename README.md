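# gdtec

Multi-omics fusion for cancer subtyping based on the driving relationship
between genome and transcriptome. Somatic mutations, copy-number calls and
tumor-vs-normal expression changes are discretized per gene per patient and
fused into a single binary **GDTEC** (genome-driven transcriptome
expression) matrix; patients are then stratified by resampling consensus
clustering of that matrix, and the resulting subtypes feed Cox
proportional-hazards risk models and random-forest subtype classifiers.

Intended for computational-biology groups working with TCGA-style cohorts:
a MAF (or long TSV) of mutation calls, a GISTIC-style thresholded
copy-number matrix, normalized expression matrices for tumor and normal
samples, and a clinical table with overall survival.

## The method

For gene *g* and patient *s*, with log2 fold change
LFC(g,s) = log2((T(g,s)+p) / (mean_j N(g,j)+p)) against the normal
reference:

- **post-RNAseq**: R = +1 if LFC ≥ 1, −1 if LFC ≤ −1, else 0
  (the band (−1, 1) is normal expression).
- **post-CNV**: C = sign of the copy-number call.
- **post-SNV**: S = 1 if the patient carries a non-silent mutation in *g*.

Two consistency matrices mark expression changes that are plausibly driven
by each genomic mechanism:

- CNV-RNAseq: 1 iff C + R ∈ {−2, +2} (concordant sign),
- SNV-RNAseq: 1 iff S = 1 and |R| = 1 (mutation co-occurring with any
  expression change),

and their fusion is the XOR — a cell claimed by **both** mechanisms is set
back to 0, simultaneous driving being treated as too rare to be signal:

    GDTEC(g,s) = CNV-RNA(g,s) ⊕ SNV-RNA(g,s)

Genes that are 0 in more than 60% of patients are removed. Consensus
clustering (PAM on a Jaccard distance, 0.8 subsampling) of the filtered
matrix yields the subtypes; the number of clusters is the inflection of the
delta-area curve of the consensus CDFs. Subtype-specific genes (GDTEC-rich
in one subtype, poor elsewhere) become features for Cox risk scoring with a
median split, two-gene event-count grouping, and Mix_Sub-vs-rest random
forests with Gini-importance feature selection.

A bundled generator produces aligned synthetic cohorts with planted
subtypes, driven-gene blocks and survival effects, so the whole pipeline is
testable without external downloads.

## Worked example

```python
from gdtec import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(simulate=True, outdir="demo_run", seed=11))
for stage in manifest["stages"]:
    print(stage["name"], stage["status"])
```

The run simulates a default cohort (200 patients, 80 genes, 4 planted
subtypes), builds the three discretized layers and the GDTEC matrix, and
clusters, models and classifies it. With seed 11 the stage summaries
report:

```
fuse      n_retained_genes = 70      # of 80 genes pass the 60% filter
cluster   chosen_k = 4, ari_vs_truth = 1.0
survival  logrank_pvalue = 0.0010    # survival separates the 4 subtypes
          risk_logrank_pvalue = 3.0e-06  # high vs low Cox risk groups
classify  gdtec_auc = 1.0, expression_auc = 0.994
```

i.e. the pipeline recovers the planted number of subtypes exactly (adjusted
Rand index 1.0 against the planted labels), the subtypes carry the planted
survival differences, and the GDTEC features separate the worst-survival
subtype from the rest.

The same run is available from the shell:

```sh
gdtec simulate --seed 11 -o cohort/
gdtec run --config run.yaml            # or compose stages:
gdtec preprocess --snv cohort/mutations.maf --cnv cohort/cnv_calls.tsv \
  --expr-tumor cohort/expr_tumor.tsv --expr-normal cohort/expr_normal.tsv -o prep/
gdtec fuse --post-snv prep/post_snv.tsv --post-cnv prep/post_cnv.tsv \
  --post-rnaseq prep/post_rnaseq.tsv -o gdtec.tsv
gdtec cluster --gdtec gdtec.tsv --method pam --distance binary --seed 17 -o run/
```

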