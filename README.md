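# immureg

Inference of transcription-factor (TF) regulation of immune-related (IR)
genes in tumor cohorts, at two complementary resolutions:

* **Single-sample framework** — for one patient with matched RNA-seq and
  ATAC-seq: link each IR gene to the accessibility peak within ±20 kb of its
  TSS whose signal best tracks the gene's expression (Spearman, p < 0.01),
  derive candidate TFs from motif hits in the peak sequence, test whether
  peak signal, TF expression and IR-gene expression deviate from the normal
  reference in that patient, and call signed regulation: open chromatin with
  an over-expressed TF implies activation (`+`) when the target is high and
  repression (`-`) when it is low. Calls are verified and weighted by a
  STRING-style TF–gene interaction-score table.

* **Population framework** — per tumor subtype, best-subset (L0-penalized)
  regression of each IR gene on its candidate TFs:

      argmin_beta  (1/2n)‖y − X·beta‖² + γ·‖beta‖₀

  solved by coordinate descent plus local combinatorial search, γ chosen by
  cross-validation. The refit R² per target is the *TF regulatory value*
  (the variance fraction of the gene attributable to its selected TFs), and
  the per-cluster Spearman correlation between expression and gene-level
  copy number quantifies CNV influence.

Around these sit NMF consensus clustering with cophenetic-coefficient rank
selection (to discover immune subtypes), per-cluster differential expression
with the stimulatory/inhibitory signature-gene filter, and a Lasso-Cox
prognostic model whose fitted coefficients ζ define the linear risk score
`Risk Score = Σ ζ_i · Exp_i`, evaluated by median stratification,
Kaplan–Meier curves, the log-rank test and time-dependent AUC.

The package is aimed at computational biologists analyzing tumor
multi-omics cohorts (expression + ATAC + CNV + survival) who want
regulatory calls they can trace to explicit statistical decisions, plus a
fully synthetic, ground-truthed cohort generator to validate every stage
without any external download. See `docs/methods.md` for the models,
defaults and limitations.

## Worked example

Generate the default synthetic cohort (200 tumors in 4 planted subtypes,
30 normals, 240 genes/TFs, 20 ATAC samples, 500 peaks), rediscover the
subtypes, and infer the cluster-level network:

```python
from immureg import (generate_cohort, select_rank, shift_nonnegative,
                     infer_cluster_network, analyze_sample, PipelineConfig)
from immureg.immucycreg import (link_peaks_to_gene, select_best_peak,
                                tf_candidates_for_sequence)

cohort = generate_cohort(seed=1)
tumors = cohort.expr.samples_in_cohort("tumor")

# subtype discovery
X = shift_nonnegative(cohort.expr.values[tumors].to_numpy())
rank, profiles = select_rank(X, range(2, 7), n_runs=20, base_seed=101,
                             max_iter=300)
print("selected rank:", rank)
print({r: round(profiles[r].cophenetic, 3) for r in profiles})

# candidate TFs per IR gene: motif hits in the best-linked peak,
# verified by the interaction-score table
pools = {}
for gene in sorted(cohort.gene_lists.ir_genes):
    ann = cohort.annotation[gene]
    link = select_best_peak(ann, cohort.expr.values.loc[gene, tumors],
                            cohort.peaks, link_peaks_to_gene(ann, cohort.peaks))
    if link is None:
        continue
    tfs = tf_candidates_for_sequence(cohort.pwms,
                                     cohort.peak_sequences[link.peak_id])
    pools[gene] = sorted(t for t in tfs if (t, gene) in cohort.scores)

edges, fits = infer_cluster_network(cohort.expr, sorted(pools), pools, seed=1)
fit = fits[0]
print(fit.target, fit.cluster_id, fit.support,
      {k: round(v, 3) for k, v in fit.beta.items()},
      "R2=%.3f" % fit.r_squared)
```

prints

```
selected rank: 4
{2: 0.938, 3: 0.937, 4: 0.977, 5: 0.941, 6: 0.947}
G001 1 ['TF02', 'TF03'] {'TF02': 1.737, 'TF03': 1.153} R2=0.950
```

The cophenetic profile peaks at rank 4 — the planted number of subtypes —
and declines beyond it. For gene `G001` in cluster 1 the selected support is
exactly its two planted regulators with positive standardized coefficients,
and the TF regulatory value 0.95 says 95% of the gene's within-cluster
expression variance is explained by those TFs.

A single-sample network for one ATAC-matched patient:

```python
edges = analyze_sample("T151", cohort.expr, sorted(cohort.gene_lists.ir_genes),
                       cohort.annotation, cohort.peaks, cohort.pwms,
                       cohort.peak_sequences, cohort.scores,
                       config=PipelineConfig())
for e in edges[:3]:
    print(e.tf_name, "->", e.target, e.sign, round(e.weight, 3),
          "p=%.2e" % e.p_value)
```

prints

```
TF04 -> G002 + 0.448 p=1.88e-06
TF04 -> G008 + 0.294 p=4.44e-04
TF04 -> G019 + 0.366 p=4.94e-05
```

Patient `T151` belongs to the subtype in which activator `TF04` is
over-expressed: its target genes deviate upward from the normal reference
(the p-values shown), their peaks are accessible, and the emitted `+` edges
carry the interaction score of each pair as weight — all of them planted
edges of the ground-truth network.

The same stages are reachable from the shell via the `immureg` console
script (`simulate`, `cluster`, `de`, `immucyc`, `l0net`, `prognosis`);
`immureg simulate --seed 1 --out fixtures/` writes every input format plus
a `truth.json` for external benchmarking.

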