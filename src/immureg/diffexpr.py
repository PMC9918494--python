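"""Per-cluster differential expression and the signature-gene inclusion rule.

Inputs are already-normalized continuous expression values, so tumor-cluster
vs normal comparisons use a Welch two-sample t-test on log2(x + eps) rather
than a count-based negative-binomial model; fold changes are
log2((mean_cluster + eps) / (mean_normal + eps)). Significance flags use the
raw p-value threshold together with the fold-change cut-off; BH-adjusted
p-values are reported alongside.

The signature filter keeps a stimulatory gene iff it is significantly highly
expressed in NO cluster, and an inhibitory gene iff it is significantly
highly expressed in at least one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneListSet

logger = logging.getLogger("immureg")


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    cluster: int
    log2fc: float
    p_value: float
    adj_p: float
    significant_high: bool
    significant_low: bool


def differential_expression(
    expr: ExpressionMatrix,
    labels: Mapping[str, int] | None = None,
    genes: Sequence[str] | None = None,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    eps: float = 1.0,
) -> list[DEResult]:
    """Welch t-test of every (gene, cluster) against the normal cohort.

    Zero variance in both groups gives p = 1 by convention (logged).
    """
    if labels is None:
        labels = expr.cluster_labels()
    if not labels:
        raise ValueError("no cluster labels available")
    normals = expr.samples_in_cohort("normal")
    if len(normals) < 2:
        raise ValueError("need >= 2 normal samples")
    gene_list = list(genes) if genes is not None else list(expr.gene_ids)
    missing = set(gene_list) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"genes absent from the matrix: {sorted(missing)[:5]}")
    ref = expr.values.loc[gene_list, normals].to_numpy(dtype=float)
    log_ref = np.log2(ref + eps)

    out: list[DEResult] = []
    for cluster in sorted(set(labels.values())):
        samples = [s for s, c in labels.items() if c == cluster]
        if len(samples) < 2:
            raise ValueError(f"cluster {cluster} has fewer than 2 samples")
        grp = expr.values.loc[gene_list, samples].to_numpy(dtype=float)
        log_grp = np.log2(grp + eps)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(log_grp, log_ref, axis=1, equal_var=False)
        flat = ~np.isfinite(pvals)
        if flat.any():
            logger.warning(
                "%d gene(s) with zero variance in both groups (cluster %d); p set to 1",
                int(flat.sum()), cluster,
            )
            pvals = np.where(flat, 1.0, pvals)
        log2fc = np.log2((grp.mean(axis=1) + eps) / (ref.mean(axis=1) + eps))
        adj = multipletests(pvals, method="fdr_bh")[1]
        for g, fc, p, ap in zip(gene_list, log2fc, pvals, adj):
            out.append(
                DEResult(
                    gene_id=g,
                    cluster=cluster,
                    log2fc=float(fc),
                    p_value=float(p),
                    adj_p=float(ap),
                    significant_high=bool(p < alpha and fc > fc_min),
                    significant_low=bool(p < alpha and fc < -fc_min),
                )
            )
    return out


def select_signature_genes(
    de: Iterable[DEResult], classes: GeneListSet
) -> set[str]:
    """Apply the stimulatory/inhibitory inclusion rule.

    stimulatory: included iff significant_high in NO cluster.
    inhibitory:  included iff significant_high in >= 1 cluster.
    Genes without a class are excluded with a warning.
    """
    high_anywhere: dict[str, bool] = {}
    for r in de:
        high_anywhere[r.gene_id] = high_anywhere.get(r.gene_id, False) or r.significant_high
    selected: set[str] = set()
    unknown = []
    for gene, high in high_anywhere.items():
        cls = classes.regulator_class.get(gene)
        if cls is None:
            unknown.append(gene)
        elif cls == "stimulatory" and not high:
            selected.add(gene)
        elif cls == "inhibitory" and high:
            selected.add(gene)
    if unknown:
        logger.warning("%d gene(s) without a stimulatory/inhibitory class excluded",
                       len(unknown))
    return selected
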