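"""Synthetic multi-omics cohort with planted ground truth.

The generator emulates the statistical structure the two regulatory
frameworks assume, at roughly one tenth of a real tumor cohort's scale:

* a signed TF -> target network: activator TFs are mean-shifted (+4 sd) in
  exactly one tumor subtype each, so their targets deviate from the normal
  reference in that subtype; repressor TFs stay at baseline;
* 4 tumor subtypes defined by mean shifts (+3 sd) on disjoint gene blocks
  (the structure NMF consensus clustering should recover);
* gene-level CNV with a dosage effect (0.5 x copy number) on a dedicated
  gene subset, against unit biological noise - the regime where the
  expression-CNV Spearman correlation lands around 0.3-0.5;
* ATAC peaks near each regulated gene's TSS whose signal tracks the target's
  expression (plus in-window and scattered decoy peaks with independent
  signal), peak sequences carrying the bound TFs' consensus motifs, and an
  interaction-score table covering every planted pair plus random decoys;
* exponential survival times whose hazard follows a linear score of two
  planted prognostic features, with independent uniform censoring
  (roughly 40%).

Everything is reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .immucycreg import PWM
from .io_formats import (
    CNVMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    GeneListSet,
    InteractionScoreTable,
    PeakSet,
    SurvivalTable,
    write_expression,
    write_jaspar_pfms,
)

_BASES = np.array(list("ACGT"))

TF_SHIFT = 4.0  # sd units; activator TFs in their assigned subtype
BLOCK_SHIFT = 3.0  # sd units; subtype-defining gene blocks
CNV_DOSAGE = 0.5
PEAK_LENGTH = 300
MOTIF_LENGTH = 10


@dataclass
class PlantedTruth:
    """Ground truth the pipeline is later scored against."""

    network: set[tuple[str, str, str, float]]  # (tf, target, sign, effect)
    cluster_means: dict[int, dict[str, float]]
    regulatory_peaks: dict[str, str]
    cnv_effects: dict[str, float]
    prognostic_features: dict[str, float]
    seed: int

    def edge_set(self) -> set[tuple[str, str, str]]:
        return {(tf, g, s) for tf, g, s, _ in self.network}


@dataclass
class SyntheticCohort:
    expr: ExpressionMatrix
    peaks: PeakSet
    cnv: CNVMatrix
    survival: SurvivalTable
    annotation: dict[str, GeneAnnotation]
    scores: InteractionScoreTable
    pwms: list[PWM]
    peak_sequences: dict[str, str]
    gene_lists: GeneListSet
    validation_sets: dict[str, set[tuple[str, str]]]
    truth: PlantedTruth


def generate_cohort(
    n_tumor: int = 200,
    n_normal: int = 30,
    n_genes: int = 200,
    n_tfs: int = 40,
    n_clusters: int = 4,
    n_atac: int = 20,
    n_peaks: int = 500,
    snr: float = 10.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate the full cohort; defaults are the study conditions."""
    if n_tumor < 4 * n_clusters:
        raise ValueError("need n_tumor >= 4 * n_clusters")
    if n_atac < 8 or n_atac > n_tumor:
        raise ValueError("need 8 <= n_atac <= n_tumor")
    if n_genes < 60 or n_tfs < 12:
        raise ValueError("need n_genes >= 60 and n_tfs >= 12")
    rng = np.random.default_rng(seed)

    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    tfs = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    tumors = [f"T{i + 1:03d}" for i in range(n_tumor)]
    normals = [f"N{i + 1:03d}" for i in range(n_normal)]

    # ---- roles -----------------------------------------------------------
    n_ir = min(40, n_genes // 4)  # planted network targets (the IR genes)
    ir_genes = genes[:n_ir]
    n_cnv = min(40, n_genes // 4)
    cnv_genes = genes[n_ir:n_ir + n_cnv]
    block_start = max(n_ir + n_cnv + 20, n_genes - 25 * n_clusters)
    block_genes = genes[block_start:]
    blocks = np.array_split(np.array(block_genes), n_clusters)

    # one activator per subtype: each tumor subtype over-expresses exactly one
    # activator TF, so its regulatory program aligns with the subtype structure
    n_act = n_clusters
    activators = tfs[:n_act]
    repressors = tfs[n_act:n_act + 4]
    tf_cluster = {tf: 1 + i % n_clusters for i, tf in enumerate(activators)}

    # ---- planted network -------------------------------------------------
    network: set[tuple[str, str, str, float]] = set()
    regulators: dict[str, list[tuple[str, float]]] = {}
    for g in ir_genes:
        regs: list[tuple[str, float]] = []
        act = activators[rng.integers(len(activators))]
        regs.append((act, float(rng.uniform(0.8, 1.5))))
        if rng.random() < 0.4:
            if rng.random() < 0.5:
                rep = repressors[rng.integers(len(repressors))]
                regs.append((rep, -float(rng.uniform(0.8, 1.5))))
            else:
                other = activators[rng.integers(len(activators))]
                if other != act:
                    regs.append((other, float(rng.uniform(0.8, 1.5))))
        regulators[g] = regs
        for tf, eff in regs:
            network.add((tf, g, "+" if eff > 0 else "-", eff))

    # cluster mean shifts: subtype blocks plus the activator TFs
    cluster_means: dict[int, dict[str, float]] = {c: {} for c in range(1, n_clusters + 1)}
    for c, block in enumerate(blocks, start=1):
        for g in block:
            cluster_means[c][g] = BLOCK_SHIFT
    for tf, c in tf_cluster.items():
        cluster_means[c][tf] = TF_SHIFT

    # ---- expression ------------------------------------------------------
    cluster_of = {s: 1 + i * n_clusters // n_tumor for i, s in enumerate(tumors)}
    baseline = {name: float(rng.normal(8.0, 1.0)) for name in genes + tfs}
    # tumor purity: bulk profiles are tumor/stroma mixtures, so every
    # tumor-intrinsic mean shift is attenuated by a per-sample factor
    purity = {s: float(rng.uniform(0.5, 1.0)) for s in tumors}
    # a minority of samples carry graded mixed-subtype signal (intratumor
    # heterogeneity): their expression blends a second subtype's profile
    mix_with: dict[str, tuple[int, float]] = {}
    for s in tumors:
        if rng.random() < 0.15:
            other = 1 + int(rng.integers(n_clusters))
            if other != cluster_of[s]:
                mix_with[s] = (other, float(rng.uniform(0.25, 0.5)))

    # TF deviations from baseline: standard normal, plus the subtype shift
    z_tf_tumor = rng.standard_normal((n_tfs, n_tumor))
    z_tf_normal = rng.standard_normal((n_tfs, n_normal))
    tf_idx = {tf: i for i, tf in enumerate(tfs)}
    # per-sample cluster weights: own subtype plus any admixed second subtype
    cluster_weight: dict[str, dict[int, float]] = {}
    for s in tumors:
        if s in mix_with:
            other, w = mix_with[s]
            cluster_weight[s] = {cluster_of[s]: 1.0 - w, other: w}
        else:
            cluster_weight[s] = {cluster_of[s]: 1.0}

    shift_tf = np.zeros((n_tfs, n_tumor))
    for tf, c in tf_cluster.items():
        for j, s in enumerate(tumors):
            w = cluster_weight[s].get(c, 0.0)
            if w:
                shift_tf[tf_idx[tf], j] = TF_SHIFT * purity[s] * w
    z_tf_tumor_shifted = z_tf_tumor + shift_tf

    # CNV (tumor samples only); dosage genes get unit-variance copy number
    cnv_vals = rng.normal(0.0, 0.3, size=(n_genes, n_tumor))
    cnv_idx = {g: i for i, g in enumerate(genes)}
    for g in cnv_genes:
        cnv_vals[cnv_idx[g]] = rng.standard_normal(n_tumor)

    inv_snr_sd = 0.0 if np.isinf(snr) else 1.0 / np.sqrt(snr)
    tumor = np.zeros((n_genes, n_tumor))
    normal = np.zeros((n_genes, n_normal))
    for gi, g in enumerate(genes):
        regs = regulators.get(g, [])
        signal_t = np.zeros(n_tumor)
        signal_n = np.zeros(n_normal)
        for tf, eff in regs:
            signal_t += eff * z_tf_tumor_shifted[tf_idx[tf]]
            signal_n += eff * z_tf_normal[tf_idx[tf]]
        if regs:  # network target: noise scaled by the signal-to-noise ratio
            sd = float(np.sqrt(sum(e * e for _, e in regs))) * inv_snr_sd
        elif g in cnv_genes:  # dosage against unit biological noise
            signal_t = signal_t + CNV_DOSAGE * cnv_vals[gi]
            sd = 1.0
        else:
            sd = 1.0
        shift = np.array(
            [
                purity[s]
                * sum(w * cluster_means[c].get(g, 0.0)
                      for c, w in cluster_weight[s].items())
                for s in tumors
            ]
        )
        tumor[gi] = baseline[g] + signal_t + shift + rng.normal(0.0, sd, n_tumor)
        normal[gi] = baseline[g] + signal_n + rng.normal(0.0, sd, n_normal)

    tf_tumor = np.array([baseline[tf] for tf in tfs])[:, None] + z_tf_tumor_shifted
    tf_normal = np.array([baseline[tf] for tf in tfs])[:, None] + z_tf_normal

    values = pd.DataFrame(
        np.vstack([np.hstack([tumor, normal]), np.hstack([tf_tumor, tf_normal])]),
        index=genes + tfs,
        columns=tumors + normals,
    )
    meta = pd.DataFrame(
        {
            "cohort": ["tumor"] * n_tumor + ["normal"] * n_normal,
            "cluster": [cluster_of[s] for s in tumors] + [np.nan] * n_normal,
        },
        index=tumors + normals,
    )
    expr = ExpressionMatrix(values=values, sample_meta=meta)

    # ---- annotation and peaks -------------------------------------------
    annotation: dict[str, GeneAnnotation] = {}
    for i, name in enumerate(genes + tfs):
        annotation[name] = GeneAnnotation(
            gene_id=name, chrom="chr1", tss=100_000 + i * 60_000,
            strand="+" if i % 2 == 0 else "-",
        )

    per_cluster = max(n_atac // n_clusters, 1)
    atac_samples: list[str] = []
    for c in range(1, n_clusters + 1):
        members = [s for s in tumors if cluster_of[s] == c]
        atac_samples.extend(members[:per_cluster])
    for s in tumors:  # top up to n_atac
        if len(atac_samples) >= n_atac:
            break
        if s not in atac_samples:
            atac_samples.append(s)
    atac_samples = atac_samples[:n_atac]

    peak_rows = []
    signal_rows = []
    sequences: dict[str, str] = {}
    regulatory_peaks: dict[str, str] = {}
    consensi = {tf: "".join(rng.choice(_BASES, MOTIF_LENGTH)) for tf in tfs}
    atac_cols = [tumors.index(s) for s in atac_samples]
    pid_counter = 0

    def new_pid() -> str:
        nonlocal pid_counter
        pid_counter += 1
        return f"p{pid_counter:04d}"

    def random_seq(length: int) -> str:
        return "".join(rng.choice(_BASES, length))

    for g in ir_genes:
        ann = annotation[g]
        # the regulatory peak: signal tracks the target's expression
        offset = int(rng.integers(-15_000, 14_700))
        pid = new_pid()
        start = max(ann.tss + offset, 0)
        peak_rows.append((pid, "chr1", start, start + PEAK_LENGTH))
        target_sig = tumor[cnv_idx[g], atac_cols]
        noise_sd = float(np.std(target_sig)) * inv_snr_sd
        signal_rows.append((pid, target_sig + rng.normal(0.0, noise_sd, n_atac)))
        seq = list(random_seq(PEAK_LENGTH))
        pos = 20
        for tf, _ in regulators[g]:
            seq[pos:pos + MOTIF_LENGTH] = consensi[tf]
            pos += MOTIF_LENGTH + 10
        sequences[pid] = "".join(seq)
        regulatory_peaks[g] = pid
        # two in-window decoys with independent signal
        for _ in range(2):
            off = int(rng.integers(-19_000, 18_700))
            dpid = new_pid()
            dstart = max(ann.tss + off, 0)
            peak_rows.append((dpid, "chr1", dstart, dstart + PEAK_LENGTH))
            signal_rows.append((dpid, rng.normal(5.0, 1.0, n_atac)))
            sequences[dpid] = random_seq(PEAK_LENGTH)

    genome_end = 100_000 + (n_genes + n_tfs) * 60_000
    while pid_counter < n_peaks:
        pid = new_pid()
        start = int(rng.integers(genome_end, genome_end + 10_000_000))
        peak_rows.append((pid, "chr1", start, start + PEAK_LENGTH))
        signal_rows.append((pid, rng.normal(5.0, 1.0, n_atac)))
        sequences[pid] = random_seq(PEAK_LENGTH)

    intervals = pd.DataFrame(
        [(c, s, e) for _, c, s, e in peak_rows],
        index=[p for p, *_ in peak_rows],
        columns=["chrom", "start", "end"],
    )
    intervals.index.name = "peak_id"
    signal = pd.DataFrame(
        np.vstack([sig for _, sig in signal_rows]),
        index=[p for p, _ in signal_rows],
        columns=atac_samples,
    )
    peaks = PeakSet(intervals=intervals, signal=signal)

    pwms = [
        PWM(
            tf_name=tf,
            matrix=np.array(
                [
                    [21.0 if b == base else 1.0 for base in consensi[tf]]
                    for b in "ACGT"
                ]
            ),
        )
        for tf in tfs
    ]

    # ---- interaction scores ---------------------------------------------
    entries: dict[tuple[str, str], float] = {}
    for tf, g, _, _ in sorted(network):
        entries[(tf, g)] = float(rng.uniform(0.2, 1.0))
    n_decoys = 150
    tries = 0
    while sum(1 for _ in entries) < len(network) + n_decoys and tries < 10_000:
        tries += 1
        pair = (tfs[rng.integers(n_tfs)], genes[rng.integers(n_ir)])
        if pair not in entries:
            entries[pair] = float(rng.uniform(0.15, 0.9))
    scores = InteractionScoreTable(entries=entries)

    # ---- CNV / survival --------------------------------------------------
    cnv = CNVMatrix(values=pd.DataFrame(cnv_vals, index=genes, columns=tumors))

    prognostic = {activators[0]: 1.0, ir_genes[0]: -0.8}
    eta = np.zeros(n_tumor)
    for feat, coef in prognostic.items():
        row = values.loc[feat, tumors].to_numpy(dtype=float)
        eta += coef * (row - row.mean()) / row.std()
    scale_days = 1000.0
    t_true = rng.exponential(scale_days * np.exp(-eta))
    censor = rng.uniform(1.0, 2500.0, n_tumor)
    observed = np.minimum(t_true, censor)
    event = (t_true <= censor).astype(int)
    survival = SurvivalTable(
        data=pd.DataFrame(
            {"time": np.maximum(observed, 1.0), "event": event}, index=tumors
        )
    )

    # ---- gene lists ------------------------------------------------------
    classes = {
        g: ("stimulatory" if i % 2 == 0 else "inhibitory")
        for i, g in enumerate(ir_genes)
    }
    cycle = {g: 1 + i % 7 for i, g in enumerate(ir_genes)}
    gene_lists = GeneListSet(
        ir_genes=set(ir_genes), cycle_step=cycle, regulator_class=classes
    )

    truth = PlantedTruth(
        network=network,
        cluster_means=cluster_means,
        regulatory_peaks=regulatory_peaks,
        cnv_effects={g: CNV_DOSAGE for g in cnv_genes},
        prognostic_features=prognostic,
        seed=seed,
    )
    validation_sets = {"curated_tfdb": {(tf, g) for tf, g, _, _ in network}}
    return SyntheticCohort(
        expr=expr,
        peaks=peaks,
        cnv=cnv,
        survival=survival,
        annotation=annotation,
        scores=scores,
        pwms=pwms,
        peak_sequences=sequences,
        gene_lists=gene_lists,
        validation_sets=validation_sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# serialization for the CLI / file-based workflows


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write every pipeline input format plus a truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expr, out / "expression.tsv")
    cohort.expr.sample_meta.to_csv(out / "sample_meta.tsv", sep="\t")
    iv = cohort.peaks.intervals
    with open(out / "peaks.narrowPeak", "w") as fh:
        for pid, row in iv.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{pid}\t0\t.\t0\t-1\t-1\t-1\n"
            )
    cohort.peaks.signal.to_csv(out / "atac_signal.tsv", sep="\t")
    with open(out / "peak_sequences.fasta", "w") as fh:
        for pid, seq in cohort.peak_sequences.items():
            fh.write(f">{pid}\n{seq}\n")
    write_jaspar_pfms(cohort.pwms, out / "motifs.jaspar")
    cohort.cnv.values.to_csv(out / "cnv.tsv", sep="\t")
    cohort.survival.data.to_csv(out / "survival.tsv", sep="\t")
    with open(out / "interaction_scores.tsv", "w") as fh:
        fh.write("tf\tgene\tscore\n")
        for (tf, g), s in sorted(cohort.scores.entries.items()):
            fh.write(f"{tf}\t{g}\t{s:.6f}\n")
    pd.DataFrame(
        [
            (a.gene_id, a.chrom, a.tss, a.strand)
            for a in cohort.annotation.values()
        ],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(out / "tss.tsv", sep="\t", index=False)
    with open(out / "ir_genes.txt", "w") as fh:
        fh.write("\n".join(sorted(cohort.gene_lists.ir_genes)) + "\n")
    pd.DataFrame(
        sorted(cohort.gene_lists.regulator_class.items()),
        columns=["gene_id", "regulator_class"],
    ).to_csv(out / "classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(cohort.gene_lists.cycle_step.items()), columns=["gene_id", "cycle_step"]
    ).to_csv(out / "cycle_steps.tsv", sep="\t", index=False)
    truth = cohort.truth
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "network": sorted(truth.network),
                "cluster_means": {
                    str(c): dict(sorted(m.items())) for c, m in truth.cluster_means.items()
                },
                "regulatory_peaks": dict(sorted(truth.regulatory_peaks.items())),
                "cnv_effects": dict(sorted(truth.cnv_effects.items())),
                "prognostic_features": truth.prognostic_features,
                "seed": truth.seed,
            },
            fh,
            indent=1,
        )
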