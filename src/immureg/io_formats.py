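"""File formats, domain containers, configuration and logging.

Everything the pipeline reads or writes passes through here: normalized
expression matrices (TSV, genes x samples canonical), narrowPeak intervals
plus a peak-signal matrix, gene-level CNV, clinical survival tables,
STRING-style TF-gene interaction scores, curated gene lists, JASPAR-format
motifs, FASTA peak sequences, and the edge-list / GraphML network output.

Genomic coordinates are 0-based half-open internally, regardless of the
input dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs

logger = logging.getLogger("immureg")


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Tunable thresholds of the regulatory frameworks.

    Attributes
    ----------
    tss_window : int
        Half-width (bp) of the symmetric window around the TSS inside which
        ATAC peaks are considered candidate TF-binding regions.
    peak_corr_p : float
        Significance cut-off for the peak-to-gene Spearman correlation.
    expr_deviation_p : float
        Single-sample expression deviation threshold (tumor vs normal
        reference, one-value t-test).
    peak_deviation_p : float
        Single-sample accessibility deviation threshold; looser than the
        expression one because ATAC cohorts are small.
    motif_score_fraction : float
        A PWM hit must reach this fraction of the motif's maximum log-odds.
    de_alpha, de_fc_min : float
        Differential-expression thresholds (raw p, log2 fold change).
    rank_delta : float
        Tolerance for the cophenetic "starts decreasing" rank rule.
    """

    tss_window: int = 20_000
    peak_corr_p: float = 0.01
    expr_deviation_p: float = 0.001
    peak_deviation_p: float = 0.05
    motif_score_fraction: float = 0.8
    de_alpha: float = 0.05
    de_fc_min: float = 1.0
    rank_delta: float = 0.005

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x samples, with per-sample metadata.

    ``sample_meta`` is indexed by sample id and carries a ``cohort`` column
    ("tumor"/"normal") and an optional ``cluster`` column (integers >= 1,
    NaN where unassigned).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if self.sample_meta is not None:
            missing = self.values.columns.difference(self.sample_meta.index)
            if len(missing):
                raise FormatError(f"samples without metadata: {list(missing)[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_cohort(self, cohort: str) -> list[str]:
        if self.sample_meta is None:
            raise ValueError("no sample metadata attached")
        mask = self.sample_meta["cohort"] == cohort
        return [s for s in self.sample_ids if s in self.sample_meta.index[mask]]

    def cluster_labels(self) -> dict[str, int]:
        """Sample -> cluster for samples that have a cluster assignment."""
        if self.sample_meta is None or "cluster" not in self.sample_meta.columns:
            return {}
        col = self.sample_meta["cluster"].dropna()
        return {s: int(c) for s, c in col.items() if s in self.sample_ids}


@dataclass(frozen=True)
class GeneAnnotation:
    """TSS annotation for one gene (0-based position)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise FormatError(f"{self.gene_id}: negative TSS {self.tss}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class PeakSet:
    """ATAC peaks (0-based half-open intervals) and their signal matrix.

    ``signal`` is peaks x ATAC-samples, indexed by peak id and aligned with
    ``intervals`` row-for-row.
    """

    intervals: pd.DataFrame  # columns: chrom, start, end; index: peak_id
    signal: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intervals.index.duplicated().any():
            dup = self.intervals.index[self.intervals.index.duplicated()][0]
            raise FormatError(f"duplicate peak identifier: {dup!r}")
        bad = self.intervals[self.intervals["start"] >= self.intervals["end"]]
        if len(bad):
            raise FormatError(
                f"peak {bad.index[0]!r}: start {bad['start'].iloc[0]} >= end {bad['end'].iloc[0]}"
            )
        if not self.signal.index.equals(self.intervals.index):
            raise FormatError("signal rows do not match peak intervals")

    @property
    def peak_ids(self) -> pd.Index:
        return self.intervals.index


@dataclass
class InteractionScoreTable:
    """(tf, gene) -> interaction score in [0, 1], STRING-export style."""

    entries: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (tf, gene), score in self.entries.items():
            if not 0.0 <= score <= 1.0:
                raise FormatError(f"interaction score out of [0,1] for ({tf}, {gene}): {score}")

    def get(self, tf: str, gene: str) -> float | None:
        return self.entries.get((tf, gene))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.entries


@dataclass
class GeneListSet:
    """Curated gene lists: IR genes, immune-cycle step, regulator class."""

    ir_genes: set[str]
    cycle_step: dict[str, int] = field(default_factory=dict)
    regulator_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, step in self.cycle_step.items():
            if not 1 <= step <= 7:
                raise FormatError(f"{gene}: immune-cycle step {step} outside 1..7")
        for gene, cls in self.regulator_class.items():
            if cls not in {"stimulatory", "inhibitory"}:
                raise FormatError(f"{gene}: regulator class {cls!r}")


@dataclass
class CNVMatrix:
    """Gene-level copy-number estimates, genes x samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise FormatError("duplicate identifiers in CNV matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise FormatError("non-finite CNV value")


@dataclass
class SurvivalTable:
    """Per-sample overall survival: time (days, > 0) and event (0/1)."""

    data: pd.DataFrame  # columns: time, event; index: sample_id

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample in survival table")
        if (self.data["time"] <= 0).any():
            bad = self.data.index[self.data["time"] <= 0][0]
            raise FormatError(f"non-positive survival time for sample {bad!r}")
        if not self.data["event"].isin([0, 1]).all():
            raise FormatError("survival event must be 0 or 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index


# ---------------------------------------------------------------------------
# readers


def _read_numeric_tsv(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[~df[col].map(lambda v: isinstance(v, (int, float, np.number)))]
            row = bad[0] if len(bad) else "?"
            raise FormatError(f"{what}: non-numeric cell at row {row!r}, column {col!r}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)]
        raise FormatError(f"{what}: missing value in row {rows[0]!r}")
    return df


def read_expression(
    path: str | Path,
    orientation: str = "genes_by_samples",
    sample_meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read a TSV expression matrix into canonical genes x samples form."""
    if orientation not in {"genes_by_samples", "samples_by_genes"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_numeric_tsv(path, "expression")
    if orientation == "samples_by_genes":
        df = df.T
    return ExpressionMatrix(values=df.astype(float), sample_meta=sample_meta)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, cohort, optional cluster column.

    An empty/absent cluster column yields no cluster assignments.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "cohort" not in df.columns:
        raise FormatError("sample metadata needs a 'cohort' column")
    if "cluster" in df.columns:
        df["cluster"] = pd.to_numeric(df["cluster"], errors="coerce")
    return df


_NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def read_narrowpeak(path: str | Path, signal_path: str | Path) -> PeakSet:
    """Read narrowPeak (BED6+4) intervals plus a signal TSV keyed by peak name.

    Peaks absent from the signal file are dropped (count logged).
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 4:
        raise FormatError("narrowPeak needs at least chrom/start/end/name columns")
    raw.columns = _NARROWPEAK_COLS[: raw.shape[1]]
    intervals = raw[["chrom", "start", "end", "name"]].copy()
    intervals["start"] = intervals["start"].astype(int)
    intervals["end"] = intervals["end"].astype(int)
    bad = intervals[intervals["start"] >= intervals["end"]]
    if len(bad):
        raise FormatError(
            f"peak {bad['name'].iloc[0]!r}: start {bad['start'].iloc[0]} >= end {bad['end'].iloc[0]}"
        )
    intervals = intervals.set_index("name")
    intervals.index.name = "peak_id"

    signal = _read_numeric_tsv(signal_path, "peak signal")
    keep = intervals.index.intersection(signal.index)
    dropped = len(intervals) - len(keep)
    if dropped:
        logger.warning("dropping %d peak(s) missing from the signal matrix", dropped)
    intervals = intervals.loc[keep]
    return PeakSet(intervals=intervals, signal=signal.loc[keep].astype(float))


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required <= set(df.columns):
        raise FormatError(f"gene annotation needs columns {sorted(required)}")
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def read_gene_level_cnv(path: str | Path) -> CNVMatrix:
    return CNVMatrix(values=_read_numeric_tsv(path, "CNV").astype(float))


def read_survival(path: str | Path) -> SurvivalTable:
    """Clinical TSV: sample_id, time (or OS_time), event (or OS_event)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.rename(columns={"OS_time": "time", "OS_event": "event"})
    if not {"time", "event"} <= set(df.columns):
        raise FormatError("survival table needs time/event (or OS_time/OS_event) columns")
    return SurvivalTable(data=df[["time", "event"]].astype(float))


def read_interaction_scores(path: str | Path) -> InteractionScoreTable:
    """STRING-style TSV: tf, gene, score (whitespace- or tab-separated)."""
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    if df.shape[1] < 3:
        raise FormatError("interaction score table needs tf/gene/score columns")
    df.columns = ["tf", "gene", "score", *df.columns[3:]]
    entries: dict[tuple[str, str], float] = {}
    for r in df.itertuples():
        key = (str(r.tf), str(r.gene))
        if key in entries:
            raise FormatError(f"duplicate interaction pair {key}")
        entries[key] = float(r.score)
    return InteractionScoreTable(entries=entries)


def read_gene_lists(
    ir_path: str | Path,
    cycle_path: str | Path | None = None,
    class_path: str | Path | None = None,
) -> GeneListSet:
    """IR gene list (one id per line), optional cycle-step and class TSVs."""
    ir = {line.strip() for line in open(ir_path) if line.strip()}
    cycle: dict[str, int] = {}
    if cycle_path is not None:
        df = pd.read_csv(cycle_path, sep="\t")
        cycle = {str(r.iloc[0]): int(r.iloc[1]) for _, r in df.iterrows()}
    classes: dict[str, str] = {}
    if class_path is not None:
        df = pd.read_csv(class_path, sep="\t")
        classes = {str(r.iloc[0]): str(r.iloc[1]) for _, r in df.iterrows()}
    return GeneListSet(ir_genes=ir, cycle_step=cycle, regulator_class=classes)


def read_peak_sequences(path: str | Path) -> dict[str, str]:
    """FASTA of peak sequences, keyed by peak id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_jaspar_pfms(path: str | Path):
    """JASPAR-format PFM file -> list of PWM objects (4 x L counts)."""
    from .immucycreg import PWM  # local import: avoid a module cycle

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(PWM(tf_name=m.name or m.matrix_id, matrix=counts))
    return out


def write_jaspar_pfms(pwms, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf_name}\t{pwm.tf_name}\n")
            for base, row in zip("ACGT", pwm.matrix):
                fh.write(f"{base}  [ " + " ".join(f"{v:6.0f}" for v in row) + " ]\n")


def read_peak_tf_map(path: str | Path) -> dict[str, set[str]]:
    """Precomputed peak -> TF candidates TSV (peak_id, tf columns)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r[1]), set()).add(str(r[2]))
    return out


# ---------------------------------------------------------------------------
# network output

_EDGE_COLUMNS = ["scope", "tf", "target", "sign", "weight", "p_value", "evidence"]


def _edge_records(edges) -> pd.DataFrame:
    rows = []
    for e in edges:
        rows.append(
            {
                "scope": e.scope,
                "tf": e.tf_name,
                "target": e.target,
                "sign": e.sign,
                "weight": e.weight,
                "p_value": e.p_value if e.p_value is not None else np.nan,
                "evidence": ",".join(sorted(e.evidence)) if e.evidence else "",
            }
        )
    df = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    # duplicate (scope, tf, target, sign) keys collapse to the max weight
    df = (
        df.sort_values("weight", ascending=False)
        .drop_duplicates(subset=["scope", "tf", "target", "sign"], keep="first")
        .sort_values(["scope", "target", "tf"], kind="stable")
        .reset_index(drop=True)
    )
    return df


def write_network(edges, path: str | Path, format: str = "tsv_edge_list") -> None:
    """Write regulatory edges as a TSV edge list or GraphML.

    Rows are deterministically ordered by (scope, target, tf); duplicate
    keys are deduplicated keeping the maximum weight.
    """
    if format == "tsv_edge_list":
        _edge_records(edges).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        df = _edge_records(edges)
        g = nx.MultiDiGraph()
        for r in df.itertuples(index=False):
            g.add_edge(
                r.tf, r.target, scope=str(r.scope), sign=r.sign,
                weight=float(r.weight),
                p_value=float(r.p_value) if np.isfinite(r.p_value) else -1.0,
                evidence=r.evidence,
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _EDGE_COLUMNS:
        raise FormatError(f"edge list must have columns {_EDGE_COLUMNS}")
    return df


# ---------------------------------------------------------------------------
# helper: SEG-style overlap-weighted gene-level CNV


def seg_to_gene_cnv(
    segments: pd.DataFrame, annotation: Sequence[GeneAnnotation], span: int = 10_000
) -> CNVMatrix:
    """Overlap-weighted mean of segment values over a +/- span window at each TSS.

    ``segments`` columns: sample, chrom, start, end, value (0-based half-open).
    Provided as a convenience only; gene-level CNV input is the primary path.
    """
    samples = sorted(segments["sample"].unique())
    out = pd.DataFrame(0.0, index=[g.gene_id for g in annotation], columns=samples)
    for gene in annotation:
        lo, hi = max(gene.tss - span, 0), gene.tss + span
        sel = segments[
            (segments["chrom"] == gene.chrom)
            & (segments["start"] < hi)
            & (segments["end"] > lo)
        ]
        for sample in samples:
            sub = sel[sel["sample"] == sample]
            if len(sub) == 0:
                continue
            overlap = np.minimum(sub["end"], hi) - np.maximum(sub["start"], lo)
            out.loc[gene.gene_id, sample] = float(
                np.average(sub["value"], weights=overlap)
            )
    return CNVMatrix(values=out)
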