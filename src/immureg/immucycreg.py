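"""Single-sample TF -> immune-gene regulation calling.

The framework links each immune-related (IR) gene to the ATAC peak near its
TSS that best tracks its expression, derives candidate TFs from motif hits
in the peak sequence, tests whether peak signal, TF expression and IR-gene
expression deviate from the normal reference in one patient, and turns the
pattern of deviations into a signed regulatory call. Open chromatin is a
prerequisite for TF binding, so every call requires a high peak signal:

* peak high, TF high, gene high  ->  positive regulation (+)
* peak high, TF high, gene low   ->  negative regulation (-), a repressor
* anything else                  ->  no call

Edges are verified and weighted by a STRING-style interaction-score table:
candidate (TF, gene) pairs without a score are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GeneAnnotation, InteractionScoreTable, PeakSet

logger = logging.getLogger("immureg")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PeakGeneLink:
    """Best ATAC peak for one gene: distance to TSS, Spearman rho, p."""

    gene_id: str
    peak_id: str
    distance_to_tss: int
    rho: float
    p_value: float


@dataclass
class PWM:
    """Position frequency matrix: 4 x L counts, rows A, C, G, T."""

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError(f"{self.tf_name}: PWM must be 4 x L with L >= 4")
        if (self.matrix < 0).any():
            raise ValueError(f"{self.tf_name}: negative PWM counts")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        """Log2-odds score matrix against a uniform background."""
        counts = self.matrix + self.pseudocount
        probs = counts / counts.sum(axis=0, keepdims=True)
        return np.log2(probs / background)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class DeviationCall:
    """Single-sample deviation of one quantity from its reference cohort."""

    sample_id: str
    gene_id: str
    direction: str  # high | low | normal
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class MotifHit:
    position: int
    strand: str
    score: float


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed TF -> target call, scoped to one sample or one cluster."""

    scope: str
    tf_name: str
    target: str
    sign: str
    weight: float
    p_value: float | None = None
    evidence: frozenset[str] = frozenset()


@dataclass
class SampleCalls:
    """The three deviation-call families one sample's analysis needs."""

    gene_calls: dict[str, DeviationCall]
    tf_calls: dict[str, DeviationCall]
    peak_calls: dict[str, DeviationCall]


# ---------------------------------------------------------------------------
# correlation


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Constant input yields (0.0, 1.0) with a logged warning: an undefined
    correlation is treated as "no evidence".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spearman: constant input vector, returning rho=0")
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# peak -> gene linking


def link_peaks_to_gene(
    gene: GeneAnnotation, peaks: PeakSet, window: int = 20_000
) -> list[str]:
    """Peaks whose interval overlaps [tss - window, tss + window).

    The window is symmetric around the TSS regardless of strand; overlap
    (not containment) is the inclusion rule.
    """
    iv = peaks.intervals
    mask = (
        (iv["chrom"] == gene.chrom)
        & (iv["start"] < gene.tss + window)
        & (iv["end"] > gene.tss - window)
    )
    return list(iv.index[mask])


def peak_tss_distance(gene: GeneAnnotation, start: int, end: int) -> int:
    """Signed edge-to-TSS distance; 0 when the peak spans the TSS."""
    if start > gene.tss:
        return start - gene.tss
    if end <= gene.tss:
        return end - gene.tss
    return 0


def select_best_peak(
    gene: GeneAnnotation,
    gene_expr: Mapping[str, float] | "pd.Series",
    peaks: PeakSet,
    candidate_ids: Sequence[str],
    p_max: float = 0.01,
) -> PeakGeneLink | None:
    """Among candidate peaks, the one whose signal best correlates with the
    gene's expression (highest |rho| with p < p_max, over ATAC-matched
    samples). Ties break by smaller |distance to TSS|, then peak id.
    """
    import pandas as pd

    expr = pd.Series(gene_expr, dtype=float)
    matched = [s for s in peaks.signal.columns if s in expr.index]
    if len(matched) == 0:
        raise ValueError("no ATAC samples matched to expression samples")
    best: tuple[float, int, str, float, float] | None = None
    for pid in candidate_ids:
        rho, p = spearman(
            peaks.signal.loc[pid, matched].to_numpy(), expr[matched].to_numpy()
        )
        if p >= p_max:
            continue
        row = peaks.intervals.loc[pid]
        dist = peak_tss_distance(gene, int(row["start"]), int(row["end"]))
        key = (-abs(rho), abs(dist), pid)
        if best is None or key < best[:3]:
            best = (*key, rho, p)
    if best is None:
        return None
    _, absdist, pid, rho, p = best
    row = peaks.intervals.loc[pid]
    return PeakGeneLink(
        gene_id=gene.gene_id,
        peak_id=pid,
        distance_to_tss=peak_tss_distance(gene, int(row["start"]), int(row["end"])),
        rho=rho,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# motif scanning (replaces web-based TF lookup with local PWM scanning)


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in sequence.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"bad nucleotide {exc.args[0]!r}") from None


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(sequence.upper()))


def scan_motifs(
    pwm: PWM, sequence: str, score_fraction: float = 0.8
) -> list[MotifHit]:
    """Log-odds scan of both strands; N contributes 0 (background) per position.

    A hit is any window scoring >= score_fraction x the motif's maximum
    achievable score. Positions are 0-based on the forward strand.
    """
    L = pwm.length
    if len(sequence) < L:
        return []
    lo = pwm.log_odds()
    max_score = lo.max(axis=0).sum()
    threshold = score_fraction * max_score
    # row 4 = N: zero log-odds contribution
    lo5 = np.vstack([lo, np.zeros(pwm.length)])
    enc = _encode(sequence)
    n_windows = len(enc) - L + 1
    offsets = np.arange(L)
    idx = enc[np.arange(n_windows)[:, None] + offsets]  # windows x L
    fwd = lo5[idx, offsets].sum(axis=1)
    # reverse strand: scan with the reverse-complemented matrix
    lo_rc = lo[::-1, ::-1]
    lo_rc5 = np.vstack([lo_rc, np.zeros(L)])
    rev = lo_rc5[idx, offsets].sum(axis=1)
    hits = [
        MotifHit(int(i), "+", float(s)) for i, s in enumerate(fwd) if s >= threshold
    ] + [
        MotifHit(int(i), "-", float(s)) for i, s in enumerate(rev) if s >= threshold
    ]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def tf_candidates_for_sequence(
    pwms: Iterable[PWM], sequence: str, score_fraction: float = 0.8
) -> set[str]:
    """TFs with at least one motif hit in the sequence."""
    return {
        pwm.tf_name
        for pwm in pwms
        if scan_motifs(pwm, sequence, score_fraction=score_fraction)
    }


# ---------------------------------------------------------------------------
# single-sample deviation test


def single_sample_deviation(
    value: float,
    reference: Sequence[float],
    p_threshold: float = 0.001,
    sample_id: str = "",
    gene_id: str = "",
) -> DeviationCall:
    """One value against a reference cohort, prediction-variance t form.

    statistic = (value - mean) / (sd * sqrt(1 + 1/n)), two-sided p from
    t with n - 1 df. A zero-variance reference degenerates to a strict
    comparison against the constant (p forced to 0 or 1, flagged).
    """
    ref = np.asarray(reference, dtype=float)
    n = len(ref)
    if n < 3:
        raise ValueError("reference cohort needs n >= 3")
    sd = ref.std(ddof=1)
    if sd == 0:
        if value == ref[0]:
            return DeviationCall(sample_id, gene_id, "normal", 0.0, 1.0, degenerate=True)
        direction = "high" if value > ref[0] else "low"
        statistic = np.inf if value > ref[0] else -np.inf
        return DeviationCall(sample_id, gene_id, direction, statistic, 0.0, degenerate=True)
    t = (value - ref.mean()) / (sd * np.sqrt(1.0 + 1.0 / n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    if p < p_threshold:
        direction = "high" if t > 0 else "low"
    else:
        direction = "normal"
    return DeviationCall(sample_id, gene_id, direction, float(t), float(p))


# ---------------------------------------------------------------------------
# sign inference


def infer_regulation_sign(
    peak_call: DeviationCall, tf_call: DeviationCall, gene_call: DeviationCall
) -> str | None:
    """Signed regulation from the (peak, TF, gene) deviation pattern.

    Accessible chromatin (peak high) and an expressed TF are prerequisites;
    the target's direction then decides activation vs repression. All other
    combinations yield no call.
    """
    if peak_call.direction != "high" or tf_call.direction != "high":
        return None
    if gene_call.direction == "high":
        return "+"
    if gene_call.direction == "low":
        return "-"
    return None


# ---------------------------------------------------------------------------
# per-sample network assembly


def build_single_sample_network(
    sample_id: str,
    ir_genes: Iterable[str],
    links: Mapping[str, PeakGeneLink],
    tf_candidates: Mapping[str, Iterable[str]],
    calls: SampleCalls,
    scores: InteractionScoreTable,
    validation_sets: Mapping[str, set[tuple[str, str]]] | None = None,
) -> list[RegulatoryEdge]:
    """Assemble the patient's signed regulatory network.

    For each IR gene with a linked peak, every motif-derived TF candidate
    whose deviation pattern yields a sign becomes an edge -- provided the
    (TF, gene) pair has an interaction score (verification filter). The
    score is the edge weight; named validation sets containing the pair
    become evidence flags.
    """
    validation_sets = validation_sets or {}
    edges: list[RegulatoryEdge] = []
    for gene in ir_genes:
        link = links.get(gene)
        if link is None:
            continue
        gene_call = calls.gene_calls.get(gene)
        peak_call = calls.peak_calls.get(link.peak_id)
        if gene_call is None or peak_call is None:
            continue
        for tf in sorted(set(tf_candidates.get(link.peak_id, ()))):
            tf_call = calls.tf_calls.get(tf)
            if tf_call is None:
                continue
            sign = infer_regulation_sign(peak_call, tf_call, gene_call)
            if sign is None:
                continue
            score = scores.get(tf, gene)
            if score is None:
                continue  # unverified by the interaction database
            evidence = frozenset(
                name for name, pairs in validation_sets.items() if (tf, gene) in pairs
            )
            edges.append(
                RegulatoryEdge(
                    scope=sample_id,
                    tf_name=tf,
                    target=gene,
                    sign=sign,
                    weight=score,
                    p_value=gene_call.p_value,
                    evidence=evidence,
                )
            )
    return edges


# ---------------------------------------------------------------------------
# convenience pipeline for one sample


def analyze_sample(
    sample_id: str,
    expr,  # ExpressionMatrix
    ir_genes: Sequence[str],
    annotation: Mapping[str, GeneAnnotation],
    peaks: PeakSet,
    pwms: Sequence[PWM] | None,
    peak_sequences: Mapping[str, str] | None,
    scores: InteractionScoreTable,
    peak_tf_map: Mapping[str, set[str]] | None = None,
    config=None,
    validation_sets=None,
    _links_cache: dict | None = None,
    _tf_cache: dict | None = None,
) -> list[RegulatoryEdge]:
    """Run the full single-sample framework for one ATAC-matched sample.

    TF candidates come from ``peak_tf_map`` when given, otherwise from
    scanning ``pwms`` against ``peak_sequences``. The sample must be a
    column of both the expression and the peak-signal matrices.
    """
    from .io_formats import PipelineConfig

    cfg = config or PipelineConfig()
    if sample_id not in expr.sample_ids:
        raise ValueError(f"sample {sample_id!r} not in expression matrix")
    if sample_id not in peaks.signal.columns:
        raise ValueError(f"sample {sample_id!r} has no ATAC signal; single-sample "
                         "peak calls need matched ATAC data")
    normals = expr.samples_in_cohort("normal")
    tumors = expr.samples_in_cohort("tumor")

    # peak->gene links (cacheable across samples)
    links: dict[str, PeakGeneLink] = {}
    for gene in ir_genes:
        if _links_cache is not None and gene in _links_cache:
            link = _links_cache[gene]
        else:
            ann = annotation.get(gene)
            if ann is None:
                continue
            cands = link_peaks_to_gene(ann, peaks, window=cfg.tss_window)
            link = (
                select_best_peak(
                    ann, expr.values.loc[gene, tumors], peaks, cands,
                    p_max=cfg.peak_corr_p,
                )
                if cands
                else None
            )
            if _links_cache is not None:
                _links_cache[gene] = link
        if link is not None:
            links[gene] = link

    # TF candidates per linked peak
    tf_candidates: dict[str, set[str]] = {}
    for link in links.values():
        pid = link.peak_id
        if peak_tf_map is not None:
            tf_candidates[pid] = set(peak_tf_map.get(pid, set()))
        elif _tf_cache is not None and pid in _tf_cache:
            tf_candidates[pid] = _tf_cache[pid]
        else:
            if pwms is None or peak_sequences is None:
                raise ValueError("need either peak_tf_map or pwms + peak_sequences")
            tf_candidates[pid] = tf_candidates_for_sequence(
                pwms, peak_sequences[pid], score_fraction=cfg.motif_score_fraction
            )
            if _tf_cache is not None:
                _tf_cache[pid] = tf_candidates[pid]

    # deviation calls
    ref = expr.values[normals]
    gene_calls = {
        g: single_sample_deviation(
            float(expr.values.loc[g, sample_id]), ref.loc[g].to_numpy(),
            p_threshold=cfg.expr_deviation_p, sample_id=sample_id, gene_id=g,
        )
        for g in links
    }
    all_tfs = sorted(set().union(*tf_candidates.values())) if tf_candidates else []
    tf_calls = {
        tf: single_sample_deviation(
            float(expr.values.loc[tf, sample_id]), ref.loc[tf].to_numpy(),
            p_threshold=cfg.expr_deviation_p, sample_id=sample_id, gene_id=tf,
        )
        for tf in all_tfs
        if tf in expr.gene_ids
    }
    other_atac = [s for s in peaks.signal.columns if s != sample_id]
    peak_calls = {
        link.peak_id: single_sample_deviation(
            float(peaks.signal.loc[link.peak_id, sample_id]),
            peaks.signal.loc[link.peak_id, other_atac].to_numpy(),
            p_threshold=cfg.peak_deviation_p, sample_id=sample_id,
            gene_id=link.peak_id,
        )
        for link in links.values()
    }
    calls = SampleCalls(gene_calls=gene_calls, tf_calls=tf_calls, peak_calls=peak_calls)
    return build_single_sample_network(
        sample_id, list(links), links, tf_candidates, calls, scores,
        validation_sets=validation_sets,
    )
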