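import itertools

import numpy as np
import pandas as pd
import pytest

from immureg.immucycreg import (
    DeviationCall,
    PWM,
    SampleCalls,
    build_single_sample_network,
    infer_regulation_sign,
    link_peaks_to_gene,
    reverse_complement,
    scan_motifs,
    select_best_peak,
    single_sample_deviation,
    spearman,
)
from immureg.io_formats import GeneAnnotation, InteractionScoreTable, PeakSet


def _peakset(rows, signal=None, samples=("a1", "a2", "a3", "a4")):
    intervals = pd.DataFrame(
        [(c, s, e) for _, c, s, e in rows],
        index=[r[0] for r in rows], columns=["chrom", "start", "end"],
    )
    intervals.index.name = "peak_id"
    if signal is None:
        signal = np.ones((len(rows), len(samples)))
    sig = pd.DataFrame(signal, index=intervals.index, columns=list(samples))
    return PeakSet(intervals=intervals, signal=sig)


class TestSpearman:
    def test_monotone_and_reversed(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        # ranks of y are (2,1,4,3,5): sum of squared rank differences is 4,
        # so rho = 1 - 6*4 / (5*(25-1)) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_returns_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="immureg"):
            rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert (rho, p) == (0.0, 1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        rho, _ = spearman(x, y)
        rho_t, _ = spearman(np.exp(x), y ** 3)
        assert rho_t == pytest.approx(rho)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])


class TestPeakLinking:
    GENE = GeneAnnotation("g", "chr1", 50_000, "+")

    def test_window_boundary_arithmetic(self):
        peaks = _peakset([
            ("inside", "chr1", 30_000, 30_500),      # ends 19.5 kb upstream
            ("outside", "chr1", 29_000, 29_900),     # entirely beyond 20 kb
            ("straddle", "chr1", 29_500, 30_500),    # overlaps the window edge
            ("other_chrom", "chr2", 50_000, 50_300),
        ])
        assert link_peaks_to_gene(self.GENE, peaks) == ["inside", "straddle"]

    def test_agrees_with_brute_force_interval_scan(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(300):
            start = int(rng.integers(0, 200_000))
            rows.append((f"p{i}", "chr1", start, start + int(rng.integers(50, 2000))))
        peaks = _peakset(rows)
        genes = [GeneAnnotation(f"g{i}", "chr1", int(rng.integers(0, 200_000)), "+")
                 for i in range(20)]
        w = 20_000
        for gene in genes:
            brute = [
                pid for pid, _, s, e in rows
                if s < gene.tss + w and e > gene.tss - w
            ]
            assert link_peaks_to_gene(gene, peaks) == brute


class TestBestPeak:
    GENE = GeneAnnotation("g", "chr1", 50_000, "+")

    def test_highest_correlation_wins(self):
        rng = np.random.default_rng(1)
        samples = [f"a{i}" for i in range(12)]
        expr = pd.Series(rng.normal(size=12), index=samples)
        good = expr.to_numpy() + rng.normal(0, 0.05, 12)
        poor = expr.to_numpy() * 0.3 + rng.normal(0, 1.5, 12)
        peaks = _peakset(
            [("good", "chr1", 49_000, 49_300), ("poor", "chr1", 51_000, 51_300)],
            signal=np.vstack([good, poor]), samples=samples,
        )
        link = select_best_peak(self.GENE, expr, peaks, ["good", "poor"])
        assert link.peak_id == "good"
        assert abs(link.rho) > 0.9

    def test_no_significant_candidate_gives_none(self):
        rng = np.random.default_rng(2)
        samples = [f"a{i}" for i in range(10)]
        expr = pd.Series(rng.normal(size=10), index=samples)
        peaks = _peakset(
            [("noise", "chr1", 49_000, 49_300)],
            signal=rng.normal(size=(1, 10)), samples=samples,
        )
        assert select_best_peak(self.GENE, expr, peaks, ["noise"]) is None

    def test_unmatched_samples_rejected(self):
        expr = pd.Series([1.0, 2.0], index=["x1", "x2"])
        peaks = _peakset([("p", "chr1", 49_000, 49_300)])
        with pytest.raises(ValueError, match="matched"):
            select_best_peak(self.GENE, expr, peaks, ["p"])

    def test_planted_peak_recovered_in_simulations(self):
        """A peak whose signal tracks expression wins over decoys almost always."""
        rng = np.random.default_rng(3)
        samples = [f"a{i}" for i in range(20)]
        hits = 0
        n_sim = 60
        for _ in range(n_sim):
            expr = pd.Series(rng.normal(size=20), index=samples)
            planted = expr.to_numpy() + rng.normal(0, expr.std() / np.sqrt(10), 20)
            decoys = rng.normal(size=(4, 20))
            peaks = _peakset(
                [("real", "chr1", 49_000, 49_300)]
                + [(f"d{i}", "chr1", 40_000 + 2_000 * i, 40_300 + 2_000 * i)
                   for i in range(4)],
                signal=np.vstack([planted, decoys]), samples=samples,
            )
            link = select_best_peak(
                self.GENE, expr, peaks, ["real", "d0", "d1", "d2", "d3"]
            )
            hits += link is not None and link.peak_id == "real"
        assert hits / n_sim >= 0.95


class TestMotifScanning:
    PWM_CONSENSUS = PWM("tf", np.array([
        # consensus ACGTACGTAC
        [20, 0, 0, 0, 20, 0, 0, 0, 20, 0],
        [0, 20, 0, 0, 0, 20, 0, 0, 0, 20],
        [0, 0, 20, 0, 0, 0, 20, 0, 0, 0],
        [0, 0, 0, 20, 0, 0, 0, 20, 0, 0],
    ], dtype=float))

    def test_single_forward_hit_at_planted_offset(self):
        seq = "TT" * 10 + "ACGTACGTAC" + "TT" * 10
        hits = scan_motifs(self.PWM_CONSENSUS, seq, score_fraction=0.95)
        assert [(h.position, h.strand) for h in hits] == [(20, "+")]

    def test_reverse_complement_hit_detected(self):
        site = reverse_complement("ACGTACGTAC")
        seq = "TT" * 10 + site + "TT" * 10
        hits = scan_motifs(self.PWM_CONSENSUS, seq, score_fraction=0.95)
        assert [(h.position, h.strand) for h in hits] == [(20, "-")]

    def test_sequence_shorter_than_motif_gives_no_hits(self):
        assert scan_motifs(self.PWM_CONSENSUS, "ACGTA") == []

    def test_n_bases_score_as_background(self):
        seq = "NN" * 10 + "ACGTACGTAC" + "NN" * 10
        hits = scan_motifs(self.PWM_CONSENSUS, seq, score_fraction=0.95)
        positions = {h.position for h in hits}
        assert 20 in positions
        # all-N windows score exactly 0, far below a stringent threshold
        assert all(h.score > 0 for h in hits)

    def test_hit_rate_matches_enumerated_score_distribution(self):
        """Empirical hit frequency on random sequence agrees with the exact
        per-position hit probability from the PWM score distribution."""
        pwm = self.PWM_CONSENSUS
        lo = pwm.log_odds()
        threshold = 0.95 * lo.max(axis=0).sum()
        # exact distribution: convolve the four equiprobable column scores
        probs = {0.0: 1.0}
        for col in lo.T:
            nxt = {}
            for s, p in probs.items():
                for v in col:
                    key = round(s + v, 9)
                    nxt[key] = nxt.get(key, 0.0) + p * 0.25
            probs = nxt
        p_hit = sum(p for s, p in probs.items() if s >= threshold)
        rng = np.random.default_rng(6)
        n_windows = 0
        n_hits = 0
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), 1_000))
            hits = scan_motifs(pwm, seq, score_fraction=0.95)
            n_windows += 2 * (1_000 - pwm.length + 1)  # both strands
            n_hits += len(hits)
        expected = n_windows * p_hit
        assert abs(n_hits - expected) <= 4 * np.sqrt(max(expected, 1.0))

    def test_agrees_with_biopython_pssm_scores(self):
        """Independent oracle: Biopython's PSSM gives the same forward scores."""
        from Bio.Seq import Seq
        from Bio import motifs as bio_motifs

        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 200))
        pwm = self.PWM_CONSENSUS
        m = bio_motifs.Motif(
            alphabet="ACGT",
            counts={b: list(pwm.matrix[i]) for i, b in enumerate("ACGT")},
        )
        m.pseudocounts = pwm.pseudocount
        ref_scores = m.pssm.calculate(Seq(seq))  # log2-odds, forward strand
        lo5 = np.vstack([pwm.log_odds(), np.zeros(pwm.length)])
        enc = np.array(["ACGTN".index(b) for b in seq])
        offs = np.arange(pwm.length)
        mine = lo5[enc[np.arange(len(seq) - pwm.length + 1)[:, None] + offs], offs].sum(1)
        np.testing.assert_allclose(mine, ref_scores, atol=1e-4)


class TestDeviation:
    def test_value_at_reference_mean_is_normal(self):
        call = single_sample_deviation(5.0, [4.0, 5.0, 6.0, 5.0])
        assert call.direction == "normal"
        assert call.statistic == pytest.approx(0.0)

    def test_extreme_value_called_high(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(10.0, 1.0, 100)
        call = single_sample_deviation(float(ref.mean() + 10 * ref.std(ddof=1)), ref)
        assert call.direction == "high"
        assert call.p_value < 1e-10

    def test_constant_reference_flagged_degenerate(self):
        call = single_sample_deviation(3.0, [3.0, 3.0, 3.0])
        assert call.direction == "normal" and call.degenerate
        call2 = single_sample_deviation(4.0, [3.0, 3.0, 3.0])
        assert call2.direction == "high" and call2.degenerate

    def test_statistic_uses_prediction_variance_inflation(self):
        ref = np.array([0.0, 1.0, 2.0, 3.0])
        call = single_sample_deviation(4.0, ref)
        sd = ref.std(ddof=1)
        expected = (4.0 - 1.5) / (sd * np.sqrt(1.25))
        assert call.statistic == pytest.approx(expected)

    def test_tiny_reference_rejected(self):
        with pytest.raises(ValueError):
            single_sample_deviation(1.0, [1.0, 2.0])


class TestSignInference:
    @staticmethod
    def _call(direction):
        return DeviationCall("s", "x", direction, 0.0, 0.5)

    def test_documented_activation_and_repression_cases(self):
        high = self._call("high")
        low = self._call("low")
        assert infer_regulation_sign(high, high, high) == "+"
        assert infer_regulation_sign(high, high, low) == "-"

    def test_closed_chromatin_precludes_any_call(self):
        high, normal = self._call("high"), self._call("normal")
        assert infer_regulation_sign(normal, high, high) is None

    def test_truth_table_over_all_27_combinations(self):
        expected = {("high", "high", "high"): "+", ("high", "high", "low"): "-"}
        for combo in itertools.product(["high", "low", "normal"], repeat=3):
            sign = infer_regulation_sign(*(self._call(d) for d in combo))
            assert sign == expected.get(combo), combo


class TestNetworkAssembly:
    def _setup(self, gene_dir="low", score=0.474):
        from immureg.immucycreg import PeakGeneLink

        link = PeakGeneLink("HSP90B1", "pk1", -1_000, 0.9, 1e-4)
        calls = SampleCalls(
            gene_calls={"HSP90B1": DeviationCall("s", "HSP90B1", gene_dir, -5.0, 1e-5)},
            tf_calls={"JUN": DeviationCall("s", "JUN", "high", 5.0, 1e-5)},
            peak_calls={"pk1": DeviationCall("s", "pk1", "high", 3.0, 0.01)},
        )
        entries = {} if score is None else {("JUN", "HSP90B1"): score}
        return link, calls, InteractionScoreTable(entries=entries)

    def test_repressor_edge_with_interaction_score_weight(self):
        link, calls, scores = self._setup()
        edges = build_single_sample_network(
            "s", ["HSP90B1"], {"HSP90B1": link}, {"pk1": {"JUN"}}, calls, scores,
            validation_sets={"curated_tfdb": {("JUN", "HSP90B1")}},
        )
        assert len(edges) == 1
        e = edges[0]
        assert (e.tf_name, e.target, e.sign) == ("JUN", "HSP90B1", "-")
        assert e.weight == pytest.approx(0.474)
        assert e.evidence == {"curated_tfdb"}

    def test_pair_missing_from_score_table_dropped(self):
        link, calls, scores = self._setup(score=None)
        edges = build_single_sample_network(
            "s", ["HSP90B1"], {"HSP90B1": link}, {"pk1": {"JUN"}}, calls, scores
        )
        assert edges == []

    def test_planted_repressed_gene_yields_exactly_planted_edge(self):
        """Minimal end-to-end fixture: one repressed gene, full score table."""
        link, calls, scores = self._setup()
        calls.tf_calls["OTHER"] = DeviationCall("s", "OTHER", "normal", 0.0, 0.8)
        edges = build_single_sample_network(
            "s", ["HSP90B1"], {"HSP90B1": link}, {"pk1": {"JUN", "OTHER"}},
            calls, scores,
        )
        assert [(e.tf_name, e.target, e.sign) for e in edges] == [
            ("JUN", "HSP90B1", "-")
        ]
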