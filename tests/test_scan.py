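"""Scanner correctness against exhaustive enumeration and hand cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifturnover import (
    GenomicInterval,
    MotifMatrix,
    ScanConfig,
    collapse_cluster_instances,
    extract_upstream,
    pwm_log_odds,
    scan_sequence,
    score_threshold_from_pvalue,
)
from motifturnover.io import UNCLUSTERED
from motifturnover.scan import (
    RegionRejected,
    ScanHit,
    reverse_complement,
    score_distribution,
)

CFG = ScanConfig(pseudocount=0.0)


def enumerate_scores(pwm: np.ndarray) -> np.ndarray:
    """All 4^w window scores by exhaustive enumeration (brute-force oracle)."""
    scores = np.zeros(1)
    for row in pwm:
        scores = (scores[:, None] + row[None, :]).ravel()
    return scores


class TestLogOdds:
    def test_uniform_row_scores_zero(self):
        m = MotifMatrix("U", "u", np.full((3, 4), 0.25))
        assert np.allclose(pwm_log_odds(m, CFG), 0.0)

    def test_direct_arithmetic(self):
        m = MotifMatrix("D", "d", np.array([[0.97, 0.01, 0.01, 0.01]]))
        lo = pwm_log_odds(m, CFG)
        assert lo[0, 0] == pytest.approx(np.log2(0.97 / 0.25), abs=1e-9)
        assert lo[0, 0] == pytest.approx(1.956, abs=1e-3)

    def test_zero_probability_gives_finite_sentinel(self):
        m = MotifMatrix("Z", "z", np.array([[1.0, 0.0, 0.0, 0.0]]))
        lo = pwm_log_odds(m, CFG)
        assert np.all(np.isfinite(lo))
        assert lo[0, 1] < -100

    def test_pseudocount_formula(self):
        m = MotifMatrix("P", "p", np.array([[0.5, 0.5, 0.0, 0.0]]))
        lo = pwm_log_odds(m, ScanConfig(pseudocount=1.0))
        assert lo[0, 0] == pytest.approx(np.log2((0.5 + 0.25) / (2 * 0.25)))
        assert lo[0, 2] == pytest.approx(np.log2((0.0 + 0.25) / (2 * 0.25)))


class TestThresholdDP:
    def test_width1_single_column(self):
        m = MotifMatrix("W1", "w", np.array([[0.7, 0.1, 0.1, 0.1]]))
        pwm = pwm_log_odds(m, CFG)
        thr, dist = score_threshold_from_pvalue(pwm, ScanConfig(p_threshold=0.3, pseudocount=0))
        # only the best base scores >= thr: tail mass 0.25 under uniform bg
        assert dist.tail(thr) == pytest.approx(0.25)
        assert thr == pytest.approx(pwm.max(), abs=dist.step + 1e-9)

    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_dp_tail_matches_enumeration(self, rng, width):
        """DP survival equals brute-force tails at every attainable score."""
        probs = rng.dirichlet([0.8] * 4, size=width)
        pwm = pwm_log_odds(MotifMatrix("E", "e", probs), ScanConfig())
        dist = score_distribution(pwm, ScanConfig())
        exact = enumerate_scores(pwm)
        weights = np.full(len(exact), 0.25**width)
        for g, sf in zip(dist.grid_scores, dist.sf):
            lo = weights[exact >= g + dist.step].sum()
            hi = weights[exact >= g - dist.step].sum()
            assert lo - 1e-12 <= sf <= hi + 1e-12

    def test_p1_returns_min_attainable(self, rng):
        probs = rng.dirichlet([1.0] * 4, size=3)
        pwm = pwm_log_odds(MotifMatrix("E", "e", probs), ScanConfig())
        thr, dist = score_threshold_from_pvalue(pwm, ScanConfig(p_threshold=1.0))
        assert thr == pytest.approx(dist.grid_scores[0])
        assert dist.tail(thr) == pytest.approx(1.0)


class TestScan:
    def test_sequence_shorter_than_motif(self, sharp_motif):
        assert scan_sequence(sharp_motif, "ACG", ScanConfig()) == []

    def test_planted_consensus_found_at_position(self, rng, sharp_motif):
        bg = "".join(rng.choice(list("ACGT"), 500))
        seq = bg[:100] + sharp_motif.consensus + bg[108:]
        hits = scan_sequence(sharp_motif, seq, ScanConfig())
        assert any(h.interval.start == 100 and h.strand == "+" for h in hits)
        # brute-force check of the reported score at the planted site
        pwm = pwm_log_odds(sharp_motif, ScanConfig())
        expected = sum(pwm[i, "ACGT".index(b)] for i, b in enumerate(sharp_motif.consensus))
        hit = next(h for h in hits if h.interval.start == 100)
        assert hit.score == pytest.approx(expected)
        assert hit.p_value <= 1e-4

    def test_palindrome_collapsed_to_one_hit_per_position(self, rng):
        # reverse-complement palindrome: GAATTC-like, strand scores equal
        probs = np.full((6, 4), 0.01)
        for i, b in enumerate("GAATTC"):
            probs[i, "ACGT".index(b)] = 0.97
        pal = MotifMatrix("PAL", "pal", probs)
        assert reverse_complement(pal.consensus) == pal.consensus
        bg = "".join(rng.choice(list("ACGT"), 300))
        seq = bg[:50] + "GAATTC" + bg[56:150] + "GAATTC" + bg[156:]
        cfg = ScanConfig(p_threshold=2e-3)
        hits = scan_sequence(pal, seq, cfg)
        starts = [h.interval.start for h in hits]
        assert len(starts) == len(set(starts))  # one hit per position
        for h in hits:
            if h.interval.start in (50, 150):
                assert h.strand == "+"  # tie goes to forward strand
        assert {50, 150} <= set(starts)

    def test_n_windows_skipped(self, sharp_motif):
        seq = sharp_motif.consensus[:4] + "N" + sharp_motif.consensus[5:]
        assert scan_sequence(sharp_motif, seq, ScanConfig()) == []

    @pytest.mark.parametrize("width,p_thr", [(3, 0.02), (5, 5e-3), (8, 1e-4)])
    def test_scanner_equals_brute_force(self, rng, width, p_thr):
        """Hit sets match exhaustive window scoring away from the grid edge."""
        probs = rng.dirichlet([0.5] * 4, size=width)
        motif = MotifMatrix("BF", "bf", probs)
        cfg = ScanConfig(p_threshold=p_thr)
        pwm = pwm_log_odds(motif, cfg)
        thr, dist = score_threshold_from_pvalue(pwm, cfg)
        pwm_rc = pwm[::-1, ::-1]
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 100))
            hits = {h.interval.start for h in scan_sequence(motif, seq, cfg)}
            expected = set()
            borderline = set()
            for pos in range(100 - width + 1):
                window = [int("ACGT".index(b)) for b in seq[pos : pos + width]]
                s = max(
                    sum(pwm[i, b] for i, b in enumerate(window)),
                    sum(pwm_rc[i, b] for i, b in enumerate(window)),
                )
                if abs(s - thr) <= dist.step + 1e-9:
                    borderline.add(pos)
                elif s > thr:
                    expected.add(pos)
            assert expected <= hits <= expected | borderline

    def test_false_positive_rate_matches_exact_probability(self, rng):
        """Hits on iid uniform windows occur at the exact enumerated rate."""
        width = 5
        probs = rng.dirichlet([0.7] * 4, size=width)
        motif = MotifMatrix("FP", "fp", probs)
        cfg = ScanConfig(p_threshold=0.01)
        pwm = pwm_log_odds(motif, cfg)
        thr, _ = score_threshold_from_pvalue(pwm, cfg)
        # exact per-window max-strand hit probability from 4^w enumeration
        pwm_rc = pwm[::-1, ::-1]
        fwd = enumerate_scores(pwm)
        rev = enumerate_scores(pwm_rc)
        p_hit = float(np.mean(np.maximum(fwd, rev) >= thr - 1e-9))
        # 2e4 windows of length w separated by N so no cross-window hits
        n_windows = 20_000
        blocks = rng.choice(list("ACGT"), size=(n_windows, width))
        seq = "N".join("".join(b) for b in blocks)
        n_hits = len(scan_sequence(motif, seq, cfg))
        se = np.sqrt(n_windows * p_hit * (1 - p_hit))
        assert abs(n_hits - n_windows * p_hit) <= 3 * se + 1e-9


class TestExtractUpstream:
    def test_insufficient_upstream_rejected(self):
        contig = "A" * 400
        with pytest.raises(RegionRejected, match="insufficient_upstream"):
            extract_upstream(contig, GenomicInterval("c", 100, 103, "+"),
                             ScanConfig(window_bp=500))

    def test_n_fraction_rejected(self):
        contig = "A" * 100 + "N" * 30 + "A" * 370 + "ATG" + "A" * 50
        with pytest.raises(RegionRejected, match="n_fraction"):
            extract_upstream(contig, GenomicInterval("c", 500, 503, "+"),
                             ScanConfig(window_bp=500))

    def test_five_percent_n_tolerated(self):
        contig = "N" * 25 + "A" * 475 + "ATG"
        region = extract_upstream(contig, GenomicInterval("c", 500, 503, "+"),
                                  ScanConfig(window_bp=500))
        assert region.n_frac == pytest.approx(0.05)

    def test_minus_strand_hand_case(self):
        #          0123456789012345678901234567890
        contig = "ACGTACGTACGTACGTACGTACGTACGTAC"
        anchor = GenomicInterval("c", 5, 8, "-")
        region = extract_upstream(contig, anchor, ScanConfig(window_bp=10),
                                  "og1", "asm1")
        # upstream of a minus-strand gene = RC of the 10 bases right of the anchor
        assert region.sequence == reverse_complement(contig[8:18])
        assert region.region_id == "og1|asm1"

    def test_anchor_outside_contig(self):
        with pytest.raises(ValueError, match="outside"):
            extract_upstream("ACGT", GenomicInterval("c", 10, 13, "+"), ScanConfig())


def _hit(motif_id, start, end, strand="+"):
    return ScanHit(motif_id, GenomicInterval("r", start, end, strand), strand, 10.0, 1e-5)


class TestCollapse:
    CMAP = {"m1": "c1", "m2": "c1", "m3": "c2"}

    def test_overlapping_same_cluster_merge(self):
        counts, merged = collapse_cluster_instances(
            [_hit("m1", 10, 19), _hit("m2", 15, 24)], self.CMAP
        )
        assert counts == {"c1": 1}
        assert merged["c1"] == [(10, 24)]

    def test_disjoint_same_cluster_counted_separately(self):
        counts, _ = collapse_cluster_instances(
            [_hit("m1", 0, 8), _hit("m2", 20, 28)], self.CMAP
        )
        assert counts == {"c1": 2}

    def test_different_clusters_never_merge(self):
        counts, _ = collapse_cluster_instances(
            [_hit("m1", 10, 19), _hit("m3", 15, 24)], self.CMAP
        )
        assert counts == {"c1": 1, "c2": 1}

    def test_unmapped_motif_counts_as_unclustered(self):
        counts, _ = collapse_cluster_instances([_hit("mX", 0, 8)], self.CMAP)
        assert counts == {UNCLUSTERED: 1}

    def test_strand_ignored_for_merging(self):
        counts, _ = collapse_cluster_instances(
            [_hit("m1", 10, 19, "+"), _hit("m2", 15, 24, "-")], self.CMAP
        )
        assert counts == {"c1": 1}

    @given(
        st.lists(
            st.tuples(st.sampled_from(["m1", "m2", "m3"]), st.integers(0, 80)),
            min_size=1, max_size=25,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_collapse_idempotent_and_order_invariant(self, raw, pyrandom):
        hits = [_hit(m, s, s + 8) for m, s in raw]
        counts1, merged1 = collapse_cluster_instances(hits, self.CMAP)
        shuffled = list(hits)
        pyrandom.shuffle(shuffled)
        counts2, merged2 = collapse_cluster_instances(shuffled, self.CMAP)
        assert counts1 == counts2 and merged1 == merged2
        # idempotence: collapsing the merged intervals changes nothing
        rehits = [
            _hit({"c1": "m1", "c2": "m3", UNCLUSTERED: "mX"}[c], s, e)
            for c, ivals in merged1.items() for s, e in ivals
        ]
        counts3, merged3 = collapse_cluster_instances(rehits, self.CMAP)
        assert counts3 == counts1 and merged3 == merged1


def test_counts_invariant_under_window_reverse_complement(rng, sharp_motif):
    """Max-strand scanning is RC-symmetric up to coordinate reflection."""
    cmap = {"SHARP": "clusterA"}
    for _ in range(5):
        bg = "".join(rng.choice(list("ACGT"), 300))
        seq = bg[:40] + sharp_motif.consensus + bg[48:120] + \
            reverse_complement(sharp_motif.consensus) + bg[128:]
        fwd_hits = scan_sequence(sharp_motif, seq, ScanConfig())
        rc_hits = scan_sequence(sharp_motif, reverse_complement(seq), ScanConfig())
        c1, _ = collapse_cluster_instances(fwd_hits, cmap)
        c2, _ = collapse_cluster_instances(rc_hits, cmap)
        assert c1 == c2
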