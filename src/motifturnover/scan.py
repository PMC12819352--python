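"""PWM scanning of upstream windows with an exact p-value threshold.

The scoring model is FIMO-style log2-odds against a background base
composition. The score threshold for a given p-value is obtained from the
exact null score distribution, computed by dynamic programming over
discretized per-position scores (convolution of per-column score
distributions under the background model). Scanning scores both strands at
every start position and keeps the better one (max-strand), so at most one
hit is reported per position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import BASES, UNCLUSTERED, GenomicInterval, MotifMatrix

_NEG_SENTINEL = -1e4  # stands in for log2(0): unreachable by any threshold


@dataclass(frozen=True)
class ScanConfig:
    """Scanning parameters.

    p_threshold: per-window score p-value cutoff (default 1e-4).
    background: per-base probabilities over A,C,G,T (default uniform).
    pseudocount: background-weighted pseudocount added to each probability.
    window_bp: upstream window length in bp (500 default; 1000 supported).
    max_n_frac: maximum tolerated fraction of N bases in a window.
    score_bins: discretization bins per motif column for the threshold DP.
    """

    p_threshold: float = 1e-4
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 0.1
    window_bp: int = 500
    max_n_frac: float = 0.05
    score_bins: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must lie in (0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if self.window_bp < 1:
            raise ValueError("window_bp must be positive")


@dataclass(frozen=True)
class ScanHit:
    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float
    p_value: float


@dataclass(frozen=True)
class UpstreamRegion:
    orthogroup_id: str
    assembly_id: str
    sequence: str

    @property
    def n_frac(self) -> float:
        return self.sequence.count("N") / len(self.sequence)

    @property
    def region_id(self) -> str:
        return f"{self.orthogroup_id}|{self.assembly_id}"


class RegionRejected(ValueError):
    """Raised when an upstream window fails extraction filters."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


# ---------------------------------------------------------------------------
# scoring


def pwm_log_odds(motif: MotifMatrix, config: ScanConfig = ScanConfig()) -> np.ndarray:
    """Log2-odds matrix: log2((p + pc*bg) / ((1+pc)*bg)).

    Zero probabilities with pseudocount 0 yield a large negative sentinel
    (finite, so the DP stays well-defined) rather than -inf.
    """
    bg = np.asarray(config.background)
    pc = config.pseudocount
    num = motif.probs + pc * bg[None, :]
    den = (1.0 + pc) * bg[None, :]
    with np.errstate(divide="ignore"):
        lo = np.log2(num / den)
    lo[np.isneginf(lo)] = _NEG_SENTINEL
    return lo


@dataclass
class ScoreDistribution:
    """Discretized exact null score distribution of a PWM.

    ``grid_scores`` are the discretized attainable score values (bin left
    edges, ascending) and ``sf`` the exact survival P(score >= grid) under
    the background model. ``step`` bounds the discretization error of any
    score (w * per-column rounding).
    """

    grid_scores: np.ndarray
    sf: np.ndarray
    step: float

    def tail(self, score: float) -> float:
        """P(score >= s) evaluated at the largest grid value <= s."""
        idx = np.searchsorted(self.grid_scores, score + 1e-12, side="right") - 1
        idx = max(idx, 0)
        return float(self.sf[idx])


def score_distribution(pwm: np.ndarray, config: ScanConfig = ScanConfig()) -> ScoreDistribution:
    """Exact null distribution of the max-precision discretized PWM score.

    Each column's scores are shifted to nonnegative integers on a common
    scale (``score_bins`` bins per column, round-down), then the per-column
    integer-score distributions are convolved under the background model.
    """
    w = pwm.shape[0]
    bg = np.asarray(config.background)
    offsets = pwm.min(axis=1)
    ranges = pwm.max(axis=1) - offsets
    max_range = ranges.max()
    if max_range <= 0:  # constant-score motif
        total = float(pwm.max(axis=1).sum())
        return ScoreDistribution(np.array([total]), np.array([1.0]), 0.0)
    scale = config.score_bins / max_range
    n_bins = int(np.floor(max_range * scale)) + 1
    if w * n_bins > 50_000_000:
        raise ValueError(
            f"motif width {w} with {config.score_bins} bins needs too large a DP "
            "table; lower score_bins"
        )
    ints = np.floor((pwm - offsets[:, None]) * scale).astype(np.int64)
    pmf = np.zeros(1)
    pmf[0] = 1.0
    for i in range(w):
        col = np.zeros(ints[i].max() + 1)
        np.add.at(col, ints[i], bg)
        pmf = np.convolve(pmf, col)
    support = np.flatnonzero(pmf > 0)
    probs = pmf[support]
    grid_scores = support / scale + offsets.sum()
    sf = np.cumsum(probs[::-1])[::-1]
    sf = np.minimum(sf, 1.0)
    return ScoreDistribution(grid_scores, sf, step=w / scale)


def score_threshold_from_pvalue(
    pwm: np.ndarray, config: ScanConfig = ScanConfig()
) -> tuple[float, ScoreDistribution]:
    """Minimal discretized score t with P(score >= t) <= p_threshold.

    Returns (threshold, distribution). With p_threshold = 1 the threshold
    is the minimal attainable score. If even the maximal score exceeds the
    p target (low-information motif), the threshold is set just above the
    maximum so that no window can ever pass.
    """
    dist = score_distribution(pwm, config)
    ok = np.flatnonzero(dist.sf <= config.p_threshold)
    if config.p_threshold >= 1.0:
        return float(dist.grid_scores[0]), dist
    if ok.size == 0:
        return float(dist.grid_scores[-1]) + dist.step + 1.0, dist
    return float(dist.grid_scores[ok[0]]), dist


# ---------------------------------------------------------------------------
# scanning


def _encode(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3, anything else (N) -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def scan_sequence(
    motif: MotifMatrix,
    seq: str,
    config: ScanConfig = ScanConfig(),
    seq_id: str = "region",
    _cache: dict | None = None,
) -> list[ScanHit]:
    """Scan one sequence with one motif, max-strand, exact p threshold.

    Windows containing any N are skipped. Forward/reverse score ties
    report the forward strand. Positions are 0-based within ``seq``.
    """
    w = motif.width
    if len(seq) < w:
        return []
    if _cache is not None and motif.motif_id in _cache:
        pwm, threshold, dist = _cache[motif.motif_id]
    else:
        pwm = pwm_log_odds(motif, config)
        threshold, dist = score_threshold_from_pvalue(pwm, config)
        if _cache is not None:
            _cache[motif.motif_id] = (pwm, threshold, dist)
    enc = _encode(seq)
    n_pos = len(seq) - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)[:n_pos]
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return []
    # reverse-complement scan == forward scan with the RC'd PWM
    pwm_rc = pwm[::-1, ::-1]
    idx = np.arange(w)
    wv = windows[valid]
    fwd = pwm[idx, wv].sum(axis=1)
    rev = pwm_rc[idx, wv].sum(axis=1)
    best = np.where(fwd >= rev, fwd, rev)
    strands = np.where(fwd >= rev, "+", "-")
    # compare on the discretized grid the threshold lives on: accept scores
    # within half a grid step below the threshold to avoid float fuzz
    keep = best >= threshold - 1e-9
    positions = np.flatnonzero(valid)[keep]
    hits = []
    for pos, score, strand in zip(positions, best[keep], strands[keep]):
        hits.append(
            ScanHit(
                motif_id=motif.motif_id,
                interval=GenomicInterval(seq_id, int(pos), int(pos) + w, str(strand)),
                strand=str(strand),
                score=float(score),
                p_value=dist.tail(float(score)),
            )
        )
    return hits


def extract_upstream(
    contig_seq: str,
    anchor: GenomicInterval,
    config: ScanConfig = ScanConfig(),
    orthogroup_id: str = "",
    assembly_id: str = "",
) -> UpstreamRegion:
    """Extract the window upstream of a translation start.

    Plus strand: bases [start - window_bp, start). Minus strand: reverse
    complement of [end, end + window_bp). Raises :class:`RegionRejected`
    with reason ``insufficient_upstream`` or ``n_fraction`` when the
    window cannot be taken, and ``ValueError`` when the anchor lies
    outside the contig.
    """
    L = len(contig_seq)
    if anchor.start >= L or anchor.end > L:
        raise ValueError(f"anchor {anchor} outside contig of length {L}")
    wbp = config.window_bp
    if anchor.strand == "+":
        lo = anchor.start - wbp
        if lo < 0:
            raise RegionRejected("insufficient_upstream", f"need {wbp} bp, have {anchor.start}")
        window = contig_seq[lo : anchor.start]
    else:
        hi = anchor.end + wbp
        if hi > L:
            raise RegionRejected("insufficient_upstream", f"need {wbp} bp, have {L - anchor.end}")
        window = reverse_complement(contig_seq[anchor.end : hi])
    window = window.upper()
    n_frac = window.count("N") / wbp
    if n_frac > config.max_n_frac:
        raise RegionRejected("n_fraction", f"{n_frac:.3f} > {config.max_n_frac}")
    return UpstreamRegion(orthogroup_id, assembly_id, window)


# ---------------------------------------------------------------------------
# cluster collapsing


def collapse_cluster_instances(
    hits: Sequence[ScanHit],
    cluster_map: Mapping[str, str],
) -> tuple[dict[str, int], dict[str, list[tuple[int, int]]]]:
    """Collapse overlapping same-cluster hits into merged intervals.

    Within each cluster, hits sharing >= 1 base merge transitively
    (strand-blind); the instance count per cluster is the number of merged
    intervals. Hits whose motif is absent from the map count under
    ``UNCLUSTERED``. Returns (counts, merged intervals) keyed by cluster.
    """
    by_cluster: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        cluster = cluster_map.get(h.motif_id, UNCLUSTERED)
        by_cluster.setdefault(cluster, []).append((h.interval.start, h.interval.end))
    counts: dict[str, int] = {}
    merged: dict[str, list[tuple[int, int]]] = {}
    for cluster, ivals in by_cluster.items():
        ivals.sort()
        out: list[tuple[int, int]] = []
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s < cur_e:  # >= 1 shared base
                cur_e = max(cur_e, e)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cur_s, cur_e))
        merged[cluster] = out
        counts[cluster] = len(out)
    return counts, merged


def scan_regions(
    regions: Iterable[UpstreamRegion],
    motifs: Sequence[MotifMatrix],
    cluster_map: Mapping[str, str] | None = None,
    config: ScanConfig = ScanConfig(),
):
    """Scan many regions with many motifs; return a tidy counts DataFrame.

    Columns: assembly, orthogroup, cluster, count — the currency consumed
    by the occupancy and association stages. The cluster map defaults to
    each motif's own ``cluster_id``.
    """
    import pandas as pd

    if cluster_map is None:
        cluster_map = {m.motif_id: m.cluster_id for m in motifs}
    cache: dict = {}
    rows = []
    for region in regions:
        hits: list[ScanHit] = []
        for m in motifs:
            hits.extend(scan_sequence(m, region.sequence, config, region.region_id, cache))
        counts, _ = collapse_cluster_instances(hits, cluster_map) if hits else ({}, {})
        for cluster, count in sorted(counts.items()):
            rows.append((region.assembly_id, region.orthogroup_id, cluster, count))
    return pd.DataFrame(rows, columns=["assembly", "orthogroup", "cluster", "count"])
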