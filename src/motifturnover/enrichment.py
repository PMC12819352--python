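"""Motif enrichment versus dinucleotide-shuffled backgrounds.

Each candidate regulatory region is shuffled (Altschul–Erikson exact
dinucleotide shuffle, preserving the dinucleotide count multiset and the
terminal bases) a fixed number of times (default 100). Motif counts in
the shuffled replicates form the background sample; a Poisson or negative
binomial distribution is fitted by maximum likelihood and selected by
AIC, with an empirical fallback. Two-tailed p-values against the fitted
null identify over- and under-represented motifs, controlled by
Benjamini–Hochberg FDR (default threshold 0.01) within species. A pooled
2x2 Fisher's exact test (observed vs mean shuffled counts against window
totals) is reported alongside the fitted-distribution test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MotifMatrix
from .scan import ScanConfig, scan_sequence

DEFAULT_N_SHUFFLES = 100
DEFAULT_FDR_ALPHA = 0.01


# ---------------------------------------------------------------------------
# Altschul–Erikson dinucleotide shuffle


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the exact dinucleotide count multiset.

    Uniform random Eulerian path on the dinucleotide multigraph
    (Altschul–Erikson): the output has the input's dinucleotide counts
    exactly and the same first and last base. Runs of N split the
    sequence into segments shuffled independently.
    """
    if "N" in seq:
        out, i = [], 0
        while i < len(seq):
            if seq[i] == "N":
                out.append("N")
                i += 1
            else:
                j = i
                while j < len(seq) and seq[j] != "N":
                    j += 1
                out.append(_shuffle_segment(seq[i:j], rng))
                i = j
        return "".join(out)
    return _shuffle_segment(seq, rng)


def _shuffle_segment(seq: str, rng: np.random.Generator) -> str:
    if len(seq) < 3:
        return seq
    # adjacency lists: edges[u] = multiset of successors
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = [v for v in edges if v != last]
    # choose a random last edge per non-terminal vertex until the last-edge
    # graph connects every vertex to the terminal vertex
    for _ in range(10_000):
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        if _connects_to_terminal(last_edge, last):
            break
    else:  # pragma: no cover - probability vanishes for real sequences
        raise RuntimeError("failed to sample an Eulerian-path arborescence")
    # shuffle remaining edges, append the chosen last edge at the end
    for v in vertices:
        rest = list(edges[v])
        rest.remove(last_edge[v])
        order = rng.permutation(len(rest))
        edges[v] = [rest[i] for i in order] + [last_edge[v]]
    if last in edges:
        rest = list(edges[last])
        order = rng.permutation(len(rest))
        edges[last] = [rest[i] for i in order]
    # walk the Eulerian path
    out = [seq[0]]
    ptr = {v: 0 for v in edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = edges[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _connects_to_terminal(last_edge: Mapping[str, str], terminal: str) -> bool:
    for v in last_edge:
        seen = set()
        cur = v
        while cur != terminal:
            if cur in seen or cur not in last_edge:
                return False
            seen.add(cur)
            cur = last_edge[cur]
    return True


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts = {a + b: 0 for a, b in product("ACGTN", repeat=2)}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] += 1
    return {k: v for k, v in counts.items() if v}


# ---------------------------------------------------------------------------
# background fitting


@dataclass
class BackgroundModel:
    """Fitted null distribution of a motif's background count.

    family is one of poisson / negative_binomial / empirical. Parameters:
    poisson -> (mu,); negative_binomial -> (r, p) in scipy's nbinom
    convention; empirical -> the raw counts themselves.
    """

    family: str
    parameters: tuple[float, ...]
    n_shuffles: int
    raw_counts: np.ndarray

    @property
    def mean(self) -> float:
        if self.family == "poisson":
            return self.parameters[0]
        if self.family == "negative_binomial":
            r, p = self.parameters
            return r * (1 - p) / p
        return float(np.mean(self.raw_counts))

    def cdf(self, x: int) -> float:
        if self.family == "poisson":
            return float(stats.poisson.cdf(x, self.parameters[0]))
        if self.family == "negative_binomial":
            return float(stats.nbinom.cdf(x, *self.parameters))
        return float(np.mean(self.raw_counts <= x))

    def sf_inclusive(self, x: int) -> float:
        """P(X >= x)."""
        if self.family == "poisson":
            return float(stats.poisson.sf(x - 1, self.parameters[0]))
        if self.family == "negative_binomial":
            return float(stats.nbinom.sf(x - 1, *self.parameters))
        return float(np.mean(self.raw_counts >= x))


def fit_background(counts: Sequence[int]) -> BackgroundModel:
    """Fit Poisson and negative binomial by ML, select by AIC.

    Falls back to the empirical distribution when the counts are constant
    (variance 0) or when neither parametric fit succeeds.
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    if n < 1:
        raise ValueError("need at least one background count")
    mean = counts.mean()
    var = counts.var(ddof=1) if n > 1 else 0.0
    if var == 0.0:
        return BackgroundModel("empirical", tuple(), n, counts.astype(int))

    mu = max(mean, 1e-12)
    ll_pois = float(stats.poisson.logpmf(counts, mu).sum())
    aic_pois = 2 * 1 - 2 * ll_pois

    nb_params, aic_nb = _fit_nbinom(counts, mu, var)
    if nb_params is not None and aic_nb < aic_pois:
        return BackgroundModel("negative_binomial", nb_params, n, counts.astype(int))
    return BackgroundModel("poisson", (mu,), n, counts.astype(int))


def _fit_nbinom(counts: np.ndarray, mu: float, var: float):
    """ML fit of nbinom(r, p) with mean fixed at the sample mean."""
    from scipy.optimize import minimize_scalar

    if var <= mu:  # underdispersed: NB cannot beat Poisson
        return None, np.inf

    def nll(log_r: float) -> float:
        r = np.exp(log_r)
        p = r / (r + mu)
        return -float(stats.nbinom.logpmf(counts, r, p).sum())

    r0 = mu**2 / (var - mu)
    try:
        res = minimize_scalar(
            nll, bracket=(np.log(r0) - 2, np.log(r0), np.log(r0) + 2), method="brent"
        )
    except Exception:
        return None, np.inf
    if not np.isfinite(res.fun):
        return None, np.inf
    r = float(np.exp(res.x))
    p = r / (r + mu)
    aic = 2 * 2 + 2 * res.fun
    return (r, p), aic


# ---------------------------------------------------------------------------
# testing


@dataclass
class EnrichmentResult:
    motif_id: str
    species_id: str
    observed_count: int
    background_mean: float
    log2_fold_change: float
    p_two_tailed: float
    q_value: float = np.nan
    direction: str = "ns"
    p_fisher: float = np.nan


def enrichment_test(observed: int, model: BackgroundModel) -> tuple[float, float]:
    """Two-tailed p against the fitted null and the continuity log2FC.

    p = min(1, 2 * min(P(X <= obs), P(X >= obs)));
    log2FC = log2((obs + 0.5) / (mean + 0.5)).
    """
    lower = model.cdf(observed)
    upper = model.sf_inclusive(observed)
    p = min(1.0, 2.0 * min(lower, upper))
    p = max(p, np.finfo(float).tiny)
    log2fc = float(np.log2((observed + 0.5) / (model.mean + 0.5)))
    return log2fc, p


def enrich_species(
    regions: Mapping[str, str],
    motifs: Sequence[MotifMatrix],
    species_id: str,
    config: ScanConfig = ScanConfig(),
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full enrichment battery for one species' candidate regions.

    Scans the real regions and ``n_shuffles`` dinucleotide-shuffled
    replicates of each, fits a background model per motif, and reports
    the fitted-distribution two-tailed test (BH-FDR across motifs within
    the species) plus a pooled Fisher's exact test.
    """
    from .plmm import bh_fdr

    if rng is None:
        rng = np.random.default_rng(0)
    region_items = sorted(regions.items())
    cache: dict = {}
    observed = {m.motif_id: 0 for m in motifs}
    for _, seq in region_items:
        for m in motifs:
            observed[m.motif_id] += len(scan_sequence(m, seq, config, _cache=cache))
    # one background count per shuffle replicate (summed over regions)
    bg_counts = {m.motif_id: np.zeros(n_shuffles, dtype=int) for m in motifs}
    for rep in range(n_shuffles):
        for _, seq in region_items:
            shuffled = dinucleotide_shuffle(seq, rng)
            for m in motifs:
                bg_counts[m.motif_id][rep] += len(
                    scan_sequence(m, shuffled, config, _cache=cache)
                )
    results = []
    for m in motifs:
        model = fit_background(bg_counts[m.motif_id])
        log2fc, p = enrichment_test(observed[m.motif_id], model)
        mean_bg = model.mean
        # pooled 2x2: hits vs non-hit scan positions, real vs mean-shuffled
        total_pos = sum(max(len(seq) - m.width + 1, 0) for _, seq in region_items)
        table = np.array(
            [
                [observed[m.motif_id], max(total_pos - observed[m.motif_id], 0)],
                [round(mean_bg), max(total_pos - round(mean_bg), 0)],
            ]
        )
        _, p_fisher = stats.fisher_exact(table)
        results.append(
            EnrichmentResult(
                m.motif_id, species_id, observed[m.motif_id], mean_bg, log2fc, p,
                p_fisher=float(p_fisher),
            )
        )
    q = bh_fdr(np.array([r.p_two_tailed for r in results]))
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        if qv < fdr_alpha:
            r.direction = "enriched" if r.log2_fold_change > 0 else "depleted"
    return pd.DataFrame([vars(r) for r in results])


def enriched_set(df: pd.DataFrame, fdr_alpha: float = DEFAULT_FDR_ALPHA) -> set[str]:
    """Motifs significantly over-represented (direction == enriched)."""
    mask = (df["q_value"] < fdr_alpha) & (df["log2_fold_change"] > 0)
    return set(df.loc[mask, "motif_id"])


def common_enrichment(per_species: Mapping[str, set[str]]) -> pd.DataFrame:
    """Counts of motifs per species-subset membership pattern (upset-style).

    Returns one row per nonempty pattern with columns ``pattern`` (tuple of
    member species), ``count``, plus summary rows accessible via
    :func:`enrichment_summary`. The all-species intersection is the row
    whose pattern includes every species.
    """
    species = sorted(per_species)
    universe = set().union(*per_species.values()) if per_species else set()
    pattern_counts: dict[tuple[str, ...], int] = {}
    for motif in universe:
        pattern = tuple(s for s in species if motif in per_species[s])
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1
    rows = [
        {"pattern": p, "n_species": len(p), "count": c}
        for p, c in sorted(pattern_counts.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["pattern", "n_species", "count"])


def enrichment_summary(per_species: Mapping[str, set[str]]) -> dict[str, int]:
    species = sorted(per_species)
    universe = set().union(*per_species.values()) if per_species else set()
    inter = set(universe)
    for s in species:
        inter &= per_species[s]
    return {"union": len(universe), "all_species_intersection": len(inter)}
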