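"""Synthetic data with known ground truth for every pipeline stage.

The generator produces (i) an ultrametric birth–death phylogeny, (ii)
motif-cluster counts evolving along it under a gain/loss continuous-time
Markov chain (gains at rate gamma per branch-length unit, losses at rate
delta per existing copy), (iii) upstream windows in which each count is
realized as that many embedded consensus instances on an i.i.d.
background, and (iv) environmental PC traits with Brownian phylogenetic
structure plus optional planted linear effects of motif counts. Because
counts and sequences are coupled, the scanner can be validated against
the exact embedded truth; because the gain/loss process has a known
stationary law (Poisson(gamma/delta)), shared-occupancy decay has an
analytic asymptote to test against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import MotifMatrix, parse_newick, write_fasta
from .occupancy import OccupancyTable


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline.

    Defaults give a tree deep enough for substantial motif turnover
    (stationary count Poisson(gain_rate/loss_rate) = Poisson(2)) and
    environmental traits dominated by Brownian structure with moderate
    i.i.d. noise, so planted effects are detectable but not trivial.
    """

    n_taxa: int = 300
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_orthogroups: int = 200
    n_clusters: int = 5
    root_count: int = 2
    gain_rate: float = 1.0
    loss_rate: float = 0.5
    bm_rate: float = 1.0
    n_env_pcs: int = 10
    effect_map: dict = field(default_factory=dict)  # (og, cluster) -> (envPC, beta)
    noise_sd: float = 0.5
    window_bp: int = 500
    gc_content: float = 0.5
    motif_width: int = 8
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("birth_rate", "gain_rate", "loss_rate", "bm_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.death_rate < 0 or self.death_rate >= self.birth_rate:
            raise ValueError("need birth_rate > death_rate >= 0")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")


@dataclass
class SimOutput:
    tree: dendropy.Tree
    counts: OccupancyTable
    env: pd.DataFrame
    sequences: dict[str, str] | None
    event_log: pd.DataFrame
    truth: dict

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "tree.nwk").write_text(
            self.tree.as_string(schema="newick", suppress_rooting=True)
        )
        self.counts.to_tsv(path / "counts.tsv")
        self.env.to_csv(path / "env.tsv", sep="\t")
        self.event_log.to_csv(path / "events.tsv", sep="\t", index=False)
        if self.sequences is not None:
            (path / "upstream.fa").write_text(write_fasta(self.sequences))
        (path / "truth.json").write_text(json.dumps(self.truth, indent=1, default=str))


# ---------------------------------------------------------------------------
# birth–death tree


class _Lineage:
    __slots__ = ("parent", "t_birth", "t_end", "children")

    def __init__(self, parent, t_birth: float):
        self.parent = parent
        self.t_birth = t_birth
        self.t_end: float | None = None  # split or death time; None = extant
        self.children: list["_Lineage"] = []


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    max_retries: int = 1000,
) -> dendropy.Tree:
    """Gillespie birth–death tree conditioned on n extant tips.

    Starts from the two daughters of the root at time 0 and stops the
    instant the n-th extant lineage is born (all tips are then cut at
    that time, so the tree is ultrametric). Replicates where either root
    subtree dies out are rejected and re-drawn; tips are labeled t001,
    t002, ... in traversal order, so a seeded rng gives an identical
    newick string.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 tips")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    for _ in range(max_retries):
        root = _Lineage(None, 0.0)
        root.t_end = 0.0
        left, right = _Lineage(root, 0.0), _Lineage(root, 0.0)
        root.children = [left, right]
        active = [left, right]
        t = 0.0
        failed = False
        while len(active) < n_taxa:
            total = (birth_rate + death_rate) * len(active)
            t += rng.exponential(1.0 / total)
            k = int(rng.integers(len(active)))
            lineage = active[k]
            if rng.random() < birth_rate / (birth_rate + death_rate):
                lineage.t_end = t
                a, b = _Lineage(lineage, t), _Lineage(lineage, t)
                lineage.children = [a, b]
                active[k] = a
                active.append(b)
            else:
                lineage.t_end = t
                active.pop(k)
                if not active:
                    failed = True
                    break
        if failed:
            continue
        for lin in active:
            lin.t_end = None  # extant, cut at t
        newick = _to_newick(root, t)
        if newick is None:  # a root subtree went extinct
            continue
        return parse_newick(newick + ";")
    raise RuntimeError(f"no surviving tree with {n_taxa} tips in {max_retries} tries")


def _to_newick(root: _Lineage, t_stop: float) -> str | None:
    counter = [0]

    def render(node: _Lineage) -> str | None:
        length = (t_stop if node.t_end is None else node.t_end) - node.t_birth
        if not node.children:
            if node.t_end is not None:
                return None  # extinct tip: prune
            counter[0] += 1
            return f"t{counter[0]:03d}:{length:.10g}"
        parts = [render(c) for c in node.children]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        if len(parts) == 1:  # collapse unifurcation, extend the branch
            name, _, sub_len = parts[0].rpartition(":")
            return f"{name}:{float(sub_len) + length:.10g}"
        return f"({','.join(parts)}):{length:.10g}"

    left = render(root.children[0])
    right = render(root.children[1])
    if left is None or right is None:
        return None
    return f"({left},{right})"


# ---------------------------------------------------------------------------
# gain/loss count evolution


def simulate_motif_counts(
    tree: dendropy.Tree,
    gain_rate: float,
    loss_rate: float,
    root_counts: Mapping[str, int],
    n_orthogroups: int,
    rng: np.random.Generator | None = None,
) -> tuple[OccupancyTable, pd.DataFrame]:
    """Evolve per-cluster counts along every branch by Gillespie.

    Along a branch of length L the count performs a birth–death chain:
    gains arrive at rate gamma, each existing copy is lost at rate delta.
    Returns the tip-level :class:`OccupancyTable` and an event log with
    one row per gain/loss (orthogroup, cluster, branch = child node key,
    time within branch, delta). Tip count equals root count + gains -
    losses along the root path, exactly.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    _label_internal_nodes(tree)
    clusters = sorted(root_counts)
    events = []
    rows = []

    def evolve_branch(state: int, length: float, og: str, cluster: str, branch: str) -> int:
        t = 0.0
        while True:
            rate = gain_rate + state * loss_rate
            if rate <= 0:
                return state
            t += rng.exponential(1.0 / rate)
            if t >= length:
                return state
            if rng.random() < gain_rate / rate:
                state += 1
                events.append((og, cluster, branch, t, +1))
            else:
                state -= 1
                events.append((og, cluster, branch, t, -1))

    for og_i in range(n_orthogroups):
        og = f"og{og_i:04d}"
        for cluster in clusters:
            state0 = int(root_counts[cluster])

            def visit(node, state: int) -> None:
                for child in node.child_nodes():
                    bl = child.edge.length or 0.0
                    key = (
                        child.taxon.label if child.is_leaf() else child.label
                    )
                    new_state = evolve_branch(state, bl, og, cluster, key)
                    if child.is_leaf():
                        rows.append((child.taxon.label, og, cluster, new_state))
                    else:
                        visit(child, new_state)

            visit(tree.seed_node, state0)

    counts = pd.DataFrame(rows, columns=["assembly", "orthogroup", "cluster", "count"])
    tips = sorted(counts["assembly"].unique())
    table = OccupancyTable(counts, {t: n_orthogroups for t in tips})
    log = pd.DataFrame(events, columns=["orthogroup", "cluster", "branch", "time", "delta"])
    return table, log


def _label_internal_nodes(tree: dendropy.Tree) -> None:
    i = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"node{i:04d}"
            i += 1


def stationary_mean(gain_rate: float, loss_rate: float) -> float:
    """Mean of the stationary Poisson(gamma/delta) count distribution."""
    if loss_rate <= 0:
        raise ValueError("stationary law requires loss_rate > 0")
    return gain_rate / loss_rate


def stationary_shared_fraction(gain_rate: float, loss_rate: float, max_n: int = 200) -> float:
    """E[min(X, Y)] / E[Y] for independent X, Y ~ Poisson(gamma/delta).

    The sharing level expected between infinitely diverged tips: the
    pooled shared-occupancy ratio (sum of capped minima over sum of
    reference counts) converges to exactly this value, making it the
    analytic asymptote of the decay curve on synthetic data.
    """
    from scipy import stats

    mu = stationary_mean(gain_rate, loss_rate)
    ks = np.arange(max_n + 1)
    pmf = stats.poisson.pmf(ks, mu)
    # E[min(X,Y)] = sum_{t>=0} P(X > t) P(Y > t)
    sf = 1.0 - np.cumsum(pmf)
    e_min = float(np.sum(sf * sf))
    return e_min / mu


# ---------------------------------------------------------------------------
# environmental traits


def simulate_env(
    tree: dendropy.Tree,
    counts: OccupancyTable,
    bm_rate: float,
    effect_map: Mapping[tuple[str, str], tuple[str, float]],
    noise_sd: float,
    rng: np.random.Generator | None = None,
    n_env_pcs: int = 10,
) -> pd.DataFrame:
    """Brownian envPC traits with planted linear effects of motif counts.

    envPC_j(tip) = BM_j(tip) + sum over effects targeting envPC_j of
    beta * count(tip, orthogroup, cluster) + N(0, noise_sd^2).
    """
    from .phylo import simulate_bm

    if rng is None:
        rng = np.random.default_rng(0)
    taxa = sorted(t.taxon.label for t in tree.leaf_node_iter())
    cols = {}
    for j in range(n_env_pcs):
        name = f"envPC{j+1}"
        bm = simulate_bm(tree, rng, rate=bm_rate) if bm_rate > 0 else {t: 0.0 for t in taxa}
        col = np.array([bm[t] for t in taxa])
        for (og, cluster), (target, beta) in effect_map.items():
            if target != name:
                continue
            sub = counts.counts[
                (counts.counts["orthogroup"] == og) & (counts.counts["cluster"] == cluster)
            ].set_index("assembly")["count"]
            col = col + beta * sub.reindex(taxa).fillna(0).values
        col = col + rng.normal(0.0, noise_sd, size=len(taxa))
        cols[name] = col
    return pd.DataFrame(cols, index=pd.Index(taxa, name="assembly"))


# ---------------------------------------------------------------------------
# upstream sequences with embedded instances


def make_synthetic_motifs(
    n_clusters: int,
    width: int = 8,
    rng: np.random.Generator | None = None,
    dominance: float = 0.97,
) -> list[MotifMatrix]:
    """High-information synthetic motifs, one per cluster.

    Each position puts probability ``dominance`` on a random consensus
    base, so the consensus scores far above the default detection
    threshold and planted instances are recoverable by the scanner.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    motifs = []
    for c in range(n_clusters):
        consensus = rng.integers(0, 4, size=width)
        probs = np.full((width, 4), (1 - dominance) / 3)
        probs[np.arange(width), consensus] = dominance
        cluster = f"cluster{c:02d}"
        motifs.append(MotifMatrix(f"SYN{c:03d}", f"synthetic_{c}", probs, cluster))
    return motifs


def simulate_upstream_sequences(
    counts: OccupancyTable,
    motifs: Sequence[MotifMatrix],
    window_bp: int = 500,
    gc_content: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Realize counts as embedded consensus instances on random background.

    Background bases are i.i.d. with the given GC content; for each
    (assembly, orthogroup) region, each cluster's count is embedded as
    that many non-overlapping consensus copies at uniform positions.
    Returns ({region_id: sequence}, embed log with one row per instance).
    Raises when the instances cannot be packed into the window.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    by_cluster = {m.cluster_id: m for m in motifs}
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    log_rows = []
    grouped = counts.counts.groupby(["assembly", "orthogroup"])
    for (asm, og), grp in sorted(grouped, key=lambda kv: kv[0]):
        inserts: list[tuple[str, str]] = []  # (cluster, consensus)
        for _, row in grp.iterrows():
            m = by_cluster.get(row["cluster"])
            if m is None:
                raise ValueError(f"no motif for cluster {row['cluster']!r}")
            inserts.extend([(row["cluster"], m.consensus)] * int(row["count"]))
        total = sum(len(s) for _, s in inserts)
        if total > window_bp:
            raise ValueError(
                f"region {og}|{asm}: {total} bp of instances exceed window {window_bp}"
            )
        background = bases[rng.choice(4, size=window_bp, p=p)]
        order = rng.permutation(len(inserts))
        inserts = [inserts[i] for i in order]
        slack = window_bp - total
        gaps = np.sort(rng.integers(0, slack + 1, size=len(inserts))) if inserts else []
        pos = 0
        placed = []
        for gap_target, (cluster, cons) in zip(gaps, inserts):
            start = gap_target + sum(len(c) for _, c in placed)
            background[start : start + len(cons)] = list(cons)
            placed.append((cluster, cons))
            log_rows.append((asm, og, cluster, start, start + len(cons)))
        seqs[f"{og}|{asm}"] = "".join(background)
    log = pd.DataFrame(log_rows, columns=["assembly", "orthogroup", "cluster", "start", "end"])
    return seqs, log


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(config: SimConfig, with_sequences: bool = False) -> SimOutput:
    """Generate a full coupled dataset under one master seed."""
    seeds = np.random.SeedSequence(config.master_seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in seeds]
    tree = simulate_tree(config.n_taxa, config.birth_rate, config.death_rate, rngs[0])
    root_counts = {f"cluster{c:02d}": config.root_count for c in range(config.n_clusters)}
    counts, events = simulate_motif_counts(
        tree, config.gain_rate, config.loss_rate, root_counts,
        config.n_orthogroups, rngs[1],
    )
    env = simulate_env(
        tree, counts, config.bm_rate, config.effect_map, config.noise_sd,
        rngs[2], config.n_env_pcs,
    )
    sequences = None
    if with_sequences:
        motifs = make_synthetic_motifs(config.n_clusters, config.motif_width, rngs[3])
        sequences, _ = simulate_upstream_sequences(
            counts, motifs, config.window_bp, config.gc_content, rngs[4]
        )
    truth = {
        "effect_map": {f"{og}:{cl}": [pc, beta] for (og, cl), (pc, beta) in
                       config.effect_map.items()},
        "config": {k: v for k, v in vars(config).items() if k != "effect_map"},
    }
    return SimOutput(tree, counts, env, sequences, events, truth)
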