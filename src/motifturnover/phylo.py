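"""Phylogenetic distances, shared-branch-length covariance, permulations.

The taxa x taxa matrix K ("phyloK") holds, for each pair of tips, the
branch length shared on their root-to-tip paths — i.e. the depth of their
most recent common ancestor. Under Brownian-motion trait evolution K is
exactly the trait covariance up to the rate, which is why it serves as
the random-effect covariance in the phylogenetic mixed models.

Permulations combine permutation and simulation: a Brownian trait is
simulated on the tree and the observed trait values are reassigned to
tips by matching observed ranks to simulated ranks, producing a
permutation of the data that retains phylogenetic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .io import tip_labels

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
TRANSVERSIONS_Q = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
TRANSVERSIONS_R = {("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class K81Result:
    """Kimura 3-substitution-type distance components.

    P: transition proportion; Q: A<->T / G<->C transversions;
    R: A<->C / G<->T transversions; d: substitutions per site
    (+inf and saturated=True when a log argument is nonpositive);
    n_sites: pairwise-complete sites compared.
    """

    P: float
    Q: float
    R: float
    d: float
    saturated: bool
    n_sites: int


def k81_distance(seq_a: str, seq_b: str) -> K81Result:
    """K81 distance between two aligned sequences (pairwise deletion).

    d = -1/4 * [ln(1-2P-2Q) + ln(1-2P-2R) + ln(1-2Q-2R)].
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    n = p = q = r = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue  # gaps / ambiguity: pairwise deletion
        n += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            p += 1
        elif (x, y) in TRANSVERSIONS_Q:
            q += 1
        else:
            r += 1
    if n == 0:
        raise ValueError("no pairwise-complete sites")
    P, Q, R = p / n, q / n, r / n
    args = (1 - 2 * P - 2 * Q, 1 - 2 * P - 2 * R, 1 - 2 * Q - 2 * R)
    if min(args) <= 0:
        return K81Result(P, Q, R, np.inf, True, n)
    d = -0.25 * sum(np.log(arg) for arg in args)
    return K81Result(P, Q, R, float(d), False, n)


# ---------------------------------------------------------------------------
# phyloK


def phylo_k(tree: dendropy.Tree, taxa: list[str] | None = None) -> "PhyloK":
    """Shared-branch-length matrix K[i,j] = depth of MRCA(i, j).

    The diagonal is the root-to-tip path length. Computed by a preorder
    pass accumulating node depths, so it is exact for any rooted tree
    with nonnegative branch lengths.
    """
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) < 2:
        raise ValueError("tree must be rooted (root with >= 2 children)")
    labels = tip_labels(tree)
    if taxa is None:
        taxa = sorted(labels)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    K = np.zeros((n, n))

    def visit(node, depth: float) -> list[int]:
        if node.is_leaf():
            i = index.get(node.taxon.label)
            if i is None:
                return []
            K[i, i] = depth
            return [i]
        groups = []
        for child in node.child_nodes():
            groups.append(visit(child, depth + (child.edge.length or 0.0)))
        # tips in different child subtrees have this node as MRCA
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        K[i, j] = K[j, i] = depth
        return [i for g in groups for i in g]

    visit(tree.seed_node, 0.0)
    return PhyloK(K, list(taxa))


@dataclass
class PhyloK:
    """Taxa x taxa shared-branch-length covariance with a fixed taxa order."""

    matrix: np.ndarray
    taxa: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa list")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        if (self.matrix < -1e-12).any():
            raise ValueError("K entries must be nonnegative")

    def subset(self, taxa: list[str]) -> "PhyloK":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloK(self.matrix[np.ix_(idx, idx)], list(taxa))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


# ---------------------------------------------------------------------------
# Brownian simulation and permulation


def simulate_bm(
    tree: dendropy.Tree,
    rng: np.random.Generator,
    rate: float = 1.0,
    root_value: float = 0.0,
) -> dict[str, float]:
    """One Brownian-motion trait realization at the tips.

    Each branch adds an independent N(0, rate * length) increment; the
    root starts at ``root_value``. Traversal order is deterministic
    (preorder, children in tree order) so a seeded rng reproduces draws.
    """
    values: dict[str, float] = {}

    def visit(node, value: float) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            v = value + rng.normal(0.0, np.sqrt(rate * bl)) if bl > 0 else value
            if child.is_leaf():
                values[child.taxon.label] = v
            else:
                visit(child, v)

    visit(tree.seed_node, root_value)
    return values


def permulate_trait(
    tree: dendropy.Tree,
    observed: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Rank-matched Brownian permutation of an observed trait.

    Simulates a BM trait (root 0, rate 1), then assigns the observed
    values to tips so that observed ranks match simulated ranks. The
    output is a permutation of the observed multiset carrying the tree's
    phylogenetic structure. Ties in the simulated draw are broken by tip
    label order (deterministic).
    """
    taxa = sorted(observed)
    sim = simulate_bm(tree, rng)
    missing = [t for t in taxa if t not in sim]
    if missing:
        raise ValueError(f"tips absent from tree: {missing[:5]}")
    sim_values = np.array([sim[t] for t in taxa])
    # argsort is stable, so equal simulated values fall back to label order
    sim_order = np.argsort(sim_values, kind="stable")
    obs_sorted = np.sort(np.array([observed[t] for t in taxa]))
    out = np.empty(len(taxa))
    out[sim_order] = obs_sorted
    return {t: float(v) for t, v in zip(taxa, out)}


def phylogenetic_signal_proxy(
    tree: dendropy.Tree, trait: dict[str, float]
) -> float:
    """Cheap Blomberg's-K-style signal score: tip variance over contrast variance.

    Higher values mean closely related tips have more similar trait
    values. Used to verify that permulated traits retain phylogenetic
    structure relative to uniform permutations; not a calibrated K.
    """
    values = dict(trait)

    contrasts: list[float] = []

    def visit(node) -> tuple[float, float]:
        # returns (value, extra depth) of the node after pruning
        if node.is_leaf():
            return values[node.taxon.label], 0.0
        child_states = []
        for child in node.child_nodes():
            v, extra = visit(child)
            child_states.append((v, (child.edge.length or 0.0) + extra))
        (v1, l1), (v2, l2) = child_states[0], child_states[1]
        l1 = max(l1, 1e-9)
        l2 = max(l2, 1e-9)
        contrasts.append((v1 - v2) / np.sqrt(l1 + l2))
        merged = (v1 / l1 + v2 / l2) / (1 / l1 + 1 / l2)
        extra = l1 * l2 / (l1 + l2)
        for v3, l3 in child_states[2:]:  # polytomies: fold in sequentially
            l3 = max(l3, 1e-9)
            contrasts.append((merged - v3) / np.sqrt(extra + l3))
            merged = (merged / (extra + 1e-9) + v3 / l3) / (1 / (extra + 1e-9) + 1 / l3)
        return merged, extra

    visit(tree.seed_node)
    tip_var = float(np.var(list(values.values())))
    contrast_var = float(np.mean(np.square(contrasts)))
    return tip_var / max(contrast_var, 1e-12)
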