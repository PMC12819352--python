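"""Cross-species environmental association batteries.

Two batteries mirror the two scales of the analysis:

* global models — one phylogenetic mixed model per motif cluster, response
  = the cluster's per-assembly occurrence rate, fixed effects = 10
  environmental PCs + global motif density + 5 mono/dinucleotide
  composition PCs, random effect = phyloK;
* orthogroup models — one model per (motif cluster, orthogroup) pair
  passing the presence filters (motif present in >= 10 taxa at the
  orthogroup; orthogroup present in >= 200 taxa), response = the motif
  count at that orthogroup per assembly, fixed effects = the 10 envPCs.

Wald chi-square(1) tests are computed per envPC term, and
Benjamini–Hochberg FDR is pooled across all envPC terms within each
battery. Non-converged models are excluded from the FDR with a count
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .occupancy import OccupancyTable, global_motif_density, occurrence_rates
from .phylo import PhyloK
from .plmm import KDecomposition, PhyloLMM, bh_fdr

DEFAULT_MIN_MOTIF_TAXA = 10
DEFAULT_MIN_OG_TAXA = 200


@dataclass
class AssociationBattery:
    """Tidy association results plus bookkeeping."""

    results: pd.DataFrame  # model_id, term, beta, se, wald, p, q
    n_models: int
    n_nonconverged: int
    dropped_taxa: list[str]

    def significant(self, alpha: float = 0.01) -> pd.DataFrame:
        return self.results[self.results["q"] < alpha]

    def qq_data(self) -> pd.DataFrame:
        """Sorted observed p-values vs uniform quantiles (for QQ plots)."""
        p = np.sort(self.results["p"].dropna().values)
        n = len(p)
        expected = (np.arange(1, n + 1) - 0.5) / n
        return pd.DataFrame({"expected": expected, "observed": p})


def _align(env: pd.DataFrame, K: PhyloK, extra: pd.DataFrame | None = None):
    """Complete-case taxa present in env (and extra) and K, in K's order."""
    taxa = [t for t in K.taxa if t in env.index and not env.loc[t].isna().any()]
    dropped = [t for t in K.taxa if t not in taxa]
    if extra is not None:
        taxa2 = [t for t in taxa if t in extra.index and not extra.loc[t].isna().any()]
        dropped += [t for t in taxa if t not in taxa2]
        taxa = taxa2
    return taxa, dropped


def run_global_models(
    table: OccupancyTable,
    env: pd.DataFrame,
    K: PhyloK,
    covariates: pd.DataFrame | None = None,
    fdr_pooled: bool = True,
) -> AssociationBattery:
    """One model per motif cluster: occurrence rate ~ envPCs + covariates.

    ``env`` is a taxa x envPC DataFrame (taxa index). ``covariates``
    defaults to the global motif density computed from the table itself;
    pass a wider frame to add composition PCs. FDR is pooled across all
    cluster x envPC terms.
    """
    rates = occurrence_rates(table)
    if covariates is None:
        covariates = pd.DataFrame({"global_density": global_motif_density(table)})
    taxa, dropped = _align(env, K, covariates)
    taxa = [t for t in taxa if t in rates.index]
    if len(taxa) < env.shape[1] + covariates.shape[1] + 3:
        raise ValueError("too few complete-case taxa for the global battery")
    decomp = KDecomposition.from_k(K.subset(taxa))
    env_terms = list(env.columns)
    X = np.column_stack(
        [
            np.ones(len(taxa)),
            env.loc[taxa].values,
            covariates.loc[taxa].values,
        ]
    )
    names = ["Intercept", *env_terms, *covariates.columns]
    rows = []
    n_bad = 0
    for cluster in rates.columns:
        y = rates.loc[taxa, cluster].values
        fit = PhyloLMM(y, X, decomp, names).fit()
        if not fit.converged:
            n_bad += 1
            continue
        wt = fit.wald_tests(env_terms)
        for _, r in wt.iterrows():
            rows.append((str(cluster), r["term"], r["beta"], r["se"], r["wald"], r["p"]))
    out = pd.DataFrame(rows, columns=["model_id", "term", "beta", "se", "wald", "p"])
    out["q"] = bh_fdr(out["p"].values) if (fdr_pooled and len(out)) else np.nan
    return AssociationBattery(out, n_models=rates.shape[1], n_nonconverged=n_bad,
                              dropped_taxa=dropped)


def run_orthogroup_models(
    table: OccupancyTable,
    env: pd.DataFrame,
    K: PhyloK,
    min_motif_taxa: int = DEFAULT_MIN_MOTIF_TAXA,
    min_og_taxa: int = DEFAULT_MIN_OG_TAXA,
) -> AssociationBattery:
    """One model per (cluster, orthogroup) pair: motif count ~ envPCs.

    Pairs are filtered to motifs present (count > 0) in at least
    ``min_motif_taxa`` taxa at the orthogroup and orthogroups present in
    at least ``min_og_taxa`` taxa. FDR is pooled across all emitted envPC
    terms; non-converged models are excluded and counted.
    """
    taxa_all, dropped = _align(env, K)
    taxa_set = set(taxa_all)
    env_terms = list(env.columns)
    counts = table.counts
    present = counts[counts["count"] > 0]
    og_taxa = (
        counts.groupby("orthogroup")["assembly"]
        .agg(lambda s: len(set(s) & taxa_set))
    )
    eligible_ogs = set(og_taxa[og_taxa >= min_og_taxa].index)
    motif_taxa = (
        present.groupby(["orthogroup", "cluster"])["assembly"]
        .agg(lambda s: len(set(s) & taxa_set))
    )
    decomp_cache: dict[tuple, KDecomposition] = {}
    rows = []
    n_models = 0
    n_bad = 0
    for og in sorted(eligible_ogs):
        og_counts = counts[counts["orthogroup"] == og]
        og_assemblies = sorted(set(og_counts["assembly"]) & taxa_set)
        key = tuple(og_assemblies)
        if key not in decomp_cache:
            decomp_cache[key] = KDecomposition.from_k(K.subset(og_assemblies))
        decomp = decomp_cache[key]
        X = np.column_stack([np.ones(len(og_assemblies)), env.loc[og_assemblies].values])
        names = ["Intercept", *env_terms]
        pivot = og_counts.pivot_table(
            index="assembly", columns="cluster", values="count", aggfunc="sum", fill_value=0
        ).reindex(og_assemblies, fill_value=0)
        for cluster in pivot.columns:
            if motif_taxa.get((og, cluster), 0) < min_motif_taxa:
                continue
            n_models += 1
            y = pivot[cluster].values.astype(float)
            fit = PhyloLMM(y, X, decomp, names).fit()
            if not fit.converged:
                n_bad += 1
                continue
            wt = fit.wald_tests(env_terms)
            model_id = f"{cluster}:{og}"
            for _, r in wt.iterrows():
                rows.append((model_id, r["term"], r["beta"], r["se"], r["wald"], r["p"]))
    out = pd.DataFrame(rows, columns=["model_id", "term", "beta", "se", "wald", "p"])
    out["q"] = bh_fdr(out["p"].values) if len(out) else np.nan
    return AssociationBattery(out, n_models=n_models, n_nonconverged=n_bad,
                              dropped_taxa=dropped)


# ---------------------------------------------------------------------------
# composition covariates


def dinuc_covariate_pcs(
    seqs_by_assembly: Mapping[str, Sequence[str]],
    n_axes: int = 5,
) -> pd.DataFrame:
    """Mono+dinucleotide composition PCs from background sequences.

    Per assembly, the 4 mononucleotide and 16 dinucleotide frequencies
    (each block summing to 1) are concatenated, centered across
    assemblies, and decomposed by SVD; the first ``n_axes`` principal
    axes are returned with a deterministic sign convention (the
    largest-magnitude loading on each axis is positive). Assemblies with
    no background sequences are dropped. If the compositions carry no
    variance, the axes are all zero.
    """
    bases = "ACGT"
    dinucs = [a + b for a in bases for b in bases]
    rows = {}
    for asm, seqs in sorted(seqs_by_assembly.items()):
        mono = np.zeros(4)
        di = np.zeros(16)
        for seq in seqs:
            s = seq.upper()
            for i, b in enumerate(bases):
                mono[i] += s.count(b)
            for j, d in enumerate(dinucs):
                di[j] += _count_overlapping(s, d)
        if mono.sum() == 0:
            continue  # no background sequences: dropped
        mono /= mono.sum()
        if di.sum() > 0:
            di /= di.sum()
        rows[asm] = np.concatenate([mono, di])
    if not rows:
        raise ValueError("no assembly has background sequences")
    mat = pd.DataFrame(rows).T
    centered = mat - mat.mean(axis=0)
    if np.allclose(centered.values, 0):
        out = pd.DataFrame(
            np.zeros((len(mat), n_axes)),
            index=mat.index,
            columns=[f"compPC{i+1}" for i in range(n_axes)],
        )
        return out
    U, S, Vt = np.linalg.svd(centered.values, full_matrices=False)
    k = min(n_axes, len(S))
    scores = U[:, :k] * S[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            scores[:, j] *= -1
    out = np.zeros((len(mat), n_axes))
    out[:, :k] = scores
    return pd.DataFrame(
        out, index=mat.index, columns=[f"compPC{i+1}" for i in range(n_axes)]
    )


def _count_overlapping(s: str, sub: str) -> int:
    count = start = 0
    while True:
        idx = s.find(sub, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1
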