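"""Shared motif occupancy, occurrence statistics, and the decay fit.

Shared occupancy of a target assembly relative to a reference is the
capped-minimum fraction of the reference's motif-cluster instances also
present at the target's orthologous upstream window:

    s_m = min(n_target_m, n_ref_m) / n_ref_m           (per cluster)
    S_g = sum_m min(n_target_m, n_ref_m) / sum_m n_ref_m   (per orthogroup)

Clusters absent from the reference are ignored entirely (turnover is
measured with respect to the reference's instances only). A target count
exceeding the reference contributes exactly the reference count, so all
fractions live in [0, 1]. The decline of mean shared occupancy with
divergence is summarized by a three-parameter exponential decay
y = a*exp(-b*x) + c fitted by nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class OccupancyTable:
    """Motif-cluster instance counts per (assembly, orthogroup).

    ``counts`` is a tidy DataFrame with columns assembly, orthogroup,
    cluster, count; ``regions_per_assembly`` gives the number of upstream
    windows that passed extraction filters for each assembly (the
    denominator of occurrence rates).
    """

    counts: pd.DataFrame
    regions_per_assembly: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"assembly", "orthogroup", "cluster", "count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"counts table missing columns: {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.regions_per_assembly:
            self.regions_per_assembly = (
                self.counts.groupby("assembly")["orthogroup"].nunique().to_dict()
            )

    @property
    def assemblies(self) -> list[str]:
        return sorted(self.counts["assembly"].unique())

    @property
    def clusters(self) -> list[str]:
        return sorted(self.counts["cluster"].unique())

    def orthogroup_counts(self, assembly: str, orthogroup: str) -> dict[str, int]:
        sub = self.counts[
            (self.counts["assembly"] == assembly)
            & (self.counts["orthogroup"] == orthogroup)
        ]
        return dict(zip(sub["cluster"], sub["count"]))

    def pivot(self, assembly: str) -> pd.DataFrame:
        """orthogroup x cluster count matrix for one assembly (missing -> 0)."""
        sub = self.counts[self.counts["assembly"] == assembly]
        return sub.pivot_table(
            index="orthogroup", columns="cluster", values="count",
            aggfunc="sum", fill_value=0,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, regions: Mapping[str, int] | None = None):
        df = pd.read_csv(path, sep="\t")
        return cls(df, dict(regions) if regions else {})


# ---------------------------------------------------------------------------
# occurrence statistics


def occurrence_rate(table: OccupancyTable, assembly: str, cluster: str) -> float:
    """Instances of one cluster per upstream region in one assembly."""
    n_regions = table.regions_per_assembly.get(assembly, 0)
    if n_regions <= 0:
        raise ValueError(f"assembly {assembly!r} has no upstream regions")
    sub = table.counts[
        (table.counts["assembly"] == assembly) & (table.counts["cluster"] == cluster)
    ]
    return float(sub["count"].sum()) / n_regions


def occurrence_rates(table: OccupancyTable) -> pd.DataFrame:
    """assembly x cluster occurrence-rate matrix (instances per region)."""
    totals = table.counts.pivot_table(
        index="assembly", columns="cluster", values="count", aggfunc="sum", fill_value=0
    )
    regions = pd.Series(table.regions_per_assembly).reindex(totals.index)
    if (regions <= 0).any() or regions.isna().any():
        raise ValueError("every assembly needs a positive region count")
    return totals.div(regions, axis=0)


def global_motif_density(table: OccupancyTable) -> pd.Series:
    """Per-assembly sum of all per-cluster occurrence rates."""
    return occurrence_rates(table).sum(axis=1)


def occurrence_summary(table: OccupancyTable) -> pd.DataFrame:
    """Median rate and coefficient of variation per cluster across assemblies.

    CV uses the sample (n-1) standard deviation and is undefined (NaN)
    when the mean rate is 0. Requires >= 2 assemblies.
    """
    rates = occurrence_rates(table)
    if rates.shape[0] < 2:
        raise ValueError("need >= 2 assemblies for occurrence summaries")
    med = rates.median(axis=0)
    mean = rates.mean(axis=0)
    sd = rates.std(axis=0, ddof=1)
    cv = sd / mean.where(mean > 0)
    return pd.DataFrame({"median_rate": med, "cv": cv})


# ---------------------------------------------------------------------------
# shared occupancy


@dataclass
class SharedOccupancy:
    """Shared-occupancy fractions of one target orthogroup vs the reference."""

    per_motif: dict[str, float]
    shared_count: int
    ref_total: int

    @property
    def fraction(self) -> float:
        return self.shared_count / self.ref_total

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def shared_occupancy_orthogroup(
    target_counts: Mapping[str, int], ref_counts: Mapping[str, int]
) -> SharedOccupancy:
    """Capped-minimum shared occupancy for one orthogroup.

    Clusters with zero (or absent) reference count are excluded from both
    numerator and denominator. Raises ``ValueError`` when no reference
    cluster has a positive count.
    """
    per_motif: dict[str, float] = {}
    shared = 0
    ref_total = 0
    for cluster, n_ref in ref_counts.items():
        if n_ref <= 0:
            continue
        n_t = int(target_counts.get(cluster, 0))
        capped = min(n_t, int(n_ref))
        per_motif[cluster] = capped / n_ref
        shared += capped
        ref_total += int(n_ref)
    if ref_total == 0:
        raise ValueError("all reference counts are zero; orthogroup excluded")
    return SharedOccupancy(per_motif, shared, ref_total)


def local_shared_occupancy(
    table: OccupancyTable, ref_assembly: str
) -> pd.DataFrame:
    """S_g for every (target assembly, orthogroup) sharing the reference.

    Tidy output: assembly, orthogroup, shared, ref_total, fraction.
    Orthogroups with zero total reference count are excluded.
    """
    ref = table.pivot(ref_assembly)
    ref_tot = ref.sum(axis=1)
    ref = ref.loc[ref_tot > 0]
    rows = []
    for asm in table.assemblies:
        if asm == ref_assembly:
            continue
        tgt = table.pivot(asm)
        common = ref.index.intersection(tgt.index)
        if common.empty:
            continue
        r = ref.loc[common]
        t = tgt.loc[common].reindex(columns=ref.columns, fill_value=0)
        capped = np.minimum(t.values, r.values)
        shared = capped.sum(axis=1)
        totals = r.values.sum(axis=1)
        for og, s, tot in zip(common, shared, totals):
            rows.append((asm, og, int(s), int(tot), s / tot))
    return pd.DataFrame(
        rows, columns=["assembly", "orthogroup", "shared", "ref_total", "fraction"]
    )


def global_shared_occupancy(
    table: OccupancyTable, ref_assembly: str
) -> pd.DataFrame:
    """Per-assembly mean S_g (unweighted over orthogroups) and pooled ratio.

    Columns: assembly, mean_fraction, pooled_fraction, n_orthogroups.
    Raises when a target assembly shares no orthogroup with the reference.
    """
    if ref_assembly not in table.assemblies:
        raise ValueError(f"reference assembly {ref_assembly!r} absent from table")
    local = local_shared_occupancy(table, ref_assembly)
    if local.empty:
        raise ValueError("no orthogroups shared with the reference")
    grp = local.groupby("assembly")
    out = pd.DataFrame(
        {
            "mean_fraction": grp["fraction"].mean(),
            "pooled_fraction": grp["shared"].sum() / grp["ref_total"].sum(),
            "n_orthogroups": grp.size(),
        }
    ).reset_index()
    return out


def random_pair_baseline(
    table: OccupancyTable,
    ref_assembly: str,
    n_pairs: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean S_g over random non-orthologous gene pairs within the reference.

    Samples ordered pairs (g1 != g2) uniformly with replacement across
    pairs; g1 plays the target, g2 the reference. The value is the
    asymptote-like sharing level expected between unrelated genes.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ref = table.pivot(ref_assembly)
    ref = ref.loc[ref.sum(axis=1) > 0]
    n = ref.shape[0]
    if n < 2:
        raise ValueError("need >= 2 reference orthogroups with counts")
    mat = ref.values
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # g1 != g2, uniform over ordered pairs
    capped = np.minimum(mat[i], mat[j]).sum(axis=1)
    totals = mat[j].sum(axis=1)
    return float(np.mean(capped / totals))


# ---------------------------------------------------------------------------
# exponential decay fit (Model / Results)


@dataclass
class DecayFitResults:
    """Fitted y = a*exp(-b*x) + c with least-squares diagnostics."""

    a: float
    b: float
    c: float
    rss: float
    converged: bool
    flat: bool
    n_obs: int

    @property
    def params(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * np.exp(-self.b * x) + self.c

    def summary(self) -> str:
        lines = [
            "Exponential decay fit: y = a*exp(-b*x) + c",
            f"  n_obs      {self.n_obs}",
            f"  a          {self.a:.6g}",
            f"  b          {self.b:.6g}",
            f"  c          {self.c:.6g}   (asymptote)",
            f"  rss        {self.rss:.6g}",
            f"  converged  {self.converged}",
        ]
        if self.flat:
            lines.append("  note: data are flat; b is unidentified")
        return "\n".join(lines)


class ExponentialDecay:
    """Nonlinear least-squares model for shared occupancy vs divergence.

    Initialization: a0 = max(y) - min(y), c0 = min(y), b0 from a
    log-linear regression of (y - c0); bounds b >= 0 and c in [0, 1].
    """

    def __init__(self, x: Sequence[float], y: Sequence[float]):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and of equal length")
        if len(self.x) < 4:
            raise ValueError("need >= 4 points to fit a 3-parameter decay")
        if np.any(self.x < 0):
            raise ValueError("distances must be nonnegative")
        if np.ptp(self.x) == 0:
            raise ValueError("x is degenerate (single distance value)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str = "distance", y: str = "fraction"):
        return cls(df[x].values, df[y].values)

    @staticmethod
    def _model(x, a, b, c):
        return a * np.exp(-b * x) + c

    def fit(self, maxfev: int = 10_000) -> DecayFitResults:
        x, y = self.x, self.y
        span = float(np.ptp(y))
        flat = span < 1e-12
        if flat:
            c = float(np.mean(y))
            return DecayFitResults(0.0, 0.0, min(max(c, 0.0), 1.0), float(np.sum((y - c) ** 2)),
                                   True, True, len(y))
        a0 = span
        c0 = float(np.min(y))
        b0 = self._init_rate(x, y, c0, a0)
        lower = [-1.5, 0.0, 0.0]
        upper = [1.5, np.inf, 1.0]
        p0 = [a0, b0, min(max(c0, 0.0), 1.0)]
        try:
            popt, _ = optimize.curve_fit(
                self._model, x, y, p0=p0, bounds=(lower, upper), maxfev=maxfev
            )
            converged = True
        except RuntimeError:
            popt, converged = np.array(p0), False
        rss = float(np.sum((y - self._model(x, *popt)) ** 2))
        return DecayFitResults(*map(float, popt), rss, converged, False, len(y))

    @staticmethod
    def _init_rate(x, y, c0, a0) -> float:
        resid = y - c0 + 1e-6 * a0
        mask = resid > 0
        if mask.sum() < 2:
            return 1.0
        slope = np.polyfit(x[mask], np.log(resid[mask]), 1)[0]
        return float(max(-slope, 1e-6))


def fit_decay(x: Sequence[float], y: Sequence[float]) -> DecayFitResults:
    """Convenience wrapper: fit y = a*exp(-b*x) + c."""
    return ExponentialDecay(x, y).fit()


# ---------------------------------------------------------------------------
# quartiles and group comparison


def quartile_classes(
    mean_fraction: Mapping[str, float],
    taxa_counts: Mapping[str, int],
    min_taxa: int = 200,
) -> tuple[set[str], set[str]]:
    """Top- and bottom-quartile orthogroup sets by mean shared occupancy.

    Orthogroups observed in fewer than ``min_taxa`` taxa are excluded
    first. Ties at either quartile boundary go to the more extreme class
    (>= 75th percentile is top, <= 25th percentile is bottom), which makes
    the classification deterministic and idempotent.
    """
    eligible = {
        og: f for og, f in mean_fraction.items() if taxa_counts.get(og, 0) >= min_taxa
    }
    if len(eligible) < 4:
        raise ValueError(f"need >= 4 eligible orthogroups, have {len(eligible)}")
    values = np.array(list(eligible.values()))
    q1, q3 = np.quantile(values, [0.25, 0.75])
    top = {og for og, f in eligible.items() if f >= q3}
    bottom = {og for og, f in eligible.items() if f <= q1}
    return top, bottom


def ks_compare(group_a: Sequence[float], group_b: Sequence[float]):
    """Asymptotic two-sample Kolmogorov–Smirnov test (D, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
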