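"""Phylogenetic linear mixed models by REML, with Wald tests and permulations.

Model:  y = X beta + u + e,  u ~ N(0, sigma2_phylo * K),  e ~ N(0, sigma2_resid * I)

with K the shared-branch-length ("phyloK") covariance. Estimation follows
the EMMA/FaST-LMM scheme: a single spectral decomposition of K rotates the
model to independent errors with variances (lambda * s_i + 1), where
lambda = sigma2_phylo / sigma2_resid and s_i are eigenvalues of K. The
restricted likelihood is profiled over lambda on a log grid (1e-5..1e5,
100 points) and refined by golden-section search; beta and its standard
errors come from GLS at the optimum. The decomposition is computed once
per taxa set and reused across models, which is what makes batteries of
hundreds of thousands of models tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import PhyloK, permulate_trait

_LAMBDA_GRID = np.logspace(-5, 5, 100)
_RIDGE = 1e-8


@dataclass
class KDecomposition:
    """Reusable spectral decomposition of a phyloK matrix (plus ridge)."""

    taxa: list[str]
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @classmethod
    def from_k(cls, K: PhyloK | np.ndarray, taxa: list[str] | None = None):
        if isinstance(K, PhyloK):
            mat, taxa = K.matrix, K.taxa
        else:
            mat = np.asarray(K, dtype=float)
            if taxa is None:
                taxa = [str(i) for i in range(mat.shape[0])]
        scale = float(np.mean(np.diag(mat))) or 1.0
        mat = mat + _RIDGE * scale * np.eye(mat.shape[0])
        s, U = np.linalg.eigh(mat)
        if s[0] < -1e-6 * scale:
            raise ValueError(f"K is not positive semidefinite (min eigenvalue {s[0]:.3g})")
        s = np.clip(s, 0.0, None)
        return cls(list(taxa), s, U)

    def rotate(self, arr: np.ndarray) -> np.ndarray:
        return self.eigenvectors.T @ arr


class PhyloLMM:
    """Phylogenetic linear mixed model for one response vector.

    Parameters
    ----------
    endog : response values, one per taxon.
    exog : fixed-effect design matrix (include the intercept explicitly or
        use :meth:`from_dataframe`, which prepends one).
    K : a :class:`~motifturnover.phylo.PhyloK`, a raw covariance matrix, or
        a precomputed :class:`KDecomposition` to share across models.
    exog_names : column labels for the summary table.

    Collinear columns are dropped (QR with column pivoting) and reported on
    the results object.
    """

    def __init__(
        self,
        endog: Sequence[float],
        exog: np.ndarray,
        K: PhyloK | KDecomposition | np.ndarray,
        exog_names: Sequence[str] | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        n = self.endog.shape[0]
        if exog.shape[0] != n:
            raise ValueError("endog and exog disagree on the number of taxa")
        if isinstance(K, KDecomposition):
            self.decomposition = K
        else:
            self.decomposition = KDecomposition.from_k(K)
        if len(self.decomposition.taxa) != n:
            raise ValueError("K dimension does not match the number of observations")
        names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(exog.shape[1])
        ]
        keep, dropped = _independent_columns(exog)
        self.exog = exog[:, keep]
        self.exog_names = [names[j] for j in keep]
        self.dropped_columns = [names[j] for j in dropped]
        if self.exog.shape[1] >= n:
            raise ValueError("more fixed-effect columns than observations")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        predictors: Sequence[str],
        K: PhyloK | KDecomposition,
        add_intercept: bool = True,
    ) -> "PhyloLMM":
        """Build a model from a taxa-indexed DataFrame, aligning rows to K.

        Rows with missing response or predictors are dropped (complete
        case); K is subset accordingly.
        """
        taxa_order = K.taxa if isinstance(K, (PhyloK, KDecomposition)) else list(data.index)
        cols = [response, *predictors]
        sub = data.loc[[t for t in taxa_order if t in data.index], cols].dropna()
        if isinstance(K, KDecomposition):
            if list(sub.index) != K.taxa:
                raise ValueError(
                    "precomputed decomposition requires complete data in K's taxa order"
                )
            kk = K
        else:
            kk = K.subset(list(sub.index))
        X = sub[list(predictors)].values
        names = list(predictors)
        if add_intercept:
            X = np.column_stack([np.ones(len(sub)), X])
            names = ["Intercept", *names]
        return cls(sub[response].values, X, kk, names)

    # -- restricted likelihood profile -------------------------------------

    def _profile(self, lams: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> np.ndarray:
        """REML log-likelihood (up to an additive constant) per lambda."""
        s = self.decomposition.eigenvalues
        n, p = Xr.shape
        w = lams[:, None] * s[None, :] + 1.0  # (G, n)
        Xw = Xr[None, :, :] / w[:, :, None]
        XtWX = np.einsum("np,gnq->gpq", Xr, Xw)
        XtWy = np.einsum("gnp,n->gp", Xw, yr)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
        resid = yr[None, :] - np.einsum("np,gp->gn", Xr, beta)
        rss = np.einsum("gn,gn->g", resid, resid / w)
        sigma2 = np.maximum(rss / (n - p), 1e-300)
        sign, logdet = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * np.log(sigma2)
            + np.log(w).sum(axis=1)
            + logdet
            + (n - p)
        )
        ll[sign <= 0] = -np.inf
        return ll

    def fit(self, n_golden: int = 40) -> "PhyloLMMResults":
        """Maximize the restricted likelihood over lambda and solve GLS."""
        yr = self.decomposition.rotate(self.endog)
        Xr = self.decomposition.rotate(self.exog)
        grid = _LAMBDA_GRID
        ll = self._profile(grid, yr, Xr)
        best = int(np.argmax(ll))
        converged = bool(np.isfinite(ll[best]))
        lo = np.log10(grid[max(best - 1, 0)])
        hi = np.log10(grid[min(best + 1, len(grid) - 1)])
        lam = _golden_section(
            lambda lg: float(self._profile(np.array([10.0**lg]), yr, Xr)[0]),
            lo, hi, n_golden,
        )
        # boundary handling: an optimum pinned at the grid edge means the
        # variance ratio is effectively 0 or unbounded; still well-defined
        at_edge = best in (0, len(grid) - 1)
        if at_edge:
            lam = grid[best]
        return self._solve_at(lam, yr, Xr, converged=converged)

    def _solve_at(self, lam: float, yr=None, Xr=None, converged: bool = True):
        if yr is None:
            yr = self.decomposition.rotate(self.endog)
            Xr = self.decomposition.rotate(self.exog)
        s = self.decomposition.eigenvalues
        n, p = Xr.shape
        w = lam * s + 1.0
        Xw = Xr / w[:, None]
        XtWX = Xr.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
        resid = yr - Xr @ beta
        sigma2_resid = float(resid @ (resid / w)) / (n - p)
        cov = np.linalg.inv(XtWX) * sigma2_resid
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        ll = float(self._profile(np.array([lam]), yr, Xr)[0])
        return PhyloLMMResults(
            model=self,
            params=beta,
            bse=se,
            cov_params=cov,
            sigma2_phylo=lam * sigma2_resid,
            sigma2_resid=sigma2_resid,
            reml_loglik=ll,
            converged=converged,
            nobs=n,
        )


@dataclass
class PhyloLMMResults:
    """REML estimates, uncertainties, and Wald tests for a PhyloLMM fit."""

    model: PhyloLMM
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    sigma2_phylo: float
    sigma2_resid: float
    reml_loglik: float
    converged: bool
    nobs: int

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def heritability(self) -> float:
        """sigma2_phylo / (sigma2_phylo + sigma2_resid)."""
        total = self.sigma2_phylo + self.sigma2_resid
        return self.sigma2_phylo / total if total > 0 else 0.0

    @property
    def wald_stats(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.square(self.params / self.bse)

    @property
    def pvalues(self) -> np.ndarray:
        return stats.chi2.sf(self.wald_stats, df=1)

    def wald_tests(self, terms: Sequence[str] | None = None) -> pd.DataFrame:
        """Wald chi-square(1) tests for the requested fixed-effect terms."""
        names = self.exog_names
        if terms is None:
            terms = names
        rows = []
        for term in terms:
            if term not in names:
                rows.append((term, np.nan, np.nan, np.nan, np.nan, "dropped"))
                continue
            j = names.index(term)
            if self.bse[j] <= 0 or not np.isfinite(self.bse[j]):
                rows.append((term, self.params[j], self.bse[j], np.nan, np.nan, "inestimable"))
                continue
            w = float(self.wald_stats[j])
            rows.append((term, self.params[j], self.bse[j], w,
                         float(stats.chi2.sf(w, 1)), "ok"))
        return pd.DataFrame(rows, columns=["term", "beta", "se", "wald", "p", "status"])

    def summary(self) -> str:
        lines = [
            "Phylogenetic linear mixed model (REML)",
            "=" * 62,
            f"No. observations: {self.nobs}    REML loglik: {self.reml_loglik:.3f}",
            f"sigma2_phylo: {self.sigma2_phylo:.5g}    sigma2_resid: {self.sigma2_resid:.5g}",
            f"heritability (phylo fraction): {self.heritability:.3f}"
            f"    converged: {self.converged}",
            "-" * 62,
            f"{'term':<20}{'coef':>12}{'std err':>12}{'wald':>9}{'P>chi2':>9}",
        ]
        for name, b, se, w, p in zip(
            self.exog_names, self.params, self.bse, self.wald_stats, self.pvalues
        ):
            lines.append(f"{name:<20}{b:>12.4f}{se:>12.4f}{w:>9.2f}{p:>9.3g}")
        if self.model.dropped_columns:
            lines.append(f"dropped (collinear): {', '.join(self.model.dropped_columns)}")
        lines.append("=" * 62)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permulations


@dataclass
class PermulationResult:
    """Empirical null comparison for one focal fixed-effect term."""

    observed_stat: float
    null_stats: np.ndarray
    n_nonconverged: int
    flagged: bool

    @property
    def n_perm(self) -> int:
        return len(self.null_stats)

    @property
    def p_empirical(self) -> float:
        return (1 + int(np.sum(self.null_stats >= self.observed_stat))) / (
            self.n_perm + 1
        )


def permulation_pvalue(
    model: PhyloLMM,
    focal: str,
    tree,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    max_nonconverged_frac: float = 0.1,
) -> PermulationResult:
    """Permulation null for one term: refit with the focal column permulated.

    Each replicate replaces only the focal column with a rank-matched
    Brownian permutation of its observed values (other columns held
    fixed), refits the model, and records the Wald statistic. The
    empirical p uses the add-one correction. The result is flagged when
    more than ``max_nonconverged_frac`` of refits fail to converge.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if focal not in model.exog_names:
        raise ValueError(f"focal term {focal!r} not in the model")
    j = model.exog_names.index(focal)
    fit = model.fit()
    if not fit.converged:
        raise ValueError("observed-data fit did not converge")
    observed_stat = float(fit.wald_stats[j])
    taxa = model.decomposition.taxa
    observed_col = {t: v for t, v in zip(taxa, model.exog[:, j])}
    null_stats = np.empty(n_perm)
    n_bad = 0
    for r in range(n_perm):
        perm = permulate_trait(tree, observed_col, rng)
        X = model.exog.copy()
        X[:, j] = [perm[t] for t in taxa]
        sub = PhyloLMM(model.endog, X, model.decomposition, model.exog_names)
        res = sub.fit()
        if not res.converged:
            n_bad += 1
        null_stats[r] = res.wald_stats[sub.exog_names.index(focal)]
    return PermulationResult(
        observed_stat,
        null_stats,
        n_bad,
        flagged=n_bad > max_nonconverged_frac * n_perm,
    )


# ---------------------------------------------------------------------------
# helpers


def _independent_columns(X: np.ndarray, tol: float = 1e-8):
    """Greedy left-to-right maximal independent column subset.

    Earlier columns win over later collinear ones, so the intercept and
    leading envPC terms are never the ones reported as dropped.
    """
    keep: list[int] = []
    dropped: list[int] = []
    Q: list[np.ndarray] = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        for q in Q:
            v = v - (q @ X[:, j]) * q
        if np.linalg.norm(v) > tol * max(norm0, 1.0):
            Q.append(v / np.linalg.norm(v))
            keep.append(j)
        else:
            dropped.append(j)
    return keep, dropped


def _golden_section(f, lo: float, hi: float, n_iter: int) -> float:
    """Maximize f on [lo, hi] (log10-lambda space); returns 10**argmax."""
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(n_iter):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    mid = (a + b) / 2
    return float(10.0**mid)
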