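"""Pedigree-based linear mixed model, Wald tests, and the genome scans.

Model per individual ``i``:

    y_i = mu + b1 * c1_i + b2 * c2_i + a_i + e_i

with polygenic effects ``a ~ N(0, A sigma_a^2)`` (``A`` the numerator
relationship matrix restricted to the phenotyped individuals) and residuals
``e ~ N(0, I sigma_e^2)``.  Variance components are estimated by REML.

Writing ``V = sigma_e^2 (lambda A + I)`` with ``lambda = sigma_a^2 /
sigma_e^2``, one spectral decomposition ``A = U S U'`` per dataset rotates
the model to independent observations, after which the restricted
log-likelihood is profiled over ``sigma_e^2`` and optimized over the ratio
by a bounded scalar search.  This is the standard efficient exact-REML
strategy for single-kinship models and makes per-SNP refitting cheap.

Fixed haplotype effects are tested with a Wald chi-square:
``b' V_b^{-1} b`` with ``f`` = number of free coefficients (1 for a
bisection, 2 for a trisection).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, FitError
from .genealogy import (
    FactorClustering,
    build_perfect_phylogeny,
    counts_matrix,
    extract_factors,
    maximal_compatible_interval,
    pairwise_compatibility,
)
from .haplotypes import HaplotypeMatrix
from .pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "VarianceComponents",
    "LMMFit",
    "WaldResult",
    "REMLSolver",
    "reml_fit",
    "wald_test",
    "ScanResult",
    "genmix_scan",
    "mma_scan",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ScanConfig:
    """Knobs shared by the GENMIX and single-SNP (MMA) scans."""

    maf_threshold: float = 0.05
    min_group_copies: int = 4
    reml_tolerance: float = 1e-8
    p3d: bool = False  # estimate the variance ratio once under the null, reuse
    alpha: float = 0.05


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float

    @property
    def heritability(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


@dataclass
class LMMFit:
    """REML fit of the mixed model for one fixed-effect design."""

    beta: np.ndarray  # all fixed coefficients, intercept first
    cov_beta: np.ndarray  # estimation variance-covariance of beta
    vc: VarianceComponents
    restricted_loglik: float
    ratio: float  # sigma_a^2 / sigma_e^2 at the optimum
    ratio_identifiable: bool
    n: int = 0
    column_names: tuple = ()

    @property
    def mu_hat(self) -> float:
        return float(self.beta[0])


@dataclass
class WaldResult:
    statistic: float
    df: int
    p: float
    skipped: Optional[str] = None


class REMLSolver:
    """Exact REML for one kinship matrix, reusable across designs.

    The eigendecomposition of ``A`` is computed once; each :meth:`fit`
    rotates its design and runs a bounded scalar optimization of the
    restricted log-likelihood over ``log(lambda)``.
    """

    def __init__(
        self,
        A: np.ndarray,
        tol: float = 1e-8,
        ratio_bounds: tuple[float, float] = (1e-6, 1e6),
    ):
        A = np.asarray(A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise FitError("kinship matrix must be square")
        w, U = np.linalg.eigh(A)
        if w[0] < -1e-6 * max(1.0, w[-1]):
            raise FitError("kinship matrix is not positive semi-definite")
        self.eigenvalues = np.clip(w, 0.0, None)
        self.U = U
        self.n = A.shape[0]
        self.tol = tol
        self.log_bounds = (math.log(ratio_bounds[0]), math.log(ratio_bounds[1]))

    def rotate(self, M: np.ndarray) -> np.ndarray:
        """Rotate a vector/matrix into the eigenbasis of ``A``."""
        return self.U.T @ M

    def _profile(self, lam: float, yt: np.ndarray, Xt: np.ndarray):
        """Profiled REML pieces at variance ratio ``lam``.

        Returns (-2 restricted loglik, sigma2_e, beta, XtDiX) or None when
        the design is numerically singular at this ratio.
        """
        n, p = Xt.shape
        d = lam * self.eigenvalues + 1.0
        Xd = Xt / d[:, None]
        XtDiX = Xd.T @ Xt
        XtDiy = Xd.T @ yt
        try:
            c = np.linalg.cholesky(XtDiX)
        except np.linalg.LinAlgError:
            return None
        beta = np.linalg.solve(XtDiX, XtDiy)
        rss = float(yt @ (yt / d) - XtDiy @ beta)
        rss = max(rss, 1e-300)
        sigma2_e = rss / (n - p)
        logdet_xvx = 2.0 * float(np.log(np.diag(c)).sum())
        neg2ll = (
            (n - p) * (_LOG2PI + math.log(sigma2_e) + 1.0)
            + float(np.log(d).sum())
            + logdet_xvx
        )
        return neg2ll, sigma2_e, beta, XtDiX

    def fit(
        self,
        y: np.ndarray,
        X: np.ndarray,
        fixed_ratio: Optional[float] = None,
        rotated: bool = False,
        column_names: Sequence[str] = (),
    ) -> LMMFit:
        """REML fit for response ``y`` and fixed design ``X``.

        ``fixed_ratio`` skips the ratio search (0 gives the ordinary
        least-squares limit ``sigma_a^2 = 0``).  With ``rotated=True`` the
        inputs are taken to be already in the eigenbasis.
        """
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.n or y.shape[0] != self.n:
            raise FitError("design/response dimension does not match kinship")
        n, p = X.shape
        if n - p < 1:
            raise FitError("fewer observations than fixed effects")
        if np.linalg.matrix_rank(X) < p:
            raise FitError(_describe_aliasing(X, column_names))
        yt = y if rotated else self.rotate(y)
        Xt = X if rotated else self.rotate(X)

        lo, hi = self.log_bounds
        if fixed_ratio is not None:
            lam_opt = float(fixed_ratio)
            identifiable = True
        else:
            def objective(loglam: float) -> float:
                out = self._profile(math.exp(loglam), yt, Xt)
                return math.inf if out is None else out[0]

            res = optimize.minimize_scalar(
                objective,
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": self.tol},
            )
            lam_opt = math.exp(res.x)
            # flat-profile detection (e.g. A = I): the ratio is then
            # unidentifiable although the total variance still is
            f_opt = res.fun
            spread = max(abs(objective(lo) - f_opt), abs(objective(hi) - f_opt))
            identifiable = spread > 1e-6 * (1.0 + abs(f_opt))

        out = self._profile(lam_opt, yt, Xt)
        if out is None:
            raise FitError(_describe_aliasing(X, column_names))
        neg2ll, sigma2_e, beta, XtDiX = out
        sigma2_a = lam_opt * sigma2_e
        cov_beta = sigma2_e * np.linalg.inv(XtDiX)
        return LMMFit(
            beta=beta,
            cov_beta=cov_beta,
            vc=VarianceComponents(sigma2_a, sigma2_e),
            restricted_loglik=-0.5 * neg2ll,
            ratio=lam_opt,
            ratio_identifiable=identifiable,
            n=n,
            column_names=tuple(column_names),
        )


def _describe_aliasing(X: np.ndarray, column_names: Sequence[str]) -> str:
    names = list(column_names) or [f"col{j}" for j in range(X.shape[1])]
    bad = []
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
            bad.append(names[j])
    return f"singular fixed-effect design; aliased columns: {bad or names}"


def reml_fit(
    y: pd.Series,
    fixed: np.ndarray,
    A: RelationshipMatrix,
    tol: float = 1e-8,
    column_names: Sequence[str] = (),
) -> LMMFit:
    """One-shot REML fit: restrict ``A`` to ``y``'s ids and fit ``fixed``.

    ``fixed`` must already contain the intercept column.  For repeated fits
    on the same individuals use :class:`REMLSolver` directly.
    """
    Asub = A.subset(list(y.index))
    solver = REMLSolver(Asub.values, tol=tol)
    return solver.fit(y.to_numpy(dtype=float), fixed, column_names=column_names)


def wald_test(fit: LMMFit, tested: Sequence[int]) -> WaldResult:
    """Wald chi-square for the fixed coefficients at positions ``tested``."""
    tested = list(tested)
    b = fit.beta[tested]
    V = fit.cov_beta[np.ix_(tested, tested)]
    df = len(tested)
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return WaldResult(math.nan, df, math.nan, skipped="singular V_b block")
    if stat < 0:  # numerical noise around 0
        stat = 0.0
    return WaldResult(stat, df, float(stats.chi2.sf(stat, df)), None)


# ---------------------------------------------------------------------------
# genome scans
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-SNP test results of one genome scan.

    ``tests`` has one row per performed (or skipped) test; ``summary`` has
    one row per SNP with its minimum p-value and the number of tests that
    produced a p-value.
    """

    method: str
    tests: pd.DataFrame  # snp_id, bp, test_id, statistic, df, p, skipped
    summary: pd.DataFrame  # snp_id, bp, min_p, tests_performed

    def to_tsv(self, path: str) -> None:
        df = self.tests.merge(
            self.summary[["snp_id", "min_p", "tests_performed"]], on="snp_id"
        )
        df["is_min_p"] = df["p"] == df["min_p"]
        df.to_csv(path, sep="\t", index=False)


def _align(
    hap: HaplotypeMatrix, y: pd.Series, A: RelationshipMatrix
) -> tuple[HaplotypeMatrix, np.ndarray, np.ndarray]:
    """Intersect phenotyped and genotyped individuals; subset A."""
    ids = [i for i in y.index if i in hap._index]
    missing = [i for i in y.index if i not in hap._index]
    if missing:
        logger.info(
            "dropping %d phenotyped individuals without genotypes (first: %s)",
            len(missing), missing[:3],
        )
    if len(ids) < 3:
        raise DataError("fewer than 3 individuals with both phenotype and genotype")
    hap = hap.take_individuals(ids)
    yv = y.loc[ids].to_numpy(dtype=float)
    if not np.all(np.isfinite(yv)):
        raise DataError("non-finite phenotype values")
    Asub = A.subset(ids).values
    return hap, yv, Asub


def _free_columns(
    clustering: FactorClustering, counts: np.ndarray, min_copies: int
) -> tuple[Optional[np.ndarray], Optional[list[int]], Optional[str]]:
    """Pick the free count columns for one factor.

    Groups with fewer than ``min_copies`` haplotype copies are dropped; the
    largest remaining group is the constrained baseline (its count is
    implied by the others).  Returns (X_counts, free_group_labels, reason)
    where reason is set when the factor must be skipped.
    """
    sizes = clustering.group_sizes()
    informative = [g for g in range(clustering.n_groups) if sizes[g] >= min_copies]
    if len(informative) < 2:
        return None, None, f"<2 groups with >= {min_copies} haplotype copies"
    baseline = max(informative, key=lambda g: (sizes[g], -g))
    free = [g for g in informative if g != baseline]
    return counts[:, free].astype(float), free, None


def genmix_scan(
    hap: HaplotypeMatrix,
    y: pd.Series,
    A: RelationshipMatrix,
    config: Optional[ScanConfig] = None,
) -> ScanResult:
    """GENMIX scan: per SNP, test up to 7 genealogy-derived clusterings.

    ``y`` is indexed by individual id; individuals without genotypes are
    dropped and ``A`` is subset (not re-derived) to the analysis set.  The
    scan is deterministic given its inputs.
    """
    config = config or ScanConfig()
    hap, yv, Asub = _align(hap, y, A)
    solver = REMLSolver(Asub, tol=config.reml_tolerance)
    yt = solver.rotate(yv)
    ones_t = solver.rotate(np.ones(hap.n_individuals))

    fixed_ratio = None
    if config.p3d:
        null_fit = solver.fit(yt, ones_t[:, None], rotated=True)
        fixed_ratio = null_fit.ratio

    compat = pairwise_compatibility(hap)
    # identical intervals yield identical trees and factor tests; cache them
    interval_cache: dict[tuple[int, int], list[dict]] = {}

    test_rows: list[dict] = []
    summary_rows: list[dict] = []
    for j in range(hap.n_sites):
        iv = maximal_compatible_interval(hap, j, compat=compat)
        key = (iv.left, iv.right)
        cached = interval_cache.get(key)
        if cached is None:
            cached = _test_interval(
                hap, iv, yt, ones_t, solver, config, fixed_ratio
            )
            interval_cache[key] = cached
        perf = 0
        min_p = math.nan
        for rec in cached:
            row = dict(rec)
            row["snp_id"] = hap.snp_ids[j]
            row["bp"] = int(hap.positions[j])
            test_rows.append(row)
            if row["skipped"] is None and np.isfinite(row["p"]):
                perf += 1
                min_p = row["p"] if math.isnan(min_p) else min(min_p, row["p"])
        summary_rows.append(
            {
                "snp_id": hap.snp_ids[j],
                "bp": int(hap.positions[j]),
                "min_p": min_p,
                "tests_performed": perf,
            }
        )
    cols = ["snp_id", "bp", "test_id", "statistic", "df", "p", "skipped"]
    tests = pd.DataFrame(test_rows, columns=cols)
    return ScanResult("genmix", tests, pd.DataFrame(summary_rows))


def _test_interval(
    hap: HaplotypeMatrix,
    iv,
    yt: np.ndarray,
    ones_t: np.ndarray,
    solver: REMLSolver,
    config: ScanConfig,
    fixed_ratio: Optional[float],
) -> list[dict]:
    """Fit and Wald-test every clustering of one interval's gene tree."""
    tree = build_perfect_phylogeny(hap, iv)
    out: list[dict] = []
    for clustering in extract_factors(tree):
        rec = {
            "test_id": f"cut{clustering.cut_id}",
            "statistic": math.nan,
            "df": 0,
            "p": math.nan,
            "skipped": None,
        }
        counts = counts_matrix(clustering, hap)
        Xc, free, reason = _free_columns(clustering, counts, config.min_group_copies)
        if reason is not None:
            rec["skipped"] = reason
            logger.warning("cut %d skipped: %s", clustering.cut_id, reason)
            out.append(rec)
            continue
        Xt = np.column_stack([ones_t, solver.rotate(Xc)])
        names = ["intercept"] + [f"group{g}" for g in free]
        try:
            fit = solver.fit(
                yt, Xt, fixed_ratio=fixed_ratio, rotated=True, column_names=names
            )
        except FitError as exc:
            rec["skipped"] = str(exc)
            logger.warning("cut %d skipped: %s", clustering.cut_id, exc)
            out.append(rec)
            continue
        wald = wald_test(fit, range(1, Xt.shape[1]))
        rec.update(
            statistic=wald.statistic, df=wald.df, p=wald.p, skipped=wald.skipped
        )
        out.append(rec)
    return out


def mma_scan(
    hap: HaplotypeMatrix,
    y: pd.Series,
    A: RelationshipMatrix,
    config: Optional[ScanConfig] = None,
) -> ScanResult:
    """Unified mixed-model scan: one additive single-SNP test per marker.

    Genotype is coded as 0/1/2 copies of the minor allele and tested with a
    1-df Wald chi-square against H0: alpha = 0.
    """
    config = config or ScanConfig()
    hap, yv, Asub = _align(hap, y, A)
    solver = REMLSolver(Asub, tol=config.reml_tolerance)
    yt = solver.rotate(yv)
    ones_t = solver.rotate(np.ones(hap.n_individuals))

    fixed_ratio = None
    if config.p3d:
        fixed_ratio = solver.fit(yt, ones_t[:, None], rotated=True).ratio

    g = hap.genotypes(minor=True).astype(float)
    test_rows: list[dict] = []
    summary_rows: list[dict] = []
    for j in range(hap.n_sites):
        rec = {
            "snp_id": hap.snp_ids[j],
            "bp": int(hap.positions[j]),
            "test_id": "mma",
            "statistic": math.nan,
            "df": 1,
            "p": math.nan,
            "skipped": None,
        }
        x = g[:, j]
        if x.min() == x.max():
            rec["skipped"] = "monomorphic in the phenotyped subset"
        else:
            Xt = np.column_stack([ones_t, solver.rotate(x)])
            try:
                fit = solver.fit(
                    yt, Xt, fixed_ratio=fixed_ratio, rotated=True,
                    column_names=["intercept", "snp"],
                )
                wald = wald_test(fit, [1])
                rec.update(
                    statistic=wald.statistic, df=wald.df, p=wald.p,
                    skipped=wald.skipped,
                )
            except FitError as exc:
                rec["skipped"] = str(exc)
        test_rows.append(rec)
        summary_rows.append(
            {
                "snp_id": rec["snp_id"],
                "bp": rec["bp"],
                "min_p": rec["p"],
                "tests_performed": 0 if rec["skipped"] else 1,
            }
        )
    cols = ["snp_id", "bp", "test_id", "statistic", "df", "p", "skipped"]
    return ScanResult("mma", pd.DataFrame(test_rows, columns=cols), pd.DataFrame(summary_rows))
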