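"""Significance thresholds, power, and marker-ranking metrics.

Multiple testing is handled by a Bonferroni correction over all tests on
the chromosome: 7 tree cuts per SNP for the genealogy scan, 1 test per SNP
for the single-SNP scan.  A QTL counts as detected when any test at a
marker within 2.5 Mbp of it is significant at the corrected per-test
threshold.  Localization is measured by ranking all markers by their
per-SNP minimum p-value (exact ties broken by a seeded random draw) and
taking the best rank within a 1 Mbp radius of the QTL.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "bonferroni_threshold",
    "power_criterion",
    "rank_markers",
    "best_rank_within_window",
    "aggregate_study",
]

POWER_WINDOW_BP = 2_500_000
RANK_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class ThresholdSpec:
    """Bonferroni bookkeeping for one scan."""

    alpha: float
    n_snps: int
    tests_per_snp: int

    @property
    def n_tests(self) -> int:
        return self.n_snps * self.tests_per_snp

    @property
    def per_test_threshold(self) -> float:
        return self.alpha / self.n_tests


def bonferroni_threshold(alpha: float, n_snps: int, tests_per_snp: int) -> float:
    """Per-test significance threshold ``alpha / (n_snps * tests_per_snp)``.

    The exact quotient is used for decisions; round only for display.
    """
    if alpha <= 0 or n_snps <= 0 or tests_per_snp <= 0:
        raise ValueError("alpha, n_snps and tests_per_snp must be positive")
    return alpha / (n_snps * tests_per_snp)


def power_criterion(
    scan,
    qtl_bp: float,
    threshold: float,
    window_bp: float = POWER_WINDOW_BP,
) -> bool:
    """True iff any test p-value at a SNP within ``window_bp`` of the QTL
    is below ``threshold``."""
    tests = scan.tests if hasattr(scan, "tests") else scan
    bp = tests["bp"].to_numpy(dtype=float)
    in_window = np.abs(bp - qtl_bp) <= window_bp
    if not in_window.any():
        warnings.warn(f"no SNPs within {window_bp:.0f} bp of the QTL", stacklevel=2)
        return False
    p = tests["p"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        return bool(np.any(p[in_window] < threshold))


def rank_markers(min_p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rank markers by ascending p (rank 1 = most significant).

    Exact ties are broken by a seeded uniform draw; NA p-values rank after
    every numeric p.  The result is a permutation of ``1..n``.
    """
    p = np.asarray(min_p, dtype=float)
    na = ~np.isfinite(p)
    key = np.where(na, np.inf, p)
    tiebreak = rng.random(len(p))
    order = np.lexsort((tiebreak, key))
    ranks = np.empty(len(p), dtype=np.int64)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks


def best_rank_within_window(
    ranks: np.ndarray,
    positions: np.ndarray,
    qtl_bp: float,
    window_bp: float = RANK_WINDOW_BP,
) -> tuple[Optional[int], int]:
    """Best (minimum) marker rank within ``window_bp`` of the QTL.

    Returns ``(best_rank, n_markers_in_window)``; best_rank is ``None``
    when the window is empty.
    """
    positions = np.asarray(positions, dtype=float)
    in_window = np.abs(positions - qtl_bp) <= window_bp
    n = int(in_window.sum())
    if n == 0:
        return None, 0
    return int(np.min(np.asarray(ranks)[in_window])), n


def aggregate_study(study: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-replicate study rows into power and ranking tables.

    Power: fraction of replicates detected per (h2, maf, effect, method).
    Ranking: per (maf, method), the distribution of the best rank within
    1 Mbp pooled over heritabilities and effect sizes, plus the fraction of
    replicates in which the top-ranked marker lies within the window.
    """
    power = (
        study.groupby(["h2", "maf", "effect", "method"], as_index=False)
        .agg(
            n_detected=("detected", "sum"),
            n_replicates=("detected", "size"),
        )
        .assign(power=lambda d: d.n_detected / d.n_replicates)
    )
    rows = []
    for (maf, method), grp in study.groupby(["maf", "method"]):
        best = grp["best_rank_1mbp"].dropna().astype(int)
        rows.append(
            {
                "maf": maf,
                "method": method,
                "n_pooled": len(grp),
                "pct_top_rank_within_1mbp": 100.0 * float((best == 1).mean())
                if len(best)
                else float("nan"),
                "median_best_rank_1mbp": float(best.median()) if len(best) else float("nan"),
                "mean_markers_in_window": float(grp["n_markers_1mbp"].mean()),
            }
        )
    ranking = pd.DataFrame(rows)
    return power, ranking
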