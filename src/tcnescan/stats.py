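"""Shared statistical routines: permutation enrichment, Spearman links,
multiple-testing adjustment, and thin group-comparison wrappers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    z: float | None
    n_perm: int

    def format_p(self) -> str:
        floor = 1.0 / (self.n_perm + 1)
        if self.p_value <= floor:
            return f"< {floor:g}"
        return f"{self.p_value:g}"


def permutation_enrichment(
    observed: float,
    null_sampler: Callable[[np.random.Generator], float],
    n_perm: int = 1000,
    seed: int = 666,
) -> PermutationResult:
    """Add-one empirical enrichment test.

    ``p = (1 + #{null >= observed}) / (n_perm + 1)``; never exactly zero.
    ``z`` is None when the null has zero spread.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.array([null_sampler(rng) for _ in range(n_perm)], dtype=float)
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - mean) / sd if sd > 0 else None
    return PermutationResult(
        observed=float(observed), null_mean=mean, null_sd=sd,
        p_value=p, z=z, n_perm=n_perm,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-averaged Spearman rank correlation with asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (``method='holm'`` for
    the Holm procedure)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum comparison of two groups."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    odds, p = stats.fisher_exact(np.asarray(table))
    return float(odds), float(p)
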