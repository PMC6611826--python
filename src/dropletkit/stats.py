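"""Nonparametric and parametric group comparisons for per-image metrics.

The comparison layer mirrors how droplet quantifications are analysed:
Mann–Whitney U on per-image medians/counts, Pearson's chi-squared (no
continuity correction) on the >1 μm² / ≤1 μm² size split, Welch's
unequal-variance t for biochemical triplicates, and fold changes of
medians for effect-size reporting. Test engines are scipy.stats; this
module fixes the variants (exact vs tie-corrected normal Mann–Whitney,
min-U convention, two-sided throughout) and the degenerate-input
behaviour so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "ContingencyTable",
    "mann_whitney_u",
    "chi_squared",
    "welch_t",
    "fold_change_of_medians",
]

#: Largest pooled sample size for which the exact Mann–Whitney null
#: distribution is enumerated (ties force the tie-corrected normal).
EXACT_MWU_LIMIT = 14


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    method: str
    n_x: int
    n_y: int
    exact: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ContingencyTable:
    """2×k table of nonnegative counts with optional labels."""

    counts: tuple[tuple[int, ...], ...]
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError(f"sample {name} is empty")
    if not np.isfinite(arr).all():
        raise ValueError(f"sample {name} contains non-finite values")
    return arr


def mann_whitney_u(x, y) -> StatResult:
    """Two-sided Mann–Whitney U test.

    The exact null distribution is used when n_x + n_y ≤ 14 and there are
    no ties; otherwise the normal approximation with tie correction (and
    continuity correction). U is reported in the min(U_x, U_y)
    convention. Identical constant samples (zero rank variance) return
    U = n_x·n_y/2, p = 1.
    """
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (xa.size + ya.size) <= EXACT_MWU_LIMIT and not has_ties
    if np.ptp(pooled) == 0:
        # all observations tied: the tie-corrected normal is 0/0
        return StatResult(
            statistic=xa.size * ya.size / 2.0,
            p_value=1.0,
            method="mann-whitney-u (degenerate: all tied)",
            n_x=xa.size,
            n_y=ya.size,
            exact=False,
        )
    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u_x = float(res.statistic)
    u_min = min(u_x, xa.size * ya.size - u_x)
    return StatResult(
        statistic=u_min,
        p_value=min(float(res.pvalue), 1.0),
        method="mann-whitney-u " + ("(exact)" if exact else "(normal, tie-corrected)"),
        n_x=xa.size,
        n_y=ya.size,
        exact=exact,
    )


def chi_squared(table: ContingencyTable) -> StatResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal row/column")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return StatResult(
        statistic=float(chi2),
        p_value=float(p),
        method=f"pearson-chi-squared (df={dof})",
        n_x=int(arr[0].sum()),
        n_y=int(arr[1].sum()) if arr.shape[0] > 1 else 0,
        exact=False,
    )


def welch_t(x, y) -> StatResult:
    """Two-tailed unequal-variance (Welch) t test."""
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("Welch t needs at least 2 observations per group")
    if xa.var(ddof=1) == 0 and ya.var(ddof=1) == 0:
        if xa.mean() == ya.mean():
            return StatResult(0.0, 1.0, "welch-t (degenerate: zero variance)",
                              xa.size, ya.size)
        raise ValueError("zero variance in both samples: t undefined")
    res = sps.ttest_ind(xa, ya, equal_var=False)
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="welch-t",
        n_x=xa.size,
        n_y=ya.size,
    )


def fold_change_of_medians(x, y) -> float:
    """median(y) / median(x); raises when the reference median is zero."""
    mx = float(np.median(_as_sample(x, "x")))
    my = float(np.median(_as_sample(y, "y")))
    if mx == 0:
        raise ValueError("reference median is zero: fold change undefined")
    return my / mx
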