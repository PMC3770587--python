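"""Inferential statistics for breed-trait association screens.

The workhorse is the Pearson correlation assessed nonparametrically, since
popularity measures and breed-typical trait scores are distributed far
from normal: significance comes from a two-sided permutation test (default
B = 50,000 permutations, add-one convention so p is never zero) and
confidence intervals from a paired percentile bootstrap.  Multiple-testing
control offers Bonferroni and the Benjamini-Yekutieli step-up procedure
(FDR control under arbitrary dependence, harmonic-sum correction).  The
module also provides one-way fixed-effects ANOVA with eta-squared and an
exact-with-ties Wilcoxon signed-rank test for paired comparisons.

All Monte-Carlo routines accept either an integer seed or a
``numpy.random.Generator`` so a single generator can be threaded through a
whole pipeline run for end-to-end determinism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "AnovaResult",
    "pearson_r",
    "permutation_pvalue",
    "bootstrap_ci",
    "adjust_bonferroni",
    "adjust_by",
    "adjust_bh",
    "one_way_anova",
    "variance_explained",
    "wilcoxon_signed_rank",
    "associate",
    "correlation_screen",
]

DEFAULT_B = 50_000
DEFAULT_ALPHA = 0.05

# Relative guard for >= comparisons between resampled and observed |r|, so
# that exact ties (e.g. under exhaustive-size nulls) are counted as extreme
# despite floating-point noise.
_TIE_EPS = 1e-12


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN in input; drop incomplete pairs first")
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation; raises on zero variance."""
    x, y = _clean_pair(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("undefined correlation: zero variance input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _row_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r of each row pair of two (B, n) matrices; NaN on zero var."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", Xc, Yc)
    denom = np.sqrt(
        np.einsum("ij,ij->i", Xc, Xc) * np.einsum("ij,ij->i", Yc, Yc)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / denom, np.nan)


def permutation_pvalue(
    x, y, B: int = DEFAULT_B, seed: int | np.random.Generator | None = None
) -> float:
    """Two-sided permutation p-value for the Pearson correlation.

    ``p = (1 + #{b : |r(x, pi_b(y))| >= |r(x, y)|}) / (B + 1)`` over B
    independent uniform permutations pi_b; the add-one convention keeps
    the Monte-Carlo test valid and p >= 1/(B+1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x, y = _clean_pair(x, y)
    r_obs = abs(pearson_r(x, y))
    rng = _as_rng(seed)
    n = len(x)
    count = 0
    # blockwise to bound memory at large B
    for start in range(0, B, 20_000):
        nb = min(20_000, B - start)
        perms = rng.permuted(np.tile(np.arange(n), (nb, 1)), axis=1)
        r_perm = _row_pearson(np.tile(x, (nb, 1)), y[perms])
        count += int(np.sum(np.abs(r_perm) >= r_obs - _TIE_EPS))
    return (1 + count) / (B + 1)


def bootstrap_ci(
    x,
    y,
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the Pearson correlation.

    Resamples (x_i, y_i) pairs with replacement; degenerate resamples with
    zero variance are redrawn.  Returns the alpha/2 and 1 - alpha/2
    percentiles of the bootstrap r distribution.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for a meaningful interval")
    x, y = _clean_pair(x, y)
    pearson_r(x, y)  # validates nonzero variance of the original sample
    rng = _as_rng(seed)
    n = len(x)
    out = np.empty(B)
    filled = 0
    while filled < B:
        nb = min(20_000, B - filled)
        idx = rng.integers(0, n, size=(nb, n))
        r = _row_pearson(x[idx], y[idx])
        r = r[~np.isnan(r)]  # degenerate resamples: redraw
        take = min(len(r), B - filled)
        out[filled : filled + take] = r[:take]
        filled += take
    lo, hi = np.quantile(out, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _validate_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def adjust_bonferroni(p, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment min(1, m * p), m defaulting to len(p)."""
    p = _validate_p(p)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m cannot be smaller than len(p)")
    return np.minimum(1.0, m * p)


def adjust_by(p) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    Valid under arbitrary dependence via the harmonic correction
    c(m) = sum_{i<=m} 1/i; elementwise >= the Benjamini-Hochberg values.
    """
    p = _validate_p(p)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (internal comparison baseline)."""
    p = _validate_p(p)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AnovaResult:
    response: str
    factor: str
    k: int
    N: int
    F: float
    df: tuple[int, int]
    p: float
    eta_squared: float
    degenerate: bool = False  # zero within-group variance with unequal means


def one_way_anova(
    values, groups, response: str = "value", factor: str = "group"
) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA with eta-squared.

    eta_squared = SS_between / SS_total is the fraction of variance in the
    response attributable to group membership.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels, inverse = np.unique(groups, return_inverse=True)
    k, N = len(labels), len(values)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if N <= k:
        raise ValueError("need more observations than groups")
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    if ss_total == 0:
        raise ValueError("F undefined: zero total variance")
    group_means = np.bincount(inverse, weights=values) / np.bincount(inverse)
    ss_between = float(
        (np.bincount(inverse) * (group_means - grand) ** 2).sum()
    )
    ss_within = ss_total - ss_between
    df1, df2 = k - 1, N - k
    degenerate = False
    if ss_within <= 0:
        degenerate = True
        F = math.inf
        p = float(np.nextafter(0, 1))
    else:
        F = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(F, df1, df2))
    return AnovaResult(
        response=response,
        factor=factor,
        k=k,
        N=N,
        F=F,
        df=(df1, df2),
        p=p,
        eta_squared=ss_between / ss_total,
        degenerate=degenerate,
    )


def variance_explained(y, x) -> float:
    """R-squared of the simple linear regression of y on x.

    Identical to the squared Pearson correlation for a single predictor.
    """
    return pearson_r(x, y) ** 2


def _signed_rank_exact_sf(ranks2: np.ndarray) -> np.ndarray:
    """Null distribution of 2*W+ by dynamic programming.

    ``ranks2`` are the doubled mid-ranks (integers even with ties).  Returns
    the full probability mass function over 0..sum(ranks2).
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank(a, b, exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  For n <= ``exact_max_n`` the null distribution of the
    positive-rank sum W+ is computed exactly by enumeration over all 2^n
    sign assignments (via dynamic programming, which handles ties); larger
    n uses the normal approximation with tie correction and continuity
    correction.  Returns (W+, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences zero: test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        pmf = _signed_rank_exact_sf(ranks2)
        w2 = int(round(2 * w_plus))
        lower = pmf[: w2 + 1].sum()
        upper = pmf[w2:].sum()
        p = min(1.0, 2 * min(lower, upper))
    else:
        mean = n * (n + 1) / 4
        tie_counts = np.unique(np.abs(d), return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24 - (
            (tie_counts**3 - tie_counts).sum() / 48
        )
        sd = math.sqrt(var)
        # continuity correction toward the mean
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / sd
        p = min(1.0, 2 * float(sps.norm.sf(abs(z))))
    return w_plus, p


@dataclass
class AssociationResult:
    """One correlation with its nonparametric inference bundle."""

    measure: str
    trait: str
    n: int
    r: float
    ci_low: float
    ci_high: float
    p_perm: float
    B: int
    seed: int | None = None
    p_bonferroni: float | None = None
    p_by: float | None = None


def associate(
    x,
    y,
    measure: str,
    trait: str,
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
    seed_label: int | None = None,
) -> AssociationResult:
    """Correlation, bootstrap CI and permutation p for one variable pair."""
    x, y = _clean_pair(x, y)
    rng = _as_rng(seed)
    r = pearson_r(x, y)
    lo, hi = bootstrap_ci(x, y, B=B, alpha=alpha, seed=rng)
    p = permutation_pvalue(x, y, B=B, seed=rng)
    return AssociationResult(
        measure=measure,
        trait=trait,
        n=len(x),
        r=r,
        ci_low=lo,
        ci_high=hi,
        p_perm=p,
        B=B,
        seed=seed_label,
    )


def correlation_screen(
    joined: pd.DataFrame,
    popularity_measures: list[str],
    trait_vars: list[str],
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator | None = None,
    seed_label: int | None = None,
    family: str = "panel",
) -> pd.DataFrame:
    """Screen every (popularity measure, trait) pair on a joined table.

    Each pair uses pairwise-complete observations.  Multiple-testing
    adjustment is applied within each measure's panel of traits
    (``family="panel"``, the default 14-comparison layout) or across the
    whole screen (``family="global"``).  Pairs with n < 3 or zero variance
    are skipped with a warning.  Deterministic under a fixed seed.
    """
    if family not in ("panel", "global"):
        raise ValueError("family must be 'panel' or 'global'")
    rng = _as_rng(seed)
    rows: list[AssociationResult] = []
    for measure in popularity_measures:
        for trait in trait_vars:
            sub = joined[[measure, trait]].dropna()
            if len(sub) < 3:
                logger.warning(
                    "skipping %s vs %s: only %d complete pairs",
                    measure, trait, len(sub),
                )
                continue
            try:
                rows.append(
                    associate(
                        sub[measure], sub[trait], measure, trait,
                        B=B, alpha=alpha, seed=rng, seed_label=seed_label,
                    )
                )
            except ValueError as exc:
                logger.warning("skipping %s vs %s: %s", measure, trait, exc)
    table = pd.DataFrame([vars(r) for r in rows])
    if len(table) == 0:
        return table
    if family == "panel":
        for measure, idx in table.groupby("measure").groups.items():
            p = table.loc[idx, "p_perm"].to_numpy()
            table.loc[idx, "p_bonferroni"] = adjust_bonferroni(p)
            table.loc[idx, "p_by"] = adjust_by(p)
    else:
        p = table["p_perm"].to_numpy()
        table["p_bonferroni"] = adjust_bonferroni(p)
        table["p_by"] = adjust_by(p)
    return table
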