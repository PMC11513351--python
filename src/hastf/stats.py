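"""Ablation statistics: one-way ANOVA and Games-Howell post-hoc tests.

The ANOVA decomposes total variation in the per-fold accuracies into
between-variant and within-variant sums of squares; under the null of
equal means F = MS_between / MS_within follows an F distribution with
(k-1, N-k) degrees of freedom.  Because ablation variants need not share
a variance, the pairwise follow-up uses the Games-Howell procedure:
Welch-Satterthwaite degrees of freedom per pair, standard error from the
per-group variances, and critical values from the studentized-range
distribution at the 95% family level.  An optional seeded bootstrap adds
bias estimates and BCa confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PosthocPair",
    "one_way_anova",
    "f_from_sums",
    "games_howell",
]


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f: float
    p: float

    def __str__(self) -> str:
        return (
            f"one-way ANOVA: F({self.df_between}, {self.df_within}) = "
            f"{self.f:.2f}, p = {self.p:.3g}"
        )


def one_way_anova(groups: list) -> AnovaResult:
    """Standard one-way fixed-effects decomposition.

    groups: list of value vectors, one per level; each needs >= 2 values.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for i, a in enumerate(arrs):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")

    all_values = np.concatenate(arrs)
    grand = all_values.mean()
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    ss_total = float(((all_values - grand) ** 2).sum())
    df_between = len(arrs) - 1
    df_within = all_values.size - len(arrs)
    ms_b, ms_w, f = f_from_sums(ss_between, df_between, ss_within, df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaResult(
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_total,
        df_between=df_between,
        df_within=df_within,
        df_total=df_between + df_within,
        ms_between=ms_b,
        ms_within=ms_w,
        f=f,
        p=p,
    )


def f_from_sums(ss_b: float, df_b: int, ss_w: float, df_w: int) -> tuple[float, float, float]:
    """Mean squares and F-statistic from sums of squares and df.

    Useful for reproducing published ANOVA tables from their printed
    sums of squares.
    """
    if df_b <= 0 or df_w <= 0:
        raise ValueError("degrees of freedom must be positive")
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    return ms_b, ms_w, ms_b / ms_w


@dataclass(frozen=True)
class PosthocPair:
    """One Games-Howell pairwise comparison (A minus B)."""

    group_a: str
    group_b: str
    mean_difference: float
    standard_error: float
    df: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    bias: float | None = None
    method: str = "games_howell"


def _bca_interval(
    diffs: np.ndarray, observed: float, jack: np.ndarray, alpha: float
) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval."""
    z0 = sps.norm.ppf(np.clip((diffs < observed).mean(), 1e-9, 1 - 1e-9))
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    lo, hi = [], []
    for q in (alpha / 2, 1 - alpha / 2):
        z = sps.norm.ppf(q)
        adj = sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        lo.append(adj)
    lo_q, hi_q = lo
    return float(np.quantile(diffs, lo_q)), float(np.quantile(diffs, hi_q))


def games_howell(
    groups: list,
    names: list[str] | None = None,
    alpha: float = 0.05,
    bootstrap_bca: int = 0,
    seed: int = 0,
) -> list[PosthocPair]:
    """All pairwise Games-Howell comparisons.

    Default confidence intervals are the analytic studentized-range
    intervals; bootstrap_bca > 0 additionally reports the bootstrap bias
    of the mean difference and replaces the CI with a seeded BCa interval
    (an approximation for published tables that quote bias-corrected
    intervals).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if names is None:
        names = [f"group{i}" for i in range(len(arrs))]
    k = len(arrs)
    for nm, a in zip(names, arrs):
        if a.size < 2:
            raise ValueError(f"group {nm!r} has fewer than 2 values")
        if a.var(ddof=1) <= 0:
            raise ValueError(f"group {nm!r} has zero variance")

    rng = np.random.default_rng(seed)
    pairs: list[PosthocPair] = []
    for i, j in combinations(range(k), 2):
        a, b = arrs[i], arrs[j]
        na, nb = a.size, b.size
        va, vb = a.var(ddof=1), b.var(ddof=1)
        diff = float(a.mean() - b.mean())
        se = float(np.sqrt(va / na + vb / nb))
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        t = diff / se
        p = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df))
        half = q_crit / np.sqrt(2.0) * se
        ci_low, ci_high = diff - half, diff + half
        bias = None
        if bootstrap_bca > 0:
            boot = np.empty(bootstrap_bca)
            for r in range(bootstrap_bca):
                boot[r] = rng.choice(a, na).mean() - rng.choice(b, nb).mean()
            bias = float(boot.mean() - diff)
            merged = np.concatenate([a, b])
            jack = np.array(
                [
                    np.delete(a, m).mean() - b.mean() if m < na
                    else a.mean() - np.delete(b, m - na).mean()
                    for m in range(merged.size)
                ]
            )
            ci_low, ci_high = _bca_interval(boot, diff, jack, alpha)
        pairs.append(
            PosthocPair(
                group_a=names[i],
                group_b=names[j],
                mean_difference=diff,
                standard_error=se,
                df=float(df),
                t=float(t),
                p=p,
                ci_low=ci_low,
                ci_high=ci_high,
                bias=bias,
            )
        )
    return pairs
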