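"""Group-comparison statistics.

One-way ANOVA with a variance-homogeneity-driven choice of post-hoc
family: Levene's test (median-centred) at alpha = 0.05 selects Duncan's
multiple range test when variances look equal, and Dunnett's T3 when
they do not.  Neither post-hoc test ships with scipy or statsmodels, so
both are implemented here; the omnibus F and every other test go through
scipy.stats.

Duncan's test uses studentized-range critical values at the protection
level 1 - (1-alpha)**(p-1) for a span of p ordered means, with the
harmonic mean of the group sizes in the standard error.  Dunnett's T3
uses Welch-type pairwise statistics referred to the studentized maximum
modulus; its tail is computed under independence,
P(max|T| <= q) = (2*F_t(q; df) - 1)**k, a standard working approximation
when exact SMM tables are unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

DUNCAN = "duncan"
DUNNETT_T3 = "dunnett_t3"


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    significant: bool
    p_value: Optional[float] = None  # Duncan's test is decision-only


@dataclass
class GroupSummary:
    """One-way ANOVA over named groups with post-hoc pairwise calls."""

    means: dict[str, float]
    standard_errors: dict[str, float]
    sizes: dict[str, int]
    f_statistic: float
    p_value: float
    levene_p: float
    posthoc_method: str
    pairwise: list[PairwiseResult] = field(default_factory=list)
    excluded_groups: list[str] = field(default_factory=list)


def _anova_f(groups: Sequence[np.ndarray]) -> tuple[float, float, float, int]:
    """F, p, mean-square error and error df for a one-way layout."""
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df_err = n_total - k
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    mse = sse / df_err if df_err > 0 else float("nan")
    return float(f), float(p), mse, df_err


def duncan_pairwise(
    names: Sequence[str],
    groups: Sequence[np.ndarray],
    mse: float,
    df_err: int,
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """Duncan's multiple range test over ordered group means.

    A span of p ordered means is declared significant when its range
    exceeds q(1-(1-alpha)^(p-1); p, df) * sqrt(MSE / n_h); spans nested
    inside a non-significant span are never declared significant.
    """
    order = np.argsort([g.mean() for g in groups])
    sorted_names = [names[i] for i in order]
    sorted_means = [float(groups[i].mean()) for i in order]
    n_h = len(groups) / sum(1.0 / len(g) for g in groups)
    se = math.sqrt(mse / n_h)

    k = len(groups)
    nonsig_spans: list[tuple[int, int]] = []
    results: list[PairwiseResult] = []
    # widest spans first so the containment rule can be applied
    for span in range(k, 1, -1):
        prot = (1.0 - alpha) ** (span - 1)
        q_crit = float(stats.studentized_range.ppf(prot, span, df_err))
        for i in range(0, k - span + 1):
            j = i + span - 1
            diff = sorted_means[j] - sorted_means[i]
            contained = any(a <= i and j <= b for a, b in nonsig_spans)
            sig = (not contained) and diff > q_crit * se
            if not sig:
                nonsig_spans.append((i, j))
            results.append(
                PairwiseResult(
                    group_a=sorted_names[i],
                    group_b=sorted_names[j],
                    mean_diff=diff,
                    significant=sig,
                )
            )
    return results


def dunnett_t3_pairwise(
    names: Sequence[str],
    groups: Sequence[np.ndarray],
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """Dunnett's T3: Welch pairwise t referred to the studentized maximum
    modulus over all k*(k-1)/2 comparisons."""
    k = len(groups)
    n_comp = k * (k - 1) // 2
    results: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            denom = math.sqrt(va + vb)
            t_stat = (a.mean() - b.mean()) / denom if denom > 0 else float("inf")
            df = (va + vb) ** 2 / (
                va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
            ) if va + vb > 0 else 1.0
            p_single = 2.0 * stats.t.cdf(abs(t_stat), df) - 1.0
            p_adj = 1.0 - p_single**n_comp
            results.append(
                PairwiseResult(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=float(a.mean() - b.mean()),
                    significant=p_adj < alpha,
                    p_value=float(p_adj),
                )
            )
    return results


def group_anova(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> GroupSummary:
    """One-way ANOVA with a Levene-selected post-hoc family.

    Groups with fewer than two observations are excluded (recorded on
    the summary).  Post-hoc comparisons are reported only when the
    omnibus test is significant at ``alpha`` (protected tests).
    """
    kept: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[~np.isnan(arr)]
        if len(arr) < 2:
            excluded.append(name)
        else:
            kept[name] = arr
    if len(kept) < 2:
        raise ValueError("group_anova requires at least two groups with >= 2 members")

    names = sorted(kept)
    arrays = [kept[n] for n in names]
    if all(np.ptp(a) == 0 for a in arrays) and len({a.mean() for a in arrays}) == 1:
        raise ValueError("all observations identical: ANOVA undefined (zero variance)")

    f, p, mse, df_err = _anova_f(arrays)
    try:
        _, levene_p = stats.levene(*arrays, center="median")
        levene_p = float(levene_p)
    except Exception:
        levene_p = float("nan")

    equal_var = not (levene_p == levene_p and levene_p < alpha)  # NaN -> equal
    method = DUNCAN if equal_var else DUNNETT_T3
    pairwise: list[PairwiseResult] = []
    if p < alpha:
        if method == DUNCAN:
            pairwise = duncan_pairwise(names, arrays, mse, df_err, alpha)
        else:
            pairwise = dunnett_t3_pairwise(names, arrays, alpha)

    return GroupSummary(
        means={n: float(a.mean()) for n, a in zip(names, arrays)},
        standard_errors={
            n: float(a.std(ddof=1) / math.sqrt(len(a))) for n, a in zip(names, arrays)
        },
        sizes={n: int(len(a)) for n, a in zip(names, arrays)},
        f_statistic=f,
        p_value=p,
        levene_p=levene_p,
        posthoc_method=method,
        pairwise=pairwise,
        excluded_groups=excluded,
    )


def spearman_vs_length(
    counts: Sequence[float], lengths: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, two-sided p
    from the t approximation).  Returns (rho, p); rho is NaN when either
    vector is constant."""
    x = np.asarray(counts, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if len(x) != len(y):
        raise ValueError("count and length vectors differ in size")
    if len(x) < 3:
        raise ValueError("need at least 3 chromosomes for a rank correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided)."""
    t, p = stats.ttest_ind(
        np.asarray(a, float), np.asarray(b, float), equal_var=False
    )
    return float(t), float(p)
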