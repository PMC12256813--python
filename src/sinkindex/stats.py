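"""Nonparametric group statistics: Mann–Whitney U, Kruskal–Wallis,
Dunn's post hoc with Bonferroni, and significance-tier labels.

Conventions: U is reported as min(U_a, U_b), so complete separation gives
U = 0; p-values are two-sided throughout. The Mann–Whitney p is computed
by exact enumeration when both samples have n ≤ 12 and there are no ties,
and otherwise by the tie-corrected normal approximation (no continuity
correction, so that for two groups the Kruskal–Wallis identity H = z²
holds exactly). Dunn's z compares mean ranks with the usual tie
correction; Bonferroni multiplies by the number of pairwise comparisons,
capped at 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import ValidationError


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    group_sizes: tuple[int, ...] = ()
    tier: str = ""
    df: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tier:
            p = self.adjusted_p if self.adjusted_p is not None else self.p_value
            self.tier = significance_tier(p)


def significance_tier(p: float) -> str:
    """Tier label: *** (p<0.001), ** (p<0.01), * (p<=0.05), else n.s."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def _rank_with_ties(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return ranks, counts


def _mw_u_stats(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(U_a, U_b) from midrank sums."""
    n1, n2 = a.size, b.size
    ranks, _ = _rank_with_ties(np.concatenate([a, b]))
    r_a = ranks[:n1].sum()
    u_a = r_a - n1 * (n1 + 1) / 2
    return u_a, n1 * n2 - u_a


def _mw_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by full enumeration over rank assignments.

    P(min(U_a, U_b) <= observed) over all C(n1+n2, n1) ways of assigning
    the pooled (midrank-tied) observations to group a. Handles ties, at
    the cost of exhaustive enumeration.
    """
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    u_obs = min(_mw_u_stats(a, b))
    ranks = tuple(sps.rankdata(pooled))
    offset = n1 * (n1 + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(ranks, n1):
        total += 1
        u_a = sum(combo) - offset
        if min(u_a, n1 * n2 - u_a) <= u_obs + 1e-12:
            count += 1
    return min(1.0, count / total)


def mann_whitney_u(a, b, mode: str = "auto") -> StatResult:
    """Two-sided Mann–Whitney U test.

    mode="exact" enumerates all C(n1+n2, n1) group assignments;
    mode="normal_approx" uses the tie-corrected Gaussian; "auto" picks
    exact when both n ≤ 12.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty sample")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if (a.size <= 12 and b.size <= 12) else "normal_approx"

    u_a, u_b = _mw_u_stats(a, b)
    u = min(u_a, u_b)
    n1, n2 = a.size, b.size

    if mode == "exact":
        has_ties = np.unique(np.concatenate([a, b])).size < n1 + n2
        if has_ties:
            p = _mw_exact_p(a, b)
        else:
            # tie-free case: the exact null distribution is available in
            # closed recursive form; equivalent to full enumeration
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
        z = np.nan
    else:
        n = n1 + n2
        _, tie_counts = _rank_with_ties(np.concatenate([a, b]))
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        sigma2 = n1 * n2 / 12 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            z, p = 0.0, 1.0
        else:
            z = (u_a - n1 * n2 / 2) / np.sqrt(sigma2)
            p = min(1.0, 2 * sps.norm.sf(abs(z)))
    return StatResult(
        "mann_whitney_u", float(u), float(p),
        group_sizes=(n1, n2), extra={"U_a": float(u_a), "U_b": float(u_b), "z": float(z),
                                     "mode": mode},
    )


def kruskal_wallis(groups) -> StatResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p on k−1 df."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValidationError("need >= 2 nonempty groups")
    k = len(groups)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # fully degenerate: no rank variation
        return StatResult("kruskal_wallis", 0.0, 1.0, group_sizes=tuple(g.size for g in groups),
                          df=k - 1)
    h, p = sps.kruskal(*groups)
    return StatResult(
        "kruskal_wallis", float(h), float(p),
        group_sizes=tuple(g.size for g in groups), df=k - 1,
    )


def dunn_posthoc(groups, correction: str = "bonferroni",
                 names: list[str] | None = None) -> list[StatResult]:
    """Dunn's pairwise mean-rank z tests after Kruskal–Wallis.

    Adjusted p is min(1, p × number of pairs). Singleton groups are
    skipped with a warning entry in ``extra``.
    """
    if correction != "bonferroni":
        raise ValidationError("only bonferroni correction is supported")
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    names = names or [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks, tie_counts = _rank_with_ties(pooled)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (n - 1)) if n > 1 else 0.0

    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size

    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    results = []
    for i, j in pairs:
        if sizes[i] < 2 or sizes[j] < 2:
            results.append(StatResult(
                "dunn", np.nan, 1.0, adjusted_p=1.0, group_sizes=(sizes[i], sizes[j]),
                extra={"pair": (names[i], names[j]), "warning": "singleton group; pair skipped"},
            ))
            continue
        var = (n * (n + 1) / 12 - tie_term) * (1 / sizes[i] + 1 / sizes[j])
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = min(1.0, 2 * sps.norm.sf(abs(z)))
        results.append(StatResult(
            "dunn", float(z), float(p), adjusted_p=min(1.0, p * m),
            group_sizes=(sizes[i], sizes[j]), extra={"pair": (names[i], names[j])},
        ))
    return results
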