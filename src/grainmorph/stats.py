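"""Statistical battery for cultivar comparisons.

Group descriptives report the sample standard deviation and the
coefficient of variation ``CV = 100·SD/mean``. Cultivar means are compared
by one-way ANOVA followed by Duncan's multiple range test with compact
letter display (groups sharing a letter do not differ at the chosen
level); Duncan's test is applied in its protected form, i.e. only after a
significant ANOVA F, which keeps the experimentwise type-I rate near the
nominal level. When normality fails, the rank-based Kruskal–Wallis test is
the fallback. Pairwise association uses Pearson correlation with a
two-sided t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "DuncanResult",
    "CorrelationResult",
    "descriptive",
    "anova_duncan",
    "kruskal_wallis",
    "pearson",
    "choose_test",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float  # sample SD (n-1); NaN for a single observation
    cv: float  # %, 100·SD/mean
    letters: str = ""


@dataclass(frozen=True)
class DuncanResult:
    F: float
    p: float
    letters: dict[str, str]  # group -> homogeneity letters
    means: dict[str, float]
    mse: float
    df_error: int
    significant: bool


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    p: float
    n: int
    significant: bool  # at alpha = 0.05


def descriptive(groups: dict[str, np.ndarray]) -> list[GroupSummary]:
    """Mean, sample SD and CV per group.

    A single-observation group gets ``sd = cv = NaN`` (flagged rather than
    zero); a constant group gets ``cv = 0``.
    """
    out = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        mean = float(v.mean())
        if v.size < 2:
            sd = cv = float("nan")
        else:
            sd = float(v.std(ddof=1))
            cv = 100.0 * sd / mean if mean != 0 else float("inf")
        out.append(GroupSummary(group=str(name), n=int(v.size), mean=mean, sd=sd, cv=cv))
    return out


def _duncan_letters(
    names: list[str],
    means: np.ndarray,
    mse: float,
    df_error: int,
    n_harmonic: float,
    alpha: float,
) -> dict[str, str]:
    """Compact letter display from Duncan's least significant ranges.

    The least significant range for a stretch of ``p`` ordered means uses
    the studentized range quantile at Duncan's protection level
    ``(1 - alpha)^(p - 1)``. Letters are assigned by the standard sweep
    over means sorted ascending: each maximal run of mutually
    non-significant groups shares one letter.
    """
    k = len(names)
    order = np.argsort(means)
    sorted_means = means[order]
    se = np.sqrt(mse / n_harmonic)
    lsr = {
        p: float(sps.studentized_range.ppf((1 - alpha) ** (p - 1), p, df_error)) * se
        for p in range(2, k + 1)
    }

    def differ(i: int, j: int) -> bool:
        # i < j in sorted order; range spans j - i + 1 means
        return (sorted_means[j] - sorted_means[i]) > lsr[j - i + 1]

    # maximal runs of mutually non-significant means
    runs: list[tuple[int, int]] = []
    start = 0
    while start < k:
        end = start
        while end + 1 < k and not differ(start, end + 1):
            end += 1
        runs.append((start, end))
        start += 1
    # keep only runs not contained in another run
    maximal = [
        (a, b)
        for a, b in runs
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in runs)
    ]
    maximal = sorted(set(maximal))

    letters_sorted = ["" for _ in range(k)]
    for idx, (a, b) in enumerate(maximal):
        letter = chr(ord("a") + idx)
        for i in range(a, b + 1):
            letters_sorted[i] += letter
    return {names[order[i]]: letters_sorted[i] for i in range(k)}


def anova_duncan(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> DuncanResult:
    """One-way ANOVA with protected Duncan's multiple range test.

    When the ANOVA F test is not significant at ``alpha`` every group
    shares the letter ``a`` (the protected form of the test). Otherwise
    letters come from Duncan's least significant ranges with the harmonic
    mean group size standing in for unbalanced designs.

    Raises
    ------
    ValueError
        For fewer than two groups, any group of size < 2, or zero
        within-group variance everywhere.
    """
    names = [str(n) for n in groups]
    data = [np.asarray(groups[n], dtype=float) for n in groups]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(len(d) < 2 for d in data):
        raise ValueError("every group needs at least two observations")
    means = np.array([d.mean() for d in data])
    ns = np.array([len(d) for d in data])
    df_error = int(ns.sum() - len(data))
    sse = float(sum(((d - d.mean()) ** 2).sum() for d in data))
    if sse == 0:
        raise ValueError("zero within-group variance everywhere: F undefined")
    mse = sse / df_error
    f_stat, p_val = sps.f_oneway(*data)
    significant = bool(p_val <= alpha)
    if significant:
        n_h = len(ns) / np.sum(1.0 / ns)
        letters = _duncan_letters(names, means, mse, df_error, n_h, alpha)
    else:
        letters = {n: "a" for n in names}
    return DuncanResult(
        F=float(f_stat),
        p=float(p_val),
        letters=letters,
        means={n: float(m) for n, m in zip(names, means)},
        mse=mse,
        df_error=df_error,
        significant=significant,
    )


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-square p-value."""
    data = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(data)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*data)
    return float(h), float(p)


def choose_test(groups: dict[str, np.ndarray], alpha: float = 0.05) -> str:
    """Pick "anova" or "kruskal" by per-group Shapiro–Wilk normality.

    Any group failing Shapiro–Wilk at ``alpha`` routes the comparison to
    the rank-based test. Groups of fewer than 3 observations cannot be
    tested and are treated as normal.
    """
    for values in groups.values():
        v = np.asarray(values, dtype=float)
        if len(v) >= 3 and np.ptp(v) > 0:
            if sps.shapiro(v).pvalue < alpha:
                return "kruskal"
    return "anova"


def pearson(
    x: np.ndarray,
    y: np.ndarray,
    names: tuple[str, str] = ("x", "y"),
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson r with a two-sided t test on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least three complete pairs")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        pair=names, r=float(r), p=float(p), n=int(len(x)),
        significant=bool(p <= alpha),
    )
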