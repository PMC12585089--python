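"""Temporal trends, group comparisons, and depth correlations.

Temporal change in an isotope series is summarized three ways at once:
an OLS slope against Julian day (with its two-sided t-test), the
tie-corrected Kendall τ-b rank correlation as a nonparametric check,
and — when the slope clears a caller-supplied Bonferroni-adjusted
alpha — the decadal change Δ = slope × 3650 in ‰ per decade.

Group comparisons mirror the usual nonparametric battery for skewed
isotope data: a tie-corrected Kruskal–Wallis test followed by Dunn's
pairwise z-tests with Bonferroni adjustment and a compact letter
display (groups share a letter iff no significant difference connects
them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coastiso.errors import InsufficientDataError, SingularFitError

#: days per decade used for the decadal-change conversion
DAYS_PER_DECADE = 3650.0

#: the trend-analysis test family: 8 groups × 2 isotopes
TREND_FAMILY_SIZE = 16
TREND_ALPHA = 0.001


@dataclass(frozen=True)
class TrendResult:
    """One group × isotope temporal regression."""

    group: str
    isotope: str
    intercept: float  # ‰ at the origin date
    slope: float  # ‰ per day
    slope_p: float
    kendall_tau: float
    n: int
    significant: bool
    decadal_delta: float | None  # ‰ per decade, only when significant


@dataclass
class GroupComparison:
    """Kruskal–Wallis + Dunn outcome for one factor × isotope."""

    factor: str
    isotope: str
    summary: pd.DataFrame  # per group: n, min, max, median, mean, sd
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adj
    letters: dict[str, str]
    alpha: float
    dropped_groups: list[str] = field(default_factory=list)


def decadal_delta(slope: float) -> float:
    """Convert a per-day slope (‰/day) to ‰ per decade (× 3650)."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return float(slope) * DAYS_PER_DECADE


def fit_time_trend(
    values: Sequence[float],
    days: Sequence[float],
    group: str = "",
    isotope: str = "",
    alpha: float = TREND_ALPHA / TREND_FAMILY_SIZE,
) -> TrendResult:
    """OLS + Kendall τ-b trend of an isotope series against Julian day.

    ``alpha`` is the already-adjusted significance level the slope
    p-value is judged against (default 0.001/16, the conservative
    family-wise level for a 16-test trend family); the decadal Δ field
    is populated only for significant slopes.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 observations.
    SingularFitError
        All days equal.
    """
    values = np.asarray(values, dtype=float)
    days = np.asarray(days, dtype=float)
    if len(values) != len(days):
        raise ValueError("values and days differ in length")
    if len(values) < 3:
        raise InsufficientDataError(f"n={len(values)} < 3")
    if np.ptp(days) == 0:
        raise SingularFitError("all collection days identical")
    ols = stats.linregress(days, values)
    tau = stats.kendalltau(days, values, variant="b").statistic
    significant = bool(ols.pvalue < alpha)
    return TrendResult(
        group=group,
        isotope=isotope,
        intercept=float(ols.intercept),
        slope=float(ols.slope),
        slope_p=float(ols.pvalue),
        kendall_tau=float(tau),
        n=len(values),
        significant=significant,
        decadal_delta=decadal_delta(ols.slope) if significant else None,
    )


def _dunn_pairwise(
    groups: Mapping[str, np.ndarray], alpha: float
) -> pd.DataFrame:
    """Dunn (1964) pairwise z-tests from joint mean ranks with tie
    correction, Bonferroni-adjusted across all pairs."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[start:start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    tie_sizes = np.unique(pooled, return_counts=True)[1]
    tie_term = (tie_sizes**3 - tie_sizes).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append({
                "group_a": a, "group_b": b, "z": float(z),
                "p_raw": float(p_raw),
                "p_adj": float(min(1.0, p_raw * n_pairs)),
            })
    return pd.DataFrame(rows)


def _letter_display(
    labels: Sequence[str], pairwise: pd.DataFrame, alpha: float
) -> dict[str, str]:
    """Compact letter display: two groups share a letter iff their
    adjusted pairwise p ≥ alpha (insert-and-absorb algorithm)."""
    different = [
        (r.group_a, r.group_b)
        for r in pairwise.itertuples()
        if r.p_adj < alpha
    ]
    # insert-and-absorb: split any set holding a significant pair into
    # the two sets lacking one member each, then drop subsets
    cliques: list[set[str]] = [set(labels)]
    for a, b in different:
        next_cliques: list[set[str]] = []
        for clique in cliques:
            if a in clique and b in clique:
                next_cliques.append(clique - {a})
                next_cliques.append(clique - {b})
            else:
                next_cliques.append(clique)
        cliques = [
            c for i, c in enumerate(next_cliques)
            if c and not any(
                c <= d for j, d in enumerate(next_cliques)
                if i != j and not (c == d and i > j)
            )
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in labels}
    for letter, clique in zip(alphabet, cliques):
        for g in labels:
            if g in clique:
                letters[g] += letter
    return letters


def group_compare(
    groups: Mapping[str, Sequence[float]],
    factor: str = "",
    isotope: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Kruskal–Wallis test with Dunn post-hoc pairwise comparisons.

    Groups with fewer than 2 observations are dropped with a warning
    entry rather than failing the whole comparison.  The compact
    letter display is audited on construction: two groups carry
    disjoint letters iff their Bonferroni-adjusted Dunn p < alpha.
    """
    clean: dict[str, np.ndarray] = {}
    dropped = []
    for g, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) < 2:
            dropped.append(g)
        else:
            clean[g] = arr
    if len(clean) < 2:
        raise InsufficientDataError(
            "need >= 2 groups with >= 2 observations each")

    summary = pd.DataFrame(
        [
            {
                "group": g, "n": len(v), "min": v.min(), "max": v.max(),
                "median": float(np.median(v)), "mean": v.mean(),
                "sd": v.std(ddof=1),
            }
            for g, v in clean.items()
        ]
    ).set_index("group")

    kw = stats.kruskal(*clean.values())
    pairwise = _dunn_pairwise(clean, alpha)
    letters = _letter_display(list(clean), pairwise, alpha)

    # consistency audit: shared letter <=> not significantly different
    for r in pairwise.itertuples():
        shared = set(letters[r.group_a]) & set(letters[r.group_b])
        if (r.p_adj < alpha) == bool(shared):
            raise AssertionError(
                "letter display inconsistent with adjusted p-values")

    return GroupComparison(
        factor=factor,
        isotope=isotope,
        summary=summary,
        kw_statistic=float(kw.statistic),
        kw_p=float(kw.pvalue),
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        dropped_groups=dropped,
    )


def depth_correlation(
    values: Sequence[float],
    depths: Sequence[float],
    transform: str = "none",
    method: str = "spearman",
):
    """Correlation between an isotope series and collection depth.

    ``transform='log10'`` regresses against log₁₀ depth (used where it
    improves residual normality); ``method`` is ``'pearson_on_ols'``
    for the parametric regression r or ``'spearman'`` when regression
    assumptions fail.  The caller chooses, mirroring per-habitat
    judgment calls.

    Returns an object with ``statistic`` (the correlation coefficient)
    and ``pvalue``.
    """
    values = np.asarray(values, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if len(values) != len(depths):
        raise ValueError("values and depths differ in length")
    if transform == "log10":
        if (depths <= 0).any():
            raise ValueError("log10 transform requires strictly positive "
                             "depths")
        depths = np.log10(depths)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if method == "spearman":
        return stats.spearmanr(depths, values)
    if method == "pearson_on_ols":
        return stats.pearsonr(depths, values)
    raise ValueError(f"unknown method {method!r}")


def trend_report(results: Sequence[TrendResult]) -> pd.DataFrame:
    """Tabulate trend results in the standard report layout
    (group, isotope, intercept, slope, slope p, τ, decadal Δ), with
    decadal Δ rounded to one decimal and shown only when significant."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "isotope": r.isotope,
                "intercept": round(r.intercept, 1),
                "slope": r.slope,
                "slope_p": r.slope_p,
                "kendall_tau": r.kendall_tau,
                "decadal_delta": (
                    round(r.decadal_delta, 1) if r.significant else None
                ),
                "n": r.n,
            }
            for r in results
        ]
    )


def summary_report(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Stack per-group summary statistics (n, min, max, median,
    mean, sd) across comparisons into one long table."""
    frames = []
    for c in comparisons:
        s = c.summary.reset_index()
        s.insert(0, "isotope", c.isotope)
        s.insert(0, "factor", c.factor)
        frames.append(s)
    return pd.concat(frames, ignore_index=True)
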