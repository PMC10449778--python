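"""Age-group statistics: normality-gated omnibus test, pairwise letters, report.

The chain mirrors the analysis protocol of the emulated study:

1. Fit a one-way group-means model; Shapiro-Wilk on the pooled residuals at
   a 10% level decides between one-way ANOVA (residuals normal) and
   Kruskal-Wallis (otherwise).
2. When the omnibus test is significant at alpha (default 5%), compare
   groups pairwise: Tukey HSD after ANOVA; Dunn rank z-tests (midranks, tie
   correction) with Holm adjustment after Kruskal-Wallis (a Nemenyi /
   Tukey-on-ranks variant is available as a switch).
3. Summarize the pairwise pattern as a compact letter display
   (insert-and-absorb): two groups share a letter iff their adjusted
   pairwise comparison is non-significant; 'a' is anchored to the group
   with the smallest mean.  Non-significant omnibus -> dashes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OmnibusResult",
    "PairwiseResult",
    "GroupComparison",
    "ZeroVarianceError",
    "omnibus",
    "tukey_pairwise",
    "dunn_pairwise",
    "nemenyi_pairwise",
    "compact_letters",
    "pairwise_letters",
    "compare_groups",
    "build_report",
    "Report",
]

NO_LETTER = "-"


class ZeroVarianceError(ValueError):
    """Raised when all observations are identical (no test possible)."""


@dataclass
class OmnibusResult:
    test: str            # "ANOVA" or "Kruskal-Wallis"
    pvalue: float
    normality_p: float


@dataclass
class PairwiseResult:
    pvalues: pd.DataFrame        # symmetric adjusted p matrix (1 on diagonal)
    letters: dict[str, str]      # group -> letter string (or "-")
    method: str = ""


@dataclass
class GroupComparison:
    metric: str
    test: str
    normality_p: float
    omnibus_p: float
    pairwise_p: pd.DataFrame | None
    letters: dict[str, str]
    alpha: float


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for k, v in groups.items():
        arr = np.asarray(v, dtype=float)
        arr = arr[np.isfinite(arr)]
        out[k] = arr
    return out


def omnibus(
    groups: Mapping[str, Sequence[float]], normality_alpha: float = 0.10
) -> OmnibusResult:
    """Normality-gated omnibus comparison of >= 2 groups.

    Shapiro-Wilk is applied to the pooled residuals of the one-way
    group-means fit; if its p-value is at least ``normality_alpha`` the
    one-way ANOVA p is reported, otherwise the Kruskal-Wallis p.
    """
    g = _as_groups(groups)
    if len(g) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 3 for v in g.values()):
        raise ValueError("each group needs at least 3 values")
    values = list(g.values())
    resid = np.concatenate([v - v.mean() for v in values])
    if np.allclose(resid, 0) and len({v.mean() for v in values}) == 1:
        raise ZeroVarianceError("constant data: omnibus test undefined")
    if np.allclose(resid, resid[0]):
        raise ZeroVarianceError("zero residual variance: normality gate undefined")
    norm_p = float(sps.shapiro(resid).pvalue)
    if norm_p >= normality_alpha:
        stat = sps.f_oneway(*values)
        return OmnibusResult("ANOVA", float(stat.pvalue), norm_p)
    stat = sps.kruskal(*values)
    return OmnibusResult("Kruskal-Wallis", float(stat.pvalue), norm_p)


def _pmatrix(names: Sequence[str], pairs: dict[tuple[str, str], float]) -> pd.DataFrame:
    m = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), p in pairs.items():
        m.loc[a, b] = p
        m.loc[b, a] = p
    return m


def tukey_pairwise(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for all group pairs (after ANOVA)."""
    g = _as_groups(groups)
    names = list(g)
    res = sps.tukey_hsd(*[g[n] for n in names])
    pairs = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        pairs[(names[i], names[j])] = float(res.pvalue[i, j])
    return _pmatrix(names, pairs)


def _rank_stats(g: dict[str, np.ndarray]):
    names = list(g)
    all_vals = np.concatenate([g[n] for n in names])
    n_total = all_vals.size
    ranks = sps.rankdata(all_vals)  # midranks
    mean_ranks = {}
    start = 0
    for n in names:
        k = g[n].size
        mean_ranks[n] = ranks[start : start + k].mean()
        start += k
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    return names, n_total, mean_ranks, tie_term


def dunn_pairwise(groups: Mapping[str, Sequence[float]], adjust: str = "holm") -> pd.DataFrame:
    """Dunn pairwise rank z-tests (tie-corrected), multiplicity-adjusted.

    The standard Kruskal-Wallis follow-up: for groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with T the tie term ``sum(t^3 - t)``; two-sided normal p-values are then
    adjusted (Holm by default).
    """
    g = _as_groups(groups)
    names, n_total, mean_ranks, tie_term = _rank_stats(g)
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    raw = []
    keys = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / g[a].size + 1.0 / g[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw.append(2.0 * sps.norm.sf(abs(z)))
        keys.append((a, b))
    if adjust:
        adj = multipletests(raw, method=adjust)[1]
    else:
        adj = raw
    return _pmatrix(names, dict(zip(keys, adj)))


def nemenyi_pairwise(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Nemenyi (Tukey-on-ranks) pairwise p-values after Kruskal-Wallis."""
    g = _as_groups(groups)
    names, n_total, mean_ranks, tie_term = _rank_stats(g)
    k = len(names)
    tie_corr = 1.0 - tie_term / (n_total**3 - n_total) if n_total > 1 else 1.0
    pairs = {}
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(
            n_total * (n_total + 1) / 24.0 * (1.0 / g[a].size + 1.0 / g[b].size) * tie_corr
        )
        q = abs(mean_ranks[a] - mean_ranks[b]) / se
        pairs[(a, b)] = float(sps.studentized_range.sf(q, k, np.inf))
    return _pmatrix(names, pairs)


def compact_letters(
    pvalues: pd.DataFrame, means: Mapping[str, float], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Produces a minimal letter assignment in which two groups share a letter
    iff their adjusted p-value is >= alpha.  Letters are ordered so that the
    group with the smallest mean carries 'a'.
    """
    names = list(pvalues.index)
    sig_pairs = [
        (a, b)
        for a, b in itertools.combinations(names, 2)
        if pvalues.loc[a, b] < alpha
    ]
    columns: list[set[str]] = [set(names)]
    for a, b in sig_pairs:
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop columns contained in another
        columns = []
        for col in sorted(new_cols, key=len, reverse=True):
            if col and not any(col <= kept for kept in columns):
                columns.append(col)
    # order letters by the smallest group mean inside each column
    order = sorted(names, key=lambda n: means[n])
    rank = {n: i for i, n in enumerate(order)}
    columns.sort(key=lambda col: min(rank[n] for n in col))
    letters = {n: "" for n in names}
    for li, col in enumerate(columns):
        ch = chr(ord("a") + li)
        for n in col:
            letters[n] += ch
    letters = {n: "".join(sorted(s)) for n, s in letters.items()}
    _assert_consistent(pvalues, letters, alpha)
    return letters


def _assert_consistent(pvalues: pd.DataFrame, letters: Mapping[str, str], alpha: float) -> None:
    """Exhaustively check: share a letter <=> adjusted p >= alpha."""
    for a, b in itertools.combinations(pvalues.index, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        nonsig = pvalues.loc[a, b] >= alpha
        if share != nonsig:
            raise AssertionError(
                f"letter display inconsistent for ({a}, {b}): "
                f"share={share}, p={pvalues.loc[a, b]:.4g}, alpha={alpha}"
            )


def pairwise_letters(
    groups: Mapping[str, Sequence[float]],
    test: str,
    alpha: float = 0.05,
    omnibus_p: float | None = None,
    kw_posthoc: str = "dunn",
    force: bool = False,
) -> PairwiseResult:
    """Pairwise adjusted p-values and compact letters for one metric.

    Gated on the omnibus: when ``omnibus_p`` is given and >= alpha (and
    ``force`` is False), no letters are assigned (all dashes), mirroring the
    dashes of a non-significant table row.
    """
    g = _as_groups(groups)
    if omnibus_p is not None and omnibus_p >= alpha and not force:
        return PairwiseResult(
            pvalues=None, letters={n: NO_LETTER for n in g}, method="gated"
        )
    if test.upper().startswith("ANOVA"):
        pm = tukey_pairwise(g)
        method = "tukey_hsd"
    else:
        if kw_posthoc == "dunn":
            pm = dunn_pairwise(g)
            method = "dunn_holm"
        elif kw_posthoc == "nemenyi":
            pm = nemenyi_pairwise(g)
            method = "nemenyi"
        else:
            raise ValueError(f"unknown kw_posthoc {kw_posthoc!r}")
    means = {n: float(v.mean()) for n, v in g.items()}
    letters = compact_letters(pm, means, alpha)
    return PairwiseResult(pvalues=pm, letters=letters, method=method)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    metric: str = "",
    alpha: float = 0.05,
    normality_alpha: float = 0.10,
    kw_posthoc: str = "dunn",
) -> GroupComparison:
    """Full chain for one metric: gate, omnibus, pairwise letters."""
    omni = omnibus(groups, normality_alpha=normality_alpha)
    pw = pairwise_letters(
        groups, omni.test, alpha=alpha, omnibus_p=omni.pvalue, kw_posthoc=kw_posthoc
    )
    return GroupComparison(
        metric=metric,
        test=omni.test,
        normality_p=omni.normality_p,
        omnibus_p=omni.pvalue,
        pairwise_p=pw.pvalues,
        letters=pw.letters,
        alpha=alpha,
    )


@dataclass
class Report:
    """Tables-style report: one row per (site, metric, age group)."""

    frame: pd.DataFrame
    comparisons: dict = field(default_factory=dict)  # (site, metric) -> GroupComparison

    def to_text(self) -> str:
        lines = []
        for (site, metric), sub in self.frame.groupby(["site", "metric"], sort=True):
            first = sub.iloc[0]
            test = first["test"]
            lines.append(f"{site} / {metric}   p = {first['omnibus_p']:.4g} ({test})")
            for _, row in sub.iterrows():
                lines.append(
                    f"  {row['age_group']:>8}  mean (sd) = {row['mean']:.4g} "
                    f"({row['sd']:.4g})  n = {row['n']:d}  {row['letters']}"
                )
        return "\n".join(lines)


def build_report(
    table: pd.DataFrame,
    alpha: float = 0.05,
    normality_alpha: float = 0.10,
    kw_posthoc: str = "dunn",
    group_order: Sequence[str] | None = None,
) -> Report:
    """Group-comparison report from a long metric table.

    ``table`` needs columns (subject, site, age_group, metric, value); each
    (subject, site, metric) must appear once.  Groups with missing data are
    reported as NA and excluded from the tests; metrics for which the test
    is undefined (constant data) carry NaN p-values.
    """
    required = {"subject", "site", "age_group", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metric table is missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject", "site", "metric"])
    if dup.any():
        raise ValueError("each (subject, site, metric) must appear exactly once")
    rows = []
    comparisons = {}
    for (site, metric), sub in table.groupby(["site", "metric"], sort=True):
        groups_present = (
            list(group_order) if group_order is not None
            else sorted(sub["age_group"].unique())
        )
        g = {
            grp: sub.loc[sub["age_group"] == grp, "value"].to_numpy()
            for grp in groups_present
        }
        testable = {k: v[np.isfinite(v)] for k, v in g.items() if np.isfinite(v).sum() >= 3}
        comp = None
        if len(testable) >= 2:
            try:
                comp = compare_groups(
                    testable,
                    metric=metric,
                    alpha=alpha,
                    normality_alpha=normality_alpha,
                    kw_posthoc=kw_posthoc,
                )
            except ZeroVarianceError:
                comp = None
        if comp is not None:
            comparisons[(site, metric)] = comp
        for grp in groups_present:
            vals = g.get(grp, np.array([]))
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "site": site,
                    "metric": metric,
                    "age_group": grp,
                    "n": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size >= 2 else np.nan,
                    "test": comp.test if comp else "NA",
                    "normality_p": comp.normality_p if comp else np.nan,
                    "omnibus_p": comp.omnibus_p if comp else np.nan,
                    "letters": (comp.letters.get(grp, NO_LETTER) if comp else NO_LETTER),
                }
            )
    frame = pd.DataFrame(rows)
    return Report(frame=frame, comparisons=comparisons)
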