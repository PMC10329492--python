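"""Statistical layer for the interface landscape comparisons.

Group comparisons of concavity use (by CDR label, amino acid, IMGT position,
or antibody format) are assessed by classical one-way ANOVA followed by
Tukey HSD post-hoc pairwise comparisons (Tukey-Kramer handling of unequal
group sizes, via the studentized-range distribution). Length-concavity
relationships and the antibody-antigen concavity coupling are Pearson
correlations with p-values from the t transform of r. The observation unit
is a per-complex summary (one value per complex per group) throughout; all
computations are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "CorrelationResult",
    "one_way_anova",
    "pearson",
    "length_concavity_correlation",
    "ab_ag_concavity_coupling",
    "cdr_length_table",
    "plot_length_concavity",
]

MIN_DISTINCT_LENGTHS = 4


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame = field(default_factory=pd.DataFrame)
    # tukey columns: group1, group2, mean_diff, p_adj, lower, upper, reject


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    slope: float
    intercept: float
    flag: str = ""  # "" | "insufficient_length_diversity" | "undefined" | "too_few"

    @property
    def is_reportable(self) -> bool:
        return self.flag == ""


def one_way_anova(table: pd.DataFrame, group_col: str = "group", value_col: str = "value") -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD post-hoc comparisons.

    ``table`` holds one observation row per (complex, group). Requires at
    least two groups with two observations each. The fully degenerate case
    (all values equal, no variance anywhere) is reported as F = 0, p = 1.
    """
    groups = [g[value_col].to_numpy(dtype=float) for _, g in table.groupby(group_col)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA requires >=2 groups with >=2 observations each")
    values = np.concatenate(groups)
    n = len(values)
    k = len(groups)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n - k
    if ss_within == 0.0 and ss_between == 0.0:
        f, p = 0.0, 1.0
    elif ss_within == 0.0:
        f, p = np.inf, 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(f, df_between, df_within))
    tukey = _tukey_table(table, group_col, value_col)
    return AnovaResult(
        f_statistic=float(f), df_between=df_between, df_within=df_within,
        p_value=float(p), tukey=tukey,
    )


def _tukey_table(table: pd.DataFrame, group_col: str, value_col: str) -> pd.DataFrame:
    values = table[value_col].to_numpy(dtype=float)
    if np.ptp(values) == 0.0:
        # degenerate: statsmodels cannot studentize a zero-variance pooled fit
        labels = sorted(table[group_col].unique())
        rows = [
            dict(group1=a, group2=b, mean_diff=0.0, p_adj=1.0, lower=0.0, upper=0.0, reject=False)
            for i, a in enumerate(labels) for b in labels[i + 1:]
        ]
        return pd.DataFrame(rows)
    res = pairwise_tukeyhsd(values, table[group_col].to_numpy(), alpha=0.05)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    frame = frame.rename(
        columns={"meandiff": "mean_diff", "p-adj": "p_adj"}
    )[["group1", "group2", "mean_diff", "p_adj", "lower", "upper", "reject"]]
    # recompute adjusted p at full precision (the summary rounds to 4 digits)
    frame["p_adj"] = res.pvalues
    frame["mean_diff"] = res.meandiffs
    return frame


def pearson(x, y) -> CorrelationResult:
    """Pearson r with p from the t transform, plus the least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        return CorrelationResult(np.nan, np.nan, n, np.nan, np.nan, flag="too_few")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return CorrelationResult(np.nan, np.nan, n, np.nan, np.nan, flag="undefined")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return CorrelationResult(
        r=float(r), p_value=float(p), n=n, slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def length_concavity_correlation(
    table: pd.DataFrame,
    min_distinct_lengths: int = MIN_DISTINCT_LENGTHS,
) -> dict[str, CorrelationResult]:
    """Per-CDR correlation between loop length and deepest concavity use.

    ``table`` columns: complex_id, cdr_label, length, deepest. A label whose
    length values take fewer than ``min_distinct_lengths`` distinct values is
    flagged as having insufficient length diversity rather than reported
    (correlations over one to three length subgroups are not meaningful).
    """
    out: dict[str, CorrelationResult] = {}
    for label, sub in table.groupby("cdr_label"):
        res = pearson(sub["length"], sub["deepest"])
        if res.flag == "" and sub["length"].nunique() < min_distinct_lengths:
            res.flag = "insufficient_length_diversity"
        out[str(label)] = res
    return out


def ab_ag_concavity_coupling(table: pd.DataFrame) -> dict[str, CorrelationResult]:
    """Correlation between antibody-side and antigen-side deepest concavity.

    ``table`` columns: complex_id, ab_format, ab_deepest, ag_deepest. One
    CorrelationResult per antibody format, computed over complexes.
    """
    out: dict[str, CorrelationResult] = {}
    for fmt, sub in table.groupby("ab_format"):
        out[str(fmt)] = pearson(sub["ab_deepest"], sub["ag_deepest"])
    return out


def cdr_length_table(records_cdrs: pd.DataFrame) -> pd.DataFrame:
    """Per (format, CDR label) length distribution summary.

    ``records_cdrs`` columns: complex_id, ab_format, cdr_label, length.
    Labels absent from every complex are simply omitted.
    """
    grouped = records_cdrs.groupby(["ab_format", "cdr_label"])["length"]
    summary = grouped.agg(
        n="count", mean="mean", variance=lambda s: float(np.var(s, ddof=0)),
        min="min", max="max",
    ).reset_index()
    summary["range"] = summary["max"] - summary["min"]
    return summary


def plot_length_concavity(table: pd.DataFrame, path) -> None:
    """Scatter of CDR length vs deepest concavity, one panel per label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted(table["cdr_label"].unique())
    fig, axes = plt.subplots(1, max(len(labels), 1), figsize=(3 * max(len(labels), 1), 3), squeeze=False)
    for ax, label in zip(axes[0], labels):
        sub = table[table["cdr_label"] == label]
        ax.scatter(sub["length"], sub["deepest"], s=12, alpha=0.7)
        res = pearson(sub["length"], sub["deepest"])
        if res.is_reportable:
            xs = np.linspace(sub["length"].min(), sub["length"].max(), 20)
            ax.plot(xs, res.intercept + res.slope * xs, color="crimson", lw=1)
            ax.set_title(f"{label} (r={res.r:.2f})")
        else:
            ax.set_title(label)
        ax.set_xlabel("CDR length")
        ax.set_ylabel("deepest R_inaccess (A)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
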