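"""Condition-level aggregation and the study's statistics.

The biological replicate is the unit of analysis: fields are technical
pseudo-replicates and are averaged into one value per replicate before
any testing, so n equals the number of replicates (typically 3), not the
number of fields.  Condition means are compared by one-way ANOVA followed
by Holm-Šídák-adjusted pairwise comparisons, and summaries are reported
as mean ± SD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image_io import PlateLayout

__all__ = [
    "ConditionSummary",
    "PosthocTable",
    "aggregate",
    "replicate_means",
    "one_way_anova",
    "holm_sidak",
    "pairwise_posthoc",
    "report",
    "significance_stars",
]


@dataclass
class ConditionSummary:
    condition: str
    replicate_means: list[float]
    mean: float
    sd: float
    n_replicates: int

    @classmethod
    def from_replicates(cls, condition: str, values: list[float]) -> "ConditionSummary":
        arr = np.asarray(values, dtype=float)
        return cls(
            condition=condition,
            replicate_means=list(map(float, arr)),
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            n_replicates=int(arr.size),
        )


@dataclass
class PosthocTable:
    """Pairwise comparisons with raw and Holm-Šídák-adjusted p-values."""

    comparisons: list[dict]  # group_a, group_b, raw_p, adjusted_p, significant
    alpha: float = 0.05

    def adjusted(self, a: str, b: str) -> float:
        for c in self.comparisons:
            if {c["group_a"], c["group_b"]} == {a, b}:
                return c["adjusted_p"]
        raise KeyError((a, b))

    def significant(self, a: str, b: str) -> bool:
        return self.adjusted(a, b) < self.alpha


def replicate_means(
    per_field: pd.DataFrame,
    threshold: float,
    value_col: str = "index",
) -> pd.DataFrame:
    """Collapse fields to one mean per (condition, replicate).

    Rejected fields are excluded.  ``per_field`` is the long-form results
    table (one row per field per threshold).
    """
    df = per_field.copy()
    if "rejected" in df.columns:
        df = df[~df["rejected"].astype(bool)]
    if "threshold" in df.columns:
        df = df[np.isclose(df["threshold"].astype(float), threshold)]
    df = df.dropna(subset=[value_col])
    if df.empty:
        raise ValueError(f"no accepted fields at threshold {threshold}")
    grouped = (
        df.groupby(["condition", "replicate"], sort=False)[value_col]
        .mean()
        .reset_index()
    )
    return grouped


def aggregate(
    per_field: pd.DataFrame,
    layout: PlateLayout | None,
    threshold: float,
    value_col: str = "index",
) -> list[ConditionSummary]:
    """Field -> replicate mean -> condition mean ± SD at one threshold."""
    grouped = replicate_means(per_field, threshold, value_col)
    order = (
        layout.conditions
        if layout is not None
        else list(dict.fromkeys(grouped["condition"]))
    )
    out = []
    for cond in order:
        vals = grouped.loc[grouped["condition"] == cond, value_col].tolist()
        if vals:
            out.append(ConditionSummary.from_replicates(cond, vals))
    return out


def one_way_anova(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MSB/MSW with (k-1, N-k) df.

    Each group must have >= 2 values.  When the between-group sum of
    squares is exactly zero (identical group means) F = 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs >= 2 values")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, n_total - k
    msb = ssb / df_b
    msw = ssw / df_w
    if msb == 0.0:
        return 0.0, 1.0
    if msw == 0.0:
        return float("inf"), 0.0
    f = msb / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def holm_sidak(raw_p: list[float]) -> list[float]:
    """Holm's step-down procedure with Šídák adjustment.

    Sorted ascending, the i-th smallest of m p-values becomes
    1 - (1 - p_(i))^(m - i + 1); monotone non-decreasing is enforced by a
    running maximum, values are clamped at 1 and returned in input order.
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError(f"p-values must lie in [0, 1]: {raw_p}")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adj = np.empty_like(adj_sorted)
    adj[order] = adj_sorted
    return [float(a) for a in adj]


def pairwise_posthoc(
    grouped: pd.DataFrame,
    conditions: list[str] | None = None,
    alpha: float = 0.05,
    reference: str | None = None,
    value_col: str = "index",
) -> PosthocTable:
    """Pairwise t comparisons with the pooled within-group variance.

    Pairs share the ANOVA's pooled error (MSW with N-k df); raw p-values
    are then Holm-Šídák adjusted across the comparison family.  With
    ``reference`` set, only comparisons against that condition are tested;
    default is all pairs.
    """
    conds = conditions or list(dict.fromkeys(grouped["condition"]))
    groups = {
        c: grouped.loc[grouped["condition"] == c, value_col].to_numpy(dtype=float)
        for c in conds
    }
    arrs = list(groups.values())
    n_total = sum(a.size for a in arrs)
    k = len(arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_w = n_total - k
    msw = ssw / df_w if df_w > 0 else 0.0

    if reference is not None:
        pairs = [(reference, c) for c in conds if c != reference]
    else:
        pairs = list(itertools.combinations(conds, 2))

    raw = []
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        se = np.sqrt(msw * (1.0 / ga.size + 1.0 / gb.size))
        if se == 0.0:
            raw.append(1.0 if ga.mean() == gb.mean() else 0.0)
            continue
        tstat = (ga.mean() - gb.mean()) / se
        raw.append(float(2.0 * sps.t.sf(abs(tstat), df_w)))
    adjusted = holm_sidak(raw)
    comparisons = [
        {
            "group_a": a,
            "group_b": b,
            "raw_p": rp,
            "adjusted_p": ap,
            "significant": ap < alpha,
        }
        for (a, b), rp, ap in zip(pairs, raw, adjusted)
    ]
    return PosthocTable(comparisons=comparisons, alpha=alpha)


def significance_stars(p: float) -> str:
    """Figure convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def report(
    summaries: list[ConditionSummary],
    posthoc: PosthocTable,
    out_prefix,
    reference: str | None = None,
    threshold: float | None = None,
) -> tuple:
    """Write the condition-level CSV and a mean ± SD bar figure.

    Stars above each bar mark its Holm-Šídák-adjusted comparison against
    the reference condition (first condition when unspecified).
    """
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = Path(out_prefix)
    ref = reference or (summaries[0].condition if summaries else None)

    rows = []
    for s in summaries:
        stars = ""
        if ref is not None and s.condition != ref:
            try:
                stars = significance_stars(posthoc.adjusted(ref, s.condition))
            except KeyError:
                stars = ""
        rows.append(
            {
                "condition": s.condition,
                "threshold": threshold,
                "mean": s.mean,
                "sd": s.sd,
                "n_replicates": s.n_replicates,
                "stars_vs_reference": stars,
            }
        )
    csv_path = out_prefix.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.9g")

    fig, ax = plt.subplots(figsize=(1.2 * max(len(summaries), 2) + 1, 3.2))
    xs = np.arange(len(summaries))
    means = [s.mean for s in summaries]
    sds = [s.sd for s in summaries]
    ax.bar(xs, means, yerr=sds, capsize=3, color="#7d9fc4", edgecolor="k")
    for x, s, row in zip(xs, summaries, rows):
        if row["stars_vs_reference"]:
            ax.text(
                x,
                s.mean + s.sd + 0.02 * max(means + [0.1]),
                row["stars_vs_reference"],
                ha="center",
            )
    ax.set_xticks(xs)
    ax.set_xticklabels([s.condition for s in summaries], rotation=30, ha="right")
    label = "TOLLES:YPet index"
    if threshold is not None:
        label += f" (t > {threshold:g})"
    ax.set_ylabel(label)
    fig.tight_layout()
    fig_path = out_prefix.with_suffix(".png")
    fig.savefig(fig_path, dpi=150)
    plt.close(fig)
    return csv_path, fig_path
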