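"""Standardized-difference balance accounting between two cohorts.

The standardized difference of means (SMD) is the scale-free contrast

    binary:      (p1 - p2) / sqrt((p1(1-p1) + p2(1-p2)) / 2)
    continuous:  (m1 - m2) / sqrt((s1^2 + s2^2) / 2)

i.e. the difference in means divided by the pooled standard deviation, with
Bernoulli variances for binary covariates. By the usual convention a
covariate is *balanced* when |SMD| < 0.1; here a covariate counts as
imbalanced when |SMD| >= 0.1 or when the SMD is non-finite (the degenerate
case p1 != p2 with zero pooled variance, e.g. 1 vs 0, which is the most
extreme imbalance of all and is flagged as signed infinity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BALANCE_COLUMNS = [
    "comparison_id", "window_name", "covariate_id", "covariate_kind",
    "stat_target", "stat_comparator", "smd",
]


def _smd(diff: np.ndarray, pooled_var: np.ndarray) -> np.ndarray:
    """diff / sqrt(pooled_var) with the degenerate-denominator conventions:
    0 when the groups agree, signed infinity when they differ but the pooled
    variance is 0."""
    diff = np.asarray(diff, dtype=float)
    pooled_var = np.asarray(pooled_var, dtype=float)
    out = np.zeros_like(diff)
    ok = pooled_var > 0.0
    np.divide(diff, np.sqrt(pooled_var, where=ok, out=np.ones_like(pooled_var)),
              where=ok, out=out)
    degenerate = (~ok) & (diff != 0.0)
    out[degenerate] = np.sign(diff[degenerate]) * np.inf
    return out


def smd_binary(p1, p2):
    """SMD between two proportions (scalar or array)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = _smd(p1 - p2, (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    return out.item() if out.ndim == 0 else out


def smd_continuous(m1, s1, m2, s2):
    """SMD between two means with standard deviations (scalar or array)."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("standard deviations must be nonnegative")
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    out = _smd(m1 - m2, (s1**2 + s2**2) / 2.0)
    return out.item() if out.ndim == 0 else out


_KEY = ["window_name", "covariate_id", "covariate_kind"]


def compare_cohorts(
    summary_target: pd.DataFrame, summary_comparator: pd.DataFrame
) -> pd.DataFrame:
    """One SMD row per covariate x window between two covariate summaries.

    Both summaries must cover the same covariate universe and windows
    (guaranteed when both were extracted from the same dataset).
    """
    t = summary_target.set_index(_KEY)
    c = summary_comparator.set_index(_KEY)
    if set(t.index) != set(c.index):
        raise ValueError("summaries cover different covariate universes or windows")
    c = c.reindex(t.index)
    merged = pd.DataFrame(
        {
            "stat_target": t.statistic,
            "disp_target": t.dispersion,
            "stat_comparator": c.statistic,
            "disp_comparator": c.dispersion,
        }
    ).reset_index()
    binary = merged.covariate_kind.to_numpy() == "binary"
    smd = np.empty(len(merged))
    smd[binary] = smd_binary(
        merged.stat_target.to_numpy()[binary], merged.stat_comparator.to_numpy()[binary]
    )
    cont = ~binary
    smd[cont] = smd_continuous(
        merged.stat_target.to_numpy()[cont],
        merged.disp_target.to_numpy()[cont],
        merged.stat_comparator.to_numpy()[cont],
        merged.disp_comparator.to_numpy()[cont],
    )
    cid_t = summary_target.cohort_id.iloc[0] if len(summary_target) else "target"
    cid_c = summary_comparator.cohort_id.iloc[0] if len(summary_comparator) else "comparator"
    merged["comparison_id"] = f"{cid_t}_vs_{cid_c}"
    merged["smd"] = smd
    return merged[BALANCE_COLUMNS]


def count_imbalanced(balance: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Imbalanced-covariate counts per comparison x window.

    A covariate is imbalanced when |SMD| >= threshold or the SMD is
    non-finite; non-finite SMDs are also reported separately.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    b = balance.copy()
    b["imbalanced"] = (b.smd.abs() >= threshold) | ~np.isfinite(b.smd)
    b["nonfinite"] = ~np.isfinite(b.smd)
    out = (
        b.groupby(["comparison_id", "window_name"], sort=False)
        .agg(
            n_imbalanced=("imbalanced", "sum"),
            n_total=("imbalanced", "size"),
            n_nonfinite=("nonfinite", "sum"),
        )
        .reset_index()
    )
    out["fraction"] = out.n_imbalanced / out.n_total
    return out


def export_scatter(
    summary_target: pd.DataFrame, summary_comparator: pd.DataFrame
) -> pd.DataFrame:
    """Plot-ready proportion-vs-proportion table (binary covariates only):
    one row per covariate x window, each row a dot on a scatter panel."""
    t = summary_target[summary_target.covariate_kind == "binary"].set_index(_KEY)
    c = summary_comparator[summary_comparator.covariate_kind == "binary"].set_index(_KEY)
    if set(t.index) != set(c.index):
        raise ValueError("summaries cover different covariate universes or windows")
    c = c.reindex(t.index)
    out = pd.DataFrame(
        {"proportion_target": t.statistic, "proportion_comparator": c.statistic}
    ).reset_index()
    return out[["covariate_id", "window_name", "proportion_target", "proportion_comparator"]]


def render_imbalance_table(report: pd.DataFrame, window_order: list[str] | None = None) -> str:
    """Markdown matrix of 'n/N (%)' cells: rows = target-comparator pairs,
    columns = extraction windows."""
    windows = window_order or list(dict.fromkeys(report.window_name))
    lines = ["| Target–comparator pair | " + " | ".join(windows) + " |",
             "|---" * (len(windows) + 1) + "|"]
    for comp, grp in report.groupby("comparison_id", sort=False):
        cells = []
        g = grp.set_index("window_name")
        for w in windows:
            if w in g.index:
                r = g.loc[w]
                cells.append(f"{int(r.n_imbalanced)}/{int(r.n_total)} ({100 * r.fraction:.1f}%)")
            else:
                cells.append("—")
        lines.append(f"| {comp} | " + " | ".join(cells) + " |")
    return "\n".join(lines)
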