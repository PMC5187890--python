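"""Survival quantification, group comparisons and report assembly.

The comparison layer follows the classic bench workflow: one-way ANOVA
as the gate, then unpaired two-sample t-tests (pooled-variance Student
by default, Welch behind a flag), significance stars at p < 0.05 /
0.01 / 0.001, and no multiple-testing correction unless Bonferroni is
explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "star_label",
    "unpaired_t_test",
    "one_way_anova",
    "survival_percent",
    "bonferroni",
    "build_report",
]


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Bonferroni-adjusted p-values (optional; no correction is applied
    anywhere by default)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def star_label(p_value: float) -> str:
    """Map a p-value to the conventional significance stars."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError("p-value must be in [0, 1]")
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


@dataclass
class TestResult:
    """Outcome of a hypothesis test with its star label."""

    statistic: float
    df: float
    p_value: float
    test: str
    groups: tuple[str, ...] = ()
    stars: str = "ns"
    note: str = ""


def unpaired_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_variance: bool = True,
    labels: tuple[str, str] = ("A", "B"),
) -> TestResult:
    """Two-sided two-sample t-test (pooled Student by default).

    Degenerate input - zero variance in both groups with equal means -
    is reported as p = 1 with a note rather than NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return TestResult(
            statistic=0.0,
            df=a.size + b.size - 2,
            p_value=1.0,
            test="t (pooled)" if equal_variance else "t (Welch)",
            groups=labels,
            stars="ns",
            note="zero variance in both groups with equal means; p set to 1",
        )
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    df = float(res.df)
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        test="t (pooled)" if equal_variance else "t (Welch)",
        groups=labels,
        stars=star_label(float(res.pvalue)),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """Standard one-way F test, the gate before pairwise t-tests."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if all(g.var(ddof=1) == 0 for g in arrays) and len(
        {float(g.mean()) for g in arrays}
    ) == 1:
        df1 = len(arrays) - 1
        df2 = sum(g.size for g in arrays) - len(arrays)
        return TestResult(
            statistic=0.0, df=df1, p_value=1.0, test="one-way ANOVA",
            stars="ns", note=f"identical constant groups (df2={df2})",
        )
    f_stat, p = stats.f_oneway(*arrays)
    df1 = len(arrays) - 1
    return TestResult(
        statistic=float(f_stat),
        df=float(df1),
        p_value=float(p),
        test="one-way ANOVA",
        stars=star_label(float(p)),
    )


def survival_percent(counts: pd.DataFrame) -> pd.DataFrame:
    """Colony survival as a percentage of the untreated time-0 count.

    ``counts`` has columns (strain, replicate, time_min, count); each
    (strain, replicate) series must contain a time-0 reference row.
    Returns the per-row percentages plus, in ``attrs['summary']``, the
    per-(strain, time) mean +/- SD over replicates (SD with the n-1
    denominator; NaN for a single replicate).
    """
    required = {"strain", "replicate", "time_min", "count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table is missing columns: {sorted(missing)}")
    out_rows = []
    for (strain, rep), grp in counts.groupby(["strain", "replicate"]):
        ref_rows = grp[grp["time_min"] == 0]
        if ref_rows.empty:
            raise ValueError(f"no time-0 reference for strain={strain!r}, replicate={rep!r}")
        ref = float(ref_rows["count"].iloc[0])
        if ref <= 0:
            raise ValueError(f"non-positive time-0 count for strain={strain!r}, replicate={rep!r}")
        for _, row in grp.iterrows():
            out_rows.append(
                {
                    "strain": strain,
                    "replicate": rep,
                    "time_min": row["time_min"],
                    "count": row["count"],
                    "reference_count_t0": ref,
                    "percent": 100.0 * row["count"] / ref,
                }
            )
    out = pd.DataFrame(out_rows)
    summary = (
        out.groupby(["strain", "time_min"])["percent"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    out.attrs["summary"] = summary
    return out


def build_report(
    outputs: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    figures: bool = True,
) -> list[Path]:
    """Write tidy CSV summaries (and simple figures) for a set of analyses.

    ``outputs`` maps a section name to a tidy DataFrame; each section
    becomes ``<name>.csv`` in ``outdir``. Sections whose value is None
    or empty are omitted. For recognised section names a matching
    figure is drawn: ``survival`` (percent vs time per strain) and any
    section with columns (group, mean, sd) as a bar chart with error
    bars and star annotations when a ``stars`` column is present.
    Output is deterministic given identical inputs (no timestamps).

    Returns the list of files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not any(df is not None and len(df) for df in outputs.values()):
        raise ValueError("at least one non-empty analysis output is required")

    for name, df in outputs.items():
        if df is None or not len(df):
            continue
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
        if not figures:
            continue
        fig_path = _maybe_plot(name, df, outdir)
        if fig_path is not None:
            written.append(fig_path)
    return written


def _maybe_plot(name: str, df: pd.DataFrame, outdir: Path) -> Path | None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = set(df.columns)
    path = outdir / f"{name}.png"
    if {"strain", "time_min", "percent"} <= cols:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for strain, grp in df.groupby("strain"):
            mean = grp.groupby("time_min")["percent"].mean()
            ax.plot(mean.index, mean.values, marker="o", label=str(strain))
        ax.set_xlabel("time (min)")
        ax.set_ylabel("survival (% of t0)")
        ax.legend()
    elif {"group", "mean"} <= cols:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        x = np.arange(len(df))
        yerr = df["sd"] if "sd" in cols else None
        ax.bar(x, df["mean"], yerr=yerr, capsize=3)
        ax.set_xticks(x)
        ax.set_xticklabels(df["group"].astype(str), rotation=30, ha="right")
        if "stars" in cols:
            top = df["mean"] + (df["sd"] if "sd" in cols else 0)
            for xi, (y, s) in enumerate(zip(top, df["stars"])):
                ax.annotate(str(s), (xi, y), ha="center", va="bottom")
    else:
        return None
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
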