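"""Condition-level aggregation and hypothesis tests.

Per-ring and per-cell measurements are grouped by condition (time point /
carbon source) and biological replicate.  Differences in per-ring metrics
(circumference, companion intensity, R) across conditions are tested with a
classical one-way ANOVA; replicate-level Outside percentages between two
named conditions are compared with a one-tailed paired t-test.  The unit of
analysis for the ANOVA is configurable: per-ring values pooled across
replicates (default) or replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "TestResult",
    "one_way_anova",
    "paired_t_one_tailed",
    "summarize_conditions",
]

SUMMARY_METRICS = ("circumference_nm", "mean_ch2", "R")


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    tails: str
    groups: tuple[str, ...]


def one_way_anova(groups: list[np.ndarray], labels: tuple[str, ...] = ()) -> TestResult:
    """Classical single-factor ANOVA: F = MS_between / MS_within.

    Degrees of freedom are (k - 1, N - k); the p-value is the upper tail of
    the F distribution.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("every group needs at least two values")
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise DegenerateDataError("all values identical; ANOVA undefined")
        f = np.inf
        p = 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return TestResult(
        name="one_way_anova",
        statistic=float(f),
        df=(float(df_b), float(df_w)),
        p_value=p,
        tails="upper",
        groups=labels or tuple(f"group{i}" for i in range(k)),
    )


def paired_t_one_tailed(
    x: np.ndarray, y: np.ndarray, direction: str = "greater",
    labels: tuple[str, str] = ("x", "y"),
) -> TestResult:
    """One-tailed paired t-test on d = y - x.

    ``direction="greater"`` tests whether y exceeds x (upper tail of t);
    ``"less"`` tests the opposite.  df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise ValidationError("need at least two pairs")
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d, 0):
            # no signal at all: t = 0, p = 0.5 by convention of the limit
            return TestResult("paired_t_one_tailed", 0.0, (float(len(d) - 1),),
                              0.5, direction, labels)
        raise DegenerateDataError("zero-variance nonzero differences")
    n = len(d)
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(stats.t.sf(t, df) if direction == "greater" else stats.t.cdf(t, df))
    return TestResult("paired_t_one_tailed", t, (float(df),), p, direction, labels)


def summarize_conditions(
    records: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    outside_pcts: pd.DataFrame | None = None,
    anova_level: str = "ring",
    paired_conditions: tuple[str, str] | None = None,
    paired_direction: str = "greater",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build per-condition summary and test tables.

    Parameters
    ----------
    records
        Per-peroxisome table with ``condition``, ``replicate`` and the metric
        columns (invalid rows, marked by a nonempty ``failure``, are ignored).
    cells
        Optional per-cell table (counted into the summary).
    outside_pcts
        Optional table ``condition, replicate, outside_pct`` of
        replicate-level Outside percentages (input to the paired t-test).
    anova_level
        ``"ring"`` — ANOVA on per-ring values pooled across replicates;
        ``"replicate"`` — on replicate means.
    paired_conditions
        Two condition labels whose replicate-level Outside percentages are
        compared with the one-tailed paired t-test (paired by replicate).
    """
    if anova_level not in ("ring", "replicate"):
        raise ValidationError("anova_level must be 'ring' or 'replicate'")
    req = {"condition", "replicate"}
    if not req.issubset(records.columns):
        raise ValidationError(f"records must carry columns {sorted(req)}")
    valid = records
    if "failure" in records.columns:
        valid = records[records["failure"].fillna("") == ""]

    rows = []
    conditions = sorted(valid["condition"].unique())
    for cond in conditions:
        sub = valid[valid["condition"] == cond]
        row: dict = {"condition": cond, "n_rings": len(sub)}
        if cells is not None and len(cells):
            row["n_cells"] = int((cells["condition"] == cond).sum())
        for metric in SUMMARY_METRICS:
            if metric not in sub.columns:
                continue
            v = pd.to_numeric(sub[metric], errors="coerce").dropna()
            row[f"{metric}_mean"] = v.mean() if len(v) else np.nan
            row[f"{metric}_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
            rep_means = (
                sub.assign(_v=pd.to_numeric(sub[metric], errors="coerce"))
                .groupby("replicate")["_v"].mean()
            )
            row[f"{metric}_replicate_means"] = ";".join(
                f"{r}:{m:.6g}" for r, m in rep_means.items()
            )
        if outside_pcts is not None and len(outside_pcts):
            v = outside_pcts.loc[outside_pcts["condition"] == cond, "outside_pct"].dropna()
            if len(v):
                row["outside_pct_mean"] = v.mean()
                row["outside_pct_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
        rows.append(row)
    summary = pd.DataFrame(rows)

    tests: list[dict] = []
    if len(conditions) >= 2:
        for metric in SUMMARY_METRICS:
            if metric not in valid.columns:
                continue
            groups, labels = [], []
            for cond in conditions:
                sub = valid[valid["condition"] == cond]
                if anova_level == "ring":
                    v = pd.to_numeric(sub[metric], errors="coerce").dropna().to_numpy()
                else:
                    v = (
                        sub.assign(_v=pd.to_numeric(sub[metric], errors="coerce"))
                        .groupby("replicate")["_v"].mean().dropna().to_numpy()
                    )
                if len(v) >= 2:
                    groups.append(v)
                    labels.append(cond)
            if len(groups) >= 2:
                try:
                    res = one_way_anova(groups, tuple(labels))
                except DegenerateDataError:
                    continue
                tests.append(
                    {
                        "test": res.name, "metric": metric, "level": anova_level,
                        "statistic": res.statistic, "df1": res.df[0], "df2": res.df[1],
                        "p_value": res.p_value, "tails": res.tails,
                        "groups": "|".join(res.groups),
                    }
                )
    if paired_conditions is not None and outside_pcts is not None:
        a, b = paired_conditions
        pa = outside_pcts[outside_pcts["condition"] == a].set_index("replicate")["outside_pct"]
        pb = outside_pcts[outside_pcts["condition"] == b].set_index("replicate")["outside_pct"]
        common = sorted(set(pa.index) & set(pb.index))
        if len(common) >= 2:
            res = paired_t_one_tailed(
                pa.loc[common].to_numpy(), pb.loc[common].to_numpy(),
                direction=paired_direction, labels=(a, b),
            )
            tests.append(
                {
                    "test": res.name, "metric": "outside_pct", "level": "replicate",
                    "statistic": res.statistic, "df1": res.df[0], "df2": np.nan,
                    "p_value": res.p_value, "tails": res.tails,
                    "groups": "|".join(res.groups),
                }
            )
    tests_df = pd.DataFrame(
        tests,
        columns=["test", "metric", "level", "statistic", "df1", "df2",
                 "p_value", "tails", "groups"],
    )
    return summary, tests_df
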