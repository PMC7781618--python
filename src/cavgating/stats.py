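"""Cohort aggregation and hypothesis testing.

Summaries are mean +/- SEM per construct and parameter; two groups are
compared with the unpaired equal-variance Student's t-test, three or more
with one-way ANOVA followed by Bonferroni-adjusted pairwise t-tests
(pooled within-group variance, ANOVA error df).  Stars: * p < 0.05,
** p < 0.01, *** p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "summarize",
    "compare_two",
    "compare_many",
    "stars",
    "render_table",
    "GATING_PARAMS",
    "KINETICS_PARAMS",
]

GATING_PARAMS = [
    "v_half_act", "slope_act", "v_rev",
    "v_half_inact", "slope_inact", "non_inactivating_pct",
]
KINETICS_PARAMS = ["r50", "r100", "r250", "r500", "r1000", "r5000"]

_CONVERGENCE_FLAG = {
    **{p: "act_converged" for p in ("v_half_act", "slope_act", "v_rev", "g_max_ns")},
    **{p: "ssi_converged" for p in ("v_half_inact", "slope_inact", "non_inactivating_pct")},
}


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupSummary:
    """Per-construct mean/SEM/n table plus pairwise comparisons.

    summary : DataFrame indexed by (construct, parameter) with columns
        mean, sem, n.
    comparisons : DataFrame with one row per test (reference, test,
        parameter, raw p, Bonferroni-adjusted p, stars).
    """

    summary: pd.DataFrame
    comparisons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["reference", "test", "parameter", "statistic", "df", "p_raw", "p_adj", "stars"]
        )
    )

    def cell(self, construct: str, parameter: str) -> tuple[float, float, int]:
        row = self.summary.loc[(construct, parameter)]
        return float(row["mean"]), float(row["sem"]), int(row["n"])


def included_values(results: pd.DataFrame, construct: str, parameter: str, group_key: str = "construct") -> np.ndarray:
    """Values of one parameter for one group after QC/convergence exclusion."""
    df = results[results[group_key] == construct]
    if "qc_status" in df:
        df = df[df["qc_status"] != "excluded"]
    flag = _CONVERGENCE_FLAG.get(parameter)
    if flag is not None and flag in df:
        df = df[df[flag].astype(bool)]
    vals = df[parameter].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def summarize(
    results: pd.DataFrame, group_key: str = "construct", parameters=None, strict: bool = True
) -> GroupSummary:
    """mean/SEM/n per construct and parameter, excluding QC-failed and
    non-converged cells.  SEM = SD/sqrt(n) (ddof=1).

    A (group, parameter) combination with fewer than two usable cells is an
    error when ``strict`` (the default) and silently skipped otherwise.
    """
    if parameters is None:
        parameters = [p for p in GATING_PARAMS + KINETICS_PARAMS if p in results.columns]
    rows = []
    for construct in pd.unique(results[group_key]):
        for param in parameters:
            vals = included_values(results, construct, param, group_key)
            n = len(vals)
            if n < 2:
                if not strict:
                    continue
                raise ValueError(f"group {construct!r} has < 2 usable cells for {param!r}")
            rows.append(
                {
                    group_key: construct,
                    "parameter": param,
                    "mean": float(np.mean(vals)),
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(n)),
                    "n": n,
                }
            )
    if not rows:
        raise ValueError("no group has enough usable cells to summarise")
    summary = pd.DataFrame(rows).set_index([group_key, "parameter"])
    return GroupSummary(summary=summary)


def compare_two(group_a, group_b) -> tuple[float, int, float]:
    """Unpaired two-sided equal-variance Student's t-test: (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 observations")
    df = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / df
    if pooled == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    posthoc: pd.DataFrame


def compare_many(groups: dict, comparison_set=None) -> AnovaResult:
    """One-way ANOVA with Bonferroni-adjusted pairwise post-hoc t-tests.

    groups : mapping construct -> 1-d array of values.
    comparison_set : list of (reference, test) label pairs.  Default: each
        non-first group vs the first (vs-reference convention); pass all
        pairs for an all-pairs correction.  Raw p-values are multiplied by
        the number of comparisons and clipped at 1.

    With exactly two groups the ANOVA reduces to the t-test (F = t^2).
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if comparison_set is None:
        comparison_set = [(labels[0], other) for other in labels[1:]]
    m = len(comparison_set)

    if len(labels) == 2:
        t, df, p = compare_two(arrays[0], arrays[1])
        f, df_b, df_w, p_f = t * t, 1, df, p
        mse = ((len(arrays[0]) - 1) * np.var(arrays[0], ddof=1) + (len(arrays[1]) - 1) * np.var(arrays[1], ddof=1)) / df
    else:
        f, p_f = sps.f_oneway(*arrays)
        df_b = len(labels) - 1
        df_w = sum(len(a) for a in arrays) - len(labels)
        mse = sum((len(a) - 1) * np.var(a, ddof=1) for a in arrays) / df_w
        f, p_f = float(f), float(p_f)

    rows = []
    for ref, test in comparison_set:
        a, b = np.asarray(groups[ref], float), np.asarray(groups[test], float)
        se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
        if se == 0:
            raise ValueError("zero pooled variance in post-hoc comparison")
        t = (np.mean(b) - np.mean(a)) / se
        p_raw = 2.0 * sps.t.sf(abs(t), df_w)
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {
                "reference": ref,
                "test": test,
                "parameter": "",
                "statistic": float(t),
                "df": df_w,
                "p_raw": float(p_raw),
                "p_adj": float(p_adj),
                "stars": stars(p_adj),
            }
        )
    return AnovaResult(f=f, df_between=df_b, df_within=df_w, p=p_f, posthoc=pd.DataFrame(rows))


def compare_parameters(
    results: pd.DataFrame,
    parameters,
    comparison_set=None,
    group_key: str = "construct",
) -> pd.DataFrame:
    """Run compare_many per parameter on a per-cell results table."""
    labels = list(pd.unique(results[group_key]))
    frames = []
    for param in parameters:
        groups = {c: included_values(results, c, param, group_key) for c in labels}
        groups = {c: v for c, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        res = compare_many(groups, comparison_set)
        ph = res.posthoc.copy()
        ph["parameter"] = param
        ph["anova_f"] = res.f
        ph["anova_p"] = res.p
        frames.append(ph)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _fmt(mean: float, sem: float, star: str = "") -> str:
    return f"{mean:.2f} ± {sem:.2f}{star}"


def render_table(summary: GroupSummary, layout: str = "gating", group_key: str = "construct") -> str:
    """Aligned plain-text table of mean +/- SEM with significance stars.

    layout 'gating': activation (V0.5, slope, Vrev, n) + inactivation
    (V0.5, slope, non-inactivating %, n) columns; layout 'kinetics':
    r50..r5000 + n.
    """
    if layout == "gating":
        act_cols = [("v_half_act", "V0.5,act"), ("slope_act", "slope,act"), ("v_rev", "Vrev")]
        inact_cols = [("v_half_inact", "V0.5,inact"), ("slope_inact", "slope,inact"),
                      ("non_inactivating_pct", "non-inact %")]
    elif layout == "kinetics":
        act_cols = [(p, p) for p in KINETICS_PARAMS]
        inact_cols = []
    else:
        raise ValueError(f"unknown layout {layout!r}")

    present = set(summary.summary.index.get_level_values(1))
    act_cols = [c for c in act_cols if c[0] in present]
    inact_cols = [c for c in inact_cols if c[0] in present]
    headers = ["construct"] + [h for _, h in act_cols] + ["n"]
    if inact_cols:
        headers += [h for _, h in inact_cols] + ["n(inact)"]

    star_of = {}
    for _, row in summary.comparisons.iterrows():
        star_of[(row["test"], row["parameter"])] = row["stars"]

    constructs = list(summary.summary.index.get_level_values(0).unique())
    table_rows = []
    for c in constructs:
        cells = [c]
        for block in (act_cols, inact_cols):
            if not block:
                continue
            n_block = 0
            for p, _h in block:
                if (c, p) in summary.summary.index:
                    mean, sem, n_block = summary.cell(c, p)
                    cells.append(_fmt(mean, sem, star_of.get((c, p), "")))
                else:
                    cells.append("-")
            cells.append(str(n_block))
        table_rows.append(cells)

    widths = [max(len(h), *(len(r[j]) for r in table_rows)) for j, h in enumerate(headers)]
    lines = ["  ".join(h.ljust(w) for h, w in zip(headers, widths))]
    lines.append("  ".join("-" * w for w in widths))
    for r in table_rows:
        lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))
    return "\n".join(lines)
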