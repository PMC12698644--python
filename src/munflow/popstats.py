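"""Cohort-level proportions and the study's statistical comparisons.

Per-replicate metrics (MuN share of double positives, 2nuc/>2nuc split,
per-population percentages) are summarized per condition by medians (the
headline statistic, matching how replicate panels are reported) alongside
means, and knockdown conditions are expressed relative to a named control
(control normalized to 1).

Hypothesis tests follow the study's conventions: one-way ANOVA with Tukey's
post hoc comparisons for >= 2 groups (zero-variance groups permitted — the
degenerate mean-square-error paths are explicit rather than NaN), a
two-sample two-sided t-test for pairs, and Holm–Bonferroni adjustment across
each reported family, all at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestReport",
    "CohortSummary",
    "summarize",
    "holm_adjust",
    "anova_tukey",
    "two_sided_t",
]

ALPHA = 0.05


@dataclass
class TestReport:
    """One hypothesis-test result with its multiplicity adjustment."""

    name: str
    groups: Tuple[str, ...]
    statistic: float
    p_value: float
    p_adjusted: float
    method: str
    adjust_method: str = "holm-bonferroni"
    alpha: float = ALPHA
    flags: str = ""

    @property
    def significant(self) -> bool:
        return self.p_adjusted < self.alpha

    def as_dict(self) -> Dict[str, object]:
        return {
            "name": self.name, "groups": list(self.groups),
            "statistic": self.statistic, "p_value": self.p_value,
            "p_adjusted": self.p_adjusted, "method": self.method,
            "adjust_method": self.adjust_method, "alpha": self.alpha,
            "significant": self.significant, "flags": self.flags,
        }


@dataclass
class CohortSummary:
    """Replicate- and condition-level proportion tables."""

    per_replicate: pd.DataFrame
    per_condition: pd.DataFrame
    relative: Optional[pd.DataFrame] = None
    control: Optional[str] = None


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _replicate_metrics(df: pd.DataFrame, populations: Sequence[str]) -> Dict[str, float]:
    dp = df[df["double_positive"]] if "double_positive" in df.columns else df
    n_dp = len(dp)
    muns = dp[dp["object_class"] == "MuN"]
    n_mun = len(muns)
    out: Dict[str, float] = {
        "n_events": len(df),
        "n_double_positive": n_dp,
        "n_mun": n_mun,
        "mun_proportion": n_mun / n_dp if n_dp else np.nan,
        "frac_2nuc": float((muns["nuclei_count"] == 2).mean()) if n_mun else np.nan,
        "frac_gt2nuc": float((muns["nuclei_count"] > 2).mean()) if n_mun else np.nan,
    }
    for pop in populations:
        n_pop = int((dp["population"] == pop).sum())
        out[f"pct_{pop}"] = 100.0 * n_pop / n_dp if n_dp else np.nan
    return out


def summarize(
    classified: pd.DataFrame,
    condition_col: str = "condition",
    replicate_col: str = "replicate",
    control: Optional[str] = None,
    populations: Optional[Sequence[str]] = None,
) -> CohortSummary:
    """Per-replicate and per-condition cohort metrics.

    ``classified`` is the concatenation of classified cohort tables with
    condition/replicate columns.  When ``control`` names a condition, a
    relative table is added with each condition's median metrics divided by
    the control's medians (control = 1).
    """
    if condition_col not in classified.columns:
        raise KeyError(f"missing condition column {condition_col!r}")
    if populations is None:
        populations = sorted(
            p for p in classified.get("population", pd.Series(dtype=object)).dropna().unique()
        )
    rows = []
    for (cond, rep), sub in classified.groupby([condition_col, replicate_col], sort=True):
        row = {"condition": cond, "replicate": rep}
        row.update(_replicate_metrics(sub, populations))
        rows.append(row)
    per_rep = pd.DataFrame(rows)

    metric_cols = [c for c in per_rep.columns if c not in ("condition", "replicate")]
    med = per_rep.groupby("condition")[metric_cols].median()
    mean = per_rep.groupby("condition")[metric_cols].mean()
    per_cond = med.join(mean, lsuffix="_median", rsuffix="_mean").reset_index()

    relative = None
    if control is not None:
        if control not in set(per_rep["condition"]):
            raise KeyError(f"control condition {control!r} not present")
        ratio_cols = ["mun_proportion"] + [f"pct_{p}" for p in populations]
        ctrl = med.loc[control]
        rel_rows = []
        for cond in med.index:
            row = {"condition": cond}
            for c in ratio_cols:
                denom = ctrl[c]
                row[f"{c}_relative"] = (med.loc[cond, c] / denom) if denom else np.nan
            rel_rows.append(row)
        relative = pd.DataFrame(rel_rows)
    return CohortSummary(per_replicate=per_rep, per_condition=per_cond,
                         relative=relative, control=control)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def _anova_components(groups: Mapping[str, Sequence[float]]):
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    ns = {k: len(v) for k, v in arrs.items()}
    if any(n < 2 for n in ns.values()):
        raise ValueError("each group needs >= 2 values")
    grand = np.concatenate(list(arrs.values()))
    n_total = len(grand)
    k = len(arrs)
    gm = grand.mean()
    ss_between = sum(n * (a.mean() - gm) ** 2 for a, n in zip(arrs.values(), ns.values()))
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    df_b, df_w = k - 1, n_total - k
    return arrs, ns, ss_between / df_b, ss_within / df_w if df_w else np.nan, df_b, df_w


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    alpha: float = ALPHA,
) -> List[TestReport]:
    """One-way ANOVA omnibus F-test plus all pairwise Tukey HSD comparisons,
    Holm-adjusted across the pairwise family.

    Zero within-group variance is permitted: with distinct means the
    statistic is reported as infinite with p = 0 and a ``degenerate-variance``
    flag; with identical means p = 1.
    """
    if len(groups) < 2:
        raise ValueError("anova_tukey needs at least two groups")
    arrs, ns, ms_between, ms_within, df_b, df_w = _anova_components(groups)
    names = list(arrs)

    flags = ""
    if ms_within == 0 or not np.isfinite(ms_within):
        flags = "degenerate-variance"
        if ms_between > 0:
            f_stat, p_omni = np.inf, 0.0
        else:
            f_stat, p_omni = 0.0, 1.0
    else:
        f_stat = ms_between / ms_within
        p_omni = float(stats.f.sf(f_stat, df_b, df_w))

    reports = [TestReport(
        name="anova", groups=tuple(names), statistic=float(f_stat),
        p_value=p_omni, p_adjusted=p_omni, method="one-way ANOVA",
        adjust_method="none", alpha=alpha, flags=flags,
    )]

    pair_reports = []
    raw_ps = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrs[names[i]], arrs[names[j]]
            diff = a.mean() - b.mean()
            if ms_within and np.isfinite(ms_within):
                se = np.sqrt(ms_within / 2.0 * (1.0 / ns[names[i]] + 1.0 / ns[names[j]]))
                q = abs(diff) / se if se else np.inf
                p = float(stats.studentized_range.sf(q, len(names), df_w))
                pflags = ""
            else:
                q = 0.0 if diff == 0 else np.inf
                p = 1.0 if diff == 0 else 0.0
                pflags = "degenerate-variance"
            raw_ps.append(p)
            pair_reports.append(TestReport(
                name=f"tukey:{names[i]} vs {names[j]}",
                groups=(names[i], names[j]), statistic=float(q), p_value=p,
                p_adjusted=p, method="Tukey HSD", alpha=alpha, flags=pflags,
            ))
    adjusted = holm_adjust(raw_ps)
    for rep, p_adj in zip(pair_reports, adjusted):
        rep.p_adjusted = float(p_adj)
    return reports + pair_reports


def two_sided_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
    alpha: float = ALPHA,
    name: str = "t-test",
) -> TestReport:
    """Two-sample two-sided t-test (pooled variance by default, Welch via
    ``welch=True``).  Both groups constant and equal -> p = 1 by convention,
    flagged; constant and different -> p = 0, flagged."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            stat, p, flags = 0.0, 1.0, "degenerate-variance"
        else:
            stat, p, flags = np.inf, 0.0, "degenerate-variance"
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        stat, p, flags = float(res.statistic), float(res.pvalue), ""
    return TestReport(
        name=name, groups=("A", "B"), statistic=stat, p_value=p,
        p_adjusted=p, method="Welch t-test" if welch else "two-sample t-test",
        adjust_method="none", alpha=alpha, flags=flags,
    )
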