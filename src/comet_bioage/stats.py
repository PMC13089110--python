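"""Statistical battery: Pearson, Wilcoxon rank-sum with rank-biserial effect
size, chi-squared association tests and cohort descriptives.

Conventions fixed across the package: all p-values are two-sided; the
rank-sum statistic W is the sum of midranks of the first group; group order
in comparisons is (decelerated, accelerated) and (younger, older), so a
negative rank-biserial means the first-named group tends to be lower.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EstimationError, InputError

#: Largest combined sample size for which the exact rank-sum null
#: distribution is enumerated (C(12,6) = 924 subsets).
EXACT_ENUMERATION_MAX_N = 12


@dataclass
class CorrelationResult:
    n: int
    r: float
    p_value: float


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    W: float
    p_value: float
    rank_biserial: float
    method: str = "normal_approx"


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided t-reference p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise InputError("Pearson correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise EstimationError("correlation undefined: zero variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(n=len(x), r=float(res.statistic), p_value=float(res.pvalue))


def rank_biserial(a, b) -> float:
    """Rank-biserial correlation: mean pairwise dominance of a over b.

    ``(#pairs a>b - #pairs a<b) / (n_a * n_b)``; tied pairs contribute 0.
    Equals ``2*U_a/(n_a*n_b) - 1`` with ties shared between the groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("rank_biserial needs two non-empty groups")
    greater = (a[:, None] > b[None, :]).sum()
    less = (a[:, None] < b[None, :]).sum()
    return float(greater - less) / (a.size * b.size)


def _exact_rank_sum_pvalue(ranks: np.ndarray, n_a: int, w_obs: float,
                           alternative: str) -> float:
    """p-value by full enumeration of which ranks group a occupies."""
    total = comb(len(ranks), n_a)
    sums = np.fromiter((sum(c) for c in combinations(ranks, n_a)), dtype=float, count=total)
    if alternative == "less":
        return float(np.mean(sums <= w_obs))
    if alternative == "greater":
        return float(np.mean(sums >= w_obs))
    lo = np.mean(sums <= w_obs)
    hi = np.mean(sums >= w_obs)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _normal_rank_sum_pvalue(w: float, n_a: int, n_b: int, ties: np.ndarray,
                            alternative: str) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n_a + n_b
    mu = n_a * (n + 1) / 2.0
    tie_term = ties**3 - ties
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term.sum() / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all observations tied; no evidence either way
    d = w - mu
    if alternative == "two-sided":
        z = (abs(d) - 0.5) / np.sqrt(var)
        return float(2.0 * sps.norm.sf(max(z, 0.0)))
    if alternative == "less":
        z = (d + 0.5) / np.sqrt(var)
        return float(sps.norm.cdf(z))
    z = (d - 0.5) / np.sqrt(var)
    return float(sps.norm.sf(z))


def wilcoxon_rank_sum(a, b, group_names=("a", "b"),
                      alternative: str = "two-sided") -> GroupComparison:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent groups.

    W is the sum of midranks of group ``a`` in the pooled sample. The p-value
    is exact (full enumeration of rank assignments) when the combined sample
    has at most 12 tie-free observations, otherwise a tie-corrected normal
    approximation with continuity correction. The rank-biserial correlation
    accompanies the test as effect size.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise InputError(f"unknown alternative '{alternative}'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    no_ties = bool(np.all(tie_counts == 1))
    if pooled.size <= EXACT_ENUMERATION_MAX_N and no_ties:
        p = _exact_rank_sum_pvalue(ranks, a.size, w, alternative)
        method = "exact"
    else:
        p = _normal_rank_sum_pvalue(w, a.size, b.size, tie_counts, alternative)
        method = "normal_approx"
    return GroupComparison(group_a=group_names[0], group_b=group_names[1],
                           n_a=a.size, n_b=b.size, W=w, p_value=p,
                           rank_biserial=rank_biserial(a, b), method=method)


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a 2-way contingency table.

    No continuity correction. Returns ``(statistic, df, p)``.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise InputError("contingency table must be 2-dimensional")
    if np.any(table < 0):
        raise InputError("contingency counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InputError("contingency table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# Descriptives and the primary analysis report


def _median_iqr(s: pd.Series):
    s = s.dropna()
    if s.empty:
        return np.nan, np.nan
    return float(s.median()), float(s.quantile(0.75) - s.quantile(0.25))


def describe_cohorts(participants: pd.DataFrame, cohort_labels: pd.DataFrame,
                     bag_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-cohort descriptives in the study's reporting format.

    mean (SD) for age and BAG; percentages for sex, APOE4 carriers and
    biological-age groups; median (IQR) for CDRSB and education. Cohorts of
    one subject report SD as NA; empty cohorts yield an all-NA row with n=0.
    """
    table = participants.set_index("id").join(cohort_labels, how="left")
    if bag_table is not None:
        table = table.join(bag_table[["bag", "bio_age_group"]], how="left")
    rows = {}
    for cohort in ("CU", "symptomatic", "excluded"):
        sub = table.loc[table["cohort"] == cohort]
        row = {"n": len(sub)}
        if len(sub) == 0:
            rows[cohort] = row
            continue
        row["age_mean"] = float(sub["age_at_mri"].mean())
        row["age_sd"] = float(sub["age_at_mri"].std(ddof=1)) if len(sub) > 1 else np.nan
        row["pct_female"] = float((sub["sex"] == "female").mean() * 100)
        if "apoe4_count" in sub:
            carrier = sub["apoe4_count"].dropna()
            row["pct_apoe4_carrier"] = (float((carrier > 0).mean() * 100)
                                        if len(carrier) else np.nan)
        for col in ("cdrsb", "education"):
            if col in sub:
                med, iqr = _median_iqr(sub[col])
                row[f"{col}_median"], row[f"{col}_iqr"] = med, iqr
        if "bag" in sub:
            bag = sub["bag"].dropna()
            row["n_dnam"] = len(bag)
            row["bag_mean"] = float(bag.mean()) if len(bag) else np.nan
            row["bag_sd"] = float(bag.std(ddof=1)) if len(bag) > 1 else np.nan
            groups = sub["bio_age_group"].dropna()
            for g in ("accelerated", "neutral", "decelerated"):
                row[f"pct_{g}"] = (float((groups == g).mean() * 100)
                                   if len(groups) else np.nan)
        rows[cohort] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("cohort")


def _corr_row(analysis, cohort, x, y):
    base = {"analysis": analysis, "cohort": cohort, "n": len(x)}
    if len(x) < 3 or np.std(np.asarray(x, float)) == 0 or np.std(np.asarray(y, float)) == 0:
        return {**base, "note": "not computable (n < 3 or zero variance)"}
    res = pearson(x, y)
    return {**base, "statistic": res.r, "p_value": res.p_value}


def _wilcoxon_row(analysis, cohort, a, b, names):
    base = {"analysis": analysis, "cohort": cohort,
            "group_a": names[0], "group_b": names[1],
            "n_a": len(a), "n_b": len(b)}
    if len(a) < 2 or len(b) < 2:
        return {**base, "note": "not computable (group size < 2)"}
    res = wilcoxon_rank_sum(a, b, group_names=names)
    return {**base, "statistic": res.W, "p_value": res.p_value,
            "effect_size": res.rank_biserial, "note": res.method}


def run_primary_analysis(comet_results: pd.DataFrame, bag_table: pd.DataFrame,
                         cohort_labels: pd.DataFrame,
                         participants: pd.DataFrame) -> pd.DataFrame:
    """The study's statistical comparisons on aligned per-participant tables.

    For the symptomatic cohort and its dementia-only subset: CoMeT-BAG
    Pearson correlation; Wilcoxon + rank-biserial of CoMeT for (decelerated,
    accelerated) biological-age groups and (younger, older) chronological
    groups. For the CU cohort: the same correlation as a null check plus the
    mean w-score checks. Groups too small to compare are reported as
    not-computable rows, never as a crash.
    """
    merged = (cohort_labels
              .join(comet_results, how="inner")
              .join(bag_table[["bag", "bio_age_group"]], how="left")
              .join(participants.set_index("id")[["diagnosis"]], how="left"))
    rows = []

    subsets = {
        "symptomatic": merged.loc[merged["cohort"] == "symptomatic"],
        "dementia": merged.loc[(merged["cohort"] == "symptomatic")
                               & (merged["diagnosis"] == "dementia")],
        "CU": merged.loc[merged["cohort"] == "CU"],
    }
    for name, sub in subsets.items():
        has_bag = sub.dropna(subset=["bag"])
        rows.append(_corr_row("comet_vs_bag_pearson", name,
                              has_bag["bag"], has_bag["comet"]))
        dec = has_bag.loc[has_bag["bio_age_group"] == "decelerated", "comet"]
        acc = has_bag.loc[has_bag["bio_age_group"] == "accelerated", "comet"]
        rows.append(_wilcoxon_row("comet_by_bio_age_group", name, dec, acc,
                                  ("decelerated", "accelerated")))
        young = sub.loc[sub["age_group"] == "younger", "comet"]
        old = sub.loc[sub["age_group"] == "older", "comet"]
        rows.append(_wilcoxon_row("comet_by_chron_age_group", name, young, old,
                                  ("younger", "older")))

    cu = subsets["CU"]
    for col in ("cortical_w", "mtl_w", "comet"):
        rows.append({"analysis": f"cu_mean_{col}", "cohort": "CU", "n": len(cu),
                     "statistic": float(cu[col].mean()) if len(cu) else np.nan,
                     "note": "reference-cohort null check"})
    report = pd.DataFrame(rows)
    ordered = ["analysis", "cohort", "group_a", "group_b", "n", "n_a", "n_b",
               "statistic", "p_value", "effect_size", "note"]
    return report.reindex(columns=[c for c in ordered if c in report.columns])


def format_report(report: pd.DataFrame) -> str:
    """Human-readable text rendering of the analysis report."""
    lines = ["Primary analysis report", "=" * 60]
    for _, r in report.iterrows():
        desc = f"{r['analysis']} [{r['cohort']}]"
        if isinstance(r.get("note"), str) and "not computable" in r["note"]:
            lines.append(f"{desc}: {r['note']}")
            continue
        parts = []
        if pd.notna(r.get("n")):
            parts.append(f"n={int(r['n'])}")
        if pd.notna(r.get("n_a")):
            parts.append(f"n=({int(r['n_a'])},{int(r['n_b'])})")
        if pd.notna(r.get("statistic")):
            parts.append(f"stat={r['statistic']:.4f}")
        if pd.notna(r.get("p_value")):
            parts.append(f"p={r['p_value']:.4g}")
        if pd.notna(r.get("effect_size")):
            parts.append(f"rank-biserial={r['effect_size']:.3f}")
        lines.append(f"{desc}: " + ", ".join(parts))
    return "\n".join(lines) + "\n"
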