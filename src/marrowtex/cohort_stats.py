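"""Per-sequence three-group statistical comparison of every descriptor.

Workflow per feature: Jarque-Bera normality in each group decides the
branch (ANOVA when all three groups pass at alpha_norm, Kruskal-Wallis
otherwise); the omnibus p-values are corrected with Benjamini-Hochberg
separately within the ANOVA-branch family and the KW-branch family;
features significant after correction get post hoc pairwise comparisons
(Tukey HSD on the ANOVA branch, Dunn rank comparisons with Bonferroni
correction on the KW branch).  Descriptive summaries follow the branch
convention: mean +/- std for ANOVA, median (IQR) for KW.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SampleSizeError, ValidationError
from .feature_names import ALL_FEATURES
from .roi_io import GROUPS

PAIRS = (("BME", "INJ"), ("BME", "OST"), ("INJ", "OST"))


def jarque_bera(values) -> tuple[float, float]:
    """Jarque-Bera normality statistic and chi2(2) tail p-value.

    JB = n/6 * (S^2 + (K-3)^2 / 4) with biased sample skewness S and
    kurtosis K.  A zero-variance sample returns (0, 1) by convention.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        raise SampleSizeError(f"Jarque-Bera needs n >= 8, got {n}")
    sd = x.std()
    if sd == 0:
        return 0.0, 1.0
    z = (x - x.mean()) / sd
    s = float(np.mean(z**3))
    k = float(np.mean(z**4))
    jb = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
    return float(jb), float(stats.chi2.sf(jb, df=2))


def omnibus_test(groups: list, branch: str) -> float:
    """One-way ANOVA F test or Kruskal-Wallis H test p-value for 3+ groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 3 for a in arrays):
        raise SampleSizeError("each group needs n >= 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0
    if branch == "ANOVA":
        if all(a.std() == 0 for a in arrays):
            return 0.0  # zero within-group variance, unequal means: F -> inf
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = stats.f_oneway(*arrays)
        if not np.isfinite(p):
            return 0.0
        return float(p)
    if branch == "KW":
        stat, p = stats.kruskal(*arrays)
        return float(p)
    raise ValidationError(f"unknown branch {branch!r}")


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    adjusted_p(i) = min over j >= i (in ascending p order) of m * p(j) / j,
    capped at 1; reject where adjusted_p <= q.  Original order restored.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def _dunn_pairwise(groups: dict[str, np.ndarray], alpha: float) -> set:
    """Dunn comparisons of mean ranks with tie correction, Bonferroni over 3 pairs."""
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in labels:
        n = groups[g].size
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    significant = set()
    for a, b in PAIRS:
        se = np.sqrt(variance * (1.0 / groups[a].size + 1.0 / groups[b].size))
        if se == 0:
            continue
        z = abs(mean_ranks[a] - mean_ranks[b]) / se
        p = min(1.0, 2.0 * stats.norm.sf(z) * len(PAIRS))
        if p < alpha:
            significant.add((a, b))
    return significant


def posthoc_pairwise(groups: dict[str, np.ndarray], branch: str, alpha: float = 0.05) -> set:
    """Pairs of groups significantly different at ``alpha`` after the omnibus test.

    Returns the empty set whenever the omnibus p-value exceeds ``alpha``.
    ANOVA branch uses Tukey HSD; KW branch uses Dunn mean-rank
    comparisons with Bonferroni correction over the three pairs.
    """
    arrays = {g: np.asarray(groups[g], dtype=float) for g in groups}
    if omnibus_test(list(arrays.values()), branch) > alpha:
        return set()
    if branch == "ANOVA":
        labels = list(arrays)
        res = stats.tukey_hsd(*arrays.values())
        significant = set()
        for ia, a in enumerate(labels):
            for ib, b in enumerate(labels):
                if ia < ib and res.pvalue[ia, ib] < alpha:
                    pair = (a, b) if (a, b) in PAIRS else (b, a)
                    significant.add(pair)
        return significant
    return _dunn_pairwise(arrays, alpha)


@dataclass
class GroupTestResult:
    """Outcome of the three-group comparison for one feature in one sequence."""

    feature: str
    sequence: str
    branch: str  # "ANOVA" | "KW"
    normality_p: float  # smallest per-group Jarque-Bera p
    raw_p: float
    adjusted_p: float = float("nan")
    significant_strict: bool = False
    group_summary: dict = field(default_factory=dict)
    pairwise_significant: set = field(default_factory=set)


def run_group_analysis(
    table: pd.DataFrame,
    sequence: str,
    alpha_norm: float = 0.05,
    alpha_strict: float = 0.001,
    q: float = 0.05,
    pooled_fdr: bool = False,
) -> list[GroupTestResult]:
    """Run the full per-feature testing workflow for one sequence.

    By default BH-FDR is applied separately within the ANOVA-branch and
    KW-branch families; ``pooled_fdr=True`` corrects all 81 features as
    one family instead.
    """
    sub = table[table["sequence"] == sequence]
    present = set(sub["group"])
    if present != set(GROUPS):
        raise ValidationError(
            f"sequence {sequence}: need all three groups, found {sorted(present)}"
        )
    by_group = {g: sub[sub["group"] == g] for g in GROUPS}
    results: list[GroupTestResult] = []
    for feature in ALL_FEATURES:
        arrays = {g: by_group[g][feature].to_numpy(dtype=float) for g in GROUPS}
        jb_ps = [jarque_bera(arrays[g])[1] for g in GROUPS]
        branch = "ANOVA" if all(p >= alpha_norm for p in jb_ps) else "KW"
        raw_p = omnibus_test(list(arrays.values()), branch)
        if branch == "ANOVA":
            summary = {
                g: {"mean": float(a.mean()), "std": float(a.std(ddof=1))}
                for g, a in arrays.items()
            }
        else:
            summary = {
                g: {
                    "median": float(np.median(a)),
                    "iqr": float(np.percentile(a, 75) - np.percentile(a, 25)),
                }
                for g, a in arrays.items()
            }
        results.append(
            GroupTestResult(
                feature=feature,
                sequence=sequence,
                branch=branch,
                normality_p=float(min(jb_ps)),
                raw_p=raw_p,
                group_summary=summary,
            )
        )

    families = [results] if pooled_fdr else [
        [r for r in results if r.branch == "ANOVA"],
        [r for r in results if r.branch == "KW"],
    ]
    for family in families:
        if not family:
            continue
        adjusted, _ = bh_fdr([r.raw_p for r in family], q)
        for r, adj in zip(family, adjusted):
            r.adjusted_p = float(adj)
            r.significant_strict = bool(adj < alpha_strict)

    for r in results:
        if r.significant_strict:
            sub_arrays = {
                g: by_group[g][r.feature].to_numpy(dtype=float) for g in GROUPS
            }
            r.pairwise_significant = posthoc_pairwise(
                sub_arrays, r.branch, alpha_strict
            )
    return results


def results_to_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    """Flatten test results into a one-row-per-feature table."""
    rows = []
    for r in results:
        row = {
            "feature": r.feature,
            "sequence": r.sequence,
            "branch": r.branch,
            "normality_p": r.normality_p,
            "raw_p": r.raw_p,
            "adjusted_p": r.adjusted_p,
            "significant_strict": r.significant_strict,
            "pairs": ";".join(f"{a}-{b}" for a, b in sorted(r.pairwise_significant)),
        }
        for g, summ in r.group_summary.items():
            for k, v in summ.items():
                row[f"{g}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_counts(results: list[GroupTestResult], alpha_screen: float = 0.05) -> dict:
    """Branch sizes and significance counts (raw and corrected, screen and strict)."""
    anova = [r for r in results if r.branch == "ANOVA"]
    kw = [r for r in results if r.branch == "KW"]
    return {
        "n_features": len(results),
        "n_normal": len(anova),
        "n_nonnormal": len(kw),
        "n_raw_screen": int(sum(r.raw_p < alpha_screen for r in results)),
        "n_adjusted_screen": int(sum(r.adjusted_p < alpha_screen for r in results)),
        "n_strict_anova": int(sum(r.significant_strict for r in anova)),
        "n_strict_kw": int(sum(r.significant_strict for r in kw)),
    }
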