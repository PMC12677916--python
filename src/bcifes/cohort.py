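"""Longitudinal cohort analytics: change scores, effect sizes, correlations,
responder classification and the Sobel mediation statistic.

Sign convention: change scores are post minus pre, so positive deltas and
positive Cohen's d mean improvement.  Every effect-size report carries a
flavor tag (``paired`` within-group pre-vs-post, ``independent``
between-group), since printed effect sizes rarely say which was used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate_cohort import METRICS, TIMEPOINTS, score_column, ResponderProfile


def delta_scores(
    table: pd.DataFrame,
    metric: str = "FMA",
    timepoint: str = "G6",
) -> pd.Series:
    """Per-patient change from baseline: score(timepoint) - score(G1).

    Patients missing either value are excluded; the exclusion count is in
    ``result.attrs['n_excluded']``.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if timepoint not in TIMEPOINTS[1:]:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected G2..G6")
    pre = table[score_column(metric, "G1")]
    post = table[score_column(metric, timepoint)]
    delta = post - pre
    out = delta.dropna()
    out.attrs["n_excluded"] = int(delta.isna().sum())
    out.name = f"delta_{metric.lower()}_{timepoint.lower()}"
    return out


@dataclass
class EffectSize:
    d: float
    flavor: str
    n: int
    ci95: tuple[float, float]
    flagged: bool = False  # zero-variance denominator


def cohens_d(
    values_a: np.ndarray,
    values_b: np.ndarray,
    flavor: str = "independent",
) -> EffectSize:
    """Cohen's d.

    ``independent``: (mean_a - mean_b) / pooled SD, variances weighted by
    n - 1.  ``paired``: mean(a - b) / SD(a - b) with equal-length samples.
    The 95% CI uses the standard large-sample variance approximation of d.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if flavor == "paired":
        if a.size != b.size:
            raise ValueError("paired flavor requires equal-length samples")
        if a.size < 2:
            raise ValueError("need n >= 2")
        diff = a - b
        sd = diff.std(ddof=1)
        n = a.size
        if sd == 0:
            return EffectSize(np.nan, flavor, n, (np.nan, np.nan), flagged=True)
        d = float(diff.mean() / sd)
        se = np.sqrt(1.0 / n + d**2 / (2.0 * n))
    elif flavor == "independent":
        if a.size < 2 or b.size < 2:
            raise ValueError("need n >= 2 per sample")
        na, nb = a.size, b.size
        pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        n = na + nb
        if pooled_var == 0:
            return EffectSize(np.nan, flavor, n, (np.nan, np.nan), flagged=True)
        d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
        se = np.sqrt((na + nb) / (na * nb) + d**2 / (2.0 * (na + nb)))
    else:
        raise ValueError("flavor must be 'independent' or 'paired'")
    return EffectSize(d, flavor, n, (d - 1.96 * se, d + 1.96 * se))


def effect_size_report(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = METRICS,
    timepoints: tuple[str, ...] = TIMEPOINTS[1:],
) -> pd.DataFrame:
    """Per arm x metric x timepoint: mean delta, SD, paired Cohen's d, CI."""
    rows = []
    for arm, grp in table.groupby("arm", sort=False):
        for metric in metrics:
            pre = grp[score_column(metric, "G1")]
            for tp in timepoints:
                post = grp[score_column(metric, tp)]
                mask = pre.notna() & post.notna()
                if mask.sum() < 2:
                    continue
                es = cohens_d(post[mask].to_numpy(), pre[mask].to_numpy(),
                              flavor="paired")
                delta = (post[mask] - pre[mask])
                rows.append({
                    "arm": arm, "metric": metric, "timepoint": tp,
                    "n": int(mask.sum()),
                    "mean_delta": float(delta.mean()),
                    "sd_delta": float(delta.std(ddof=1)),
                    "cohens_d": es.d, "flavor": es.flavor,
                    "ci95_low": es.ci95[0], "ci95_high": es.ci95[1],
                })
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    method: str
    n: int
    ci95: tuple[float, float]
    flagged: bool = False


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "auto",
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson or Spearman correlation with a Fisher-z 95% CI.

    ``auto`` runs Shapiro-Wilk on both variables and picks Pearson iff both
    pass at ``alpha``, mirroring the normality-gated convention of clinical
    reporting.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(np.nan, np.nan, method, x.size,
                                 (np.nan, np.nan), flagged=True)
    if method == "auto":
        normal = (stats.shapiro(x).pvalue > alpha
                  and stats.shapiro(y).pvalue > alpha)
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'auto', 'pearson' or 'spearman'")
    r, p = float(res.statistic), float(res.pvalue)
    if abs(r) < 1 and x.size > 3:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(x.size - 3)
        ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
    else:
        ci = (r, r)
    return CorrelationResult(r, p, method, x.size, ci)


@dataclass
class ResponderReport:
    labels: pd.DataFrame  # patient_id, actual, predicted
    confusion: dict
    sensitivity: float
    specificity: float
    accuracy: float
    n_excluded: int


def classify_responders(
    table: pd.DataFrame,
    profile: ResponderProfile | None = None,
    timepoint: str = "G6",
) -> ResponderReport:
    """High-responder classification against the prognostic threshold rule.

    Actual responders have delta-FMA >= 5 (inclusive); the profile predicts
    response for age < 70, onset < 23 months and baseline MBI > 40
    (conjunction).  Sensitivity is the fraction of actual responders the
    profile captures.
    """
    profile = profile or ResponderProfile()
    cols = ["age", "onset_months", score_column("MBI", "G1"),
            score_column("FMA", "G1"), score_column("FMA", timepoint)]
    mask = table[cols].notna().all(axis=1)
    sub = table[mask]
    dfma = sub[score_column("FMA", timepoint)] - sub[score_column("FMA", "G1")]
    actual = dfma >= profile.delta_fma_min
    predicted = (
        (sub["age"] < profile.age_max)
        & (sub["onset_months"] < profile.onset_max_months)
        & (sub[score_column("MBI", "G1")] > profile.mbi_min)
    )
    tp = int((actual & predicted).sum())
    tn = int((~actual & ~predicted).sum())
    fp = int((~actual & predicted).sum())
    fn = int((actual & ~predicted).sum())
    labels = pd.DataFrame({
        "patient_id": sub["patient_id"],
        "actual_responder": actual.to_numpy(),
        "predicted_responder": predicted.to_numpy(),
    })
    return ResponderReport(
        labels=labels,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        accuracy=(tp + tn) / len(sub) if len(sub) else np.nan,
        n_excluded=int((~mask).sum()),
    )


def sobel_z(a: float, se_a: float, b: float, se_b: float) -> float:
    """Sobel mediation statistic z = a*b / sqrt(b^2 se_a^2 + a^2 se_b^2)."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    denom = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    if denom == 0:
        raise ValueError("both paths are zero; mediation undefined")
    return float(a * b / denom)


@dataclass
class GroupComparison:
    test: str  # "anova" or "kruskal"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # arm_a, arm_b, p_raw, p_bonferroni
    degenerate_arms: tuple[str, ...] = ()


def group_compare(
    table: pd.DataFrame,
    metric: str = "FMA",
    timepoint: str = "G6",
    alpha: float = 0.05,
) -> GroupComparison:
    """Normality-gated omnibus comparison of per-arm delta scores.

    One-way ANOVA when every arm's deltas pass Shapiro-Wilk at ``alpha``,
    Kruskal-Wallis otherwise; pairwise follow-ups (same family of tests)
    are Bonferroni-adjusted as min(1, m * p) over the m pairs.
    """
    groups: dict[str, np.ndarray] = {}
    degenerate = []
    for arm, grp in table.groupby("arm", sort=False):
        d = delta_scores(grp, metric, timepoint).to_numpy()
        if d.size < 2 or np.std(d) == 0:
            degenerate.append(arm)
        groups[arm] = d
    valid = {a: v for a, v in groups.items() if a not in degenerate}
    if len(valid) < 2:
        raise ValueError("need >= 2 non-degenerate arms")
    normal = all(stats.shapiro(v).pvalue > alpha for v in valid.values()
                 if v.size >= 3)
    arms = list(valid)
    if normal:
        stat, p = stats.f_oneway(*valid.values())
        test = "anova"
    else:
        stat, p = stats.kruskal(*valid.values())
        test = "kruskal"
    pairs = [(arms[i], arms[j]) for i in range(len(arms))
             for j in range(i + 1, len(arms))]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if normal:
            _, pr = stats.ttest_ind(valid[a], valid[b])
        else:
            _, pr = stats.mannwhitneyu(valid[a], valid[b],
                                       alternative="two-sided")
        rows.append({"arm_a": a, "arm_b": b, "p_raw": float(pr),
                     "p_bonferroni": float(min(1.0, m * pr))})
    return GroupComparison(test=test, statistic=float(stat), p_value=float(p),
                           pairwise=pd.DataFrame(rows),
                           degenerate_arms=tuple(degenerate))
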