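"""Statistical comparison machinery.

One-way MANOVA (Wilks' lambda with Rao's F approximation) tests whether the
per-fold 12-lead metric mean vectors differ across classifiers; pairwise
two-sample Hotelling T-squared tests with Bonferroni adjustment act as the
post hoc. Group-level baseline comparisons are computed directly from
summary statistics: pooled-variance two-sample t-tests for continuous rows
and Yates-corrected chi-square tests for 2x2 count rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import MetricsPanel

logger = logging.getLogger(__name__)


@dataclass
class ManovaResult:
    wilks_lambda: float
    f_statistic: float
    df1: float
    df2: float
    p_value: float


def manova_oneway(groups: list[np.ndarray]) -> ManovaResult:
    """One-way MANOVA via Wilks' lambda and Rao's F approximation.

    ``groups`` holds one (n_i, p) observation matrix per group. H0: all
    group mean vectors are equal.
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    if any(not np.all(np.isfinite(x)) for x in groups):
        raise ValueError("observations contain undefined (NaN/inf) values")
    p = groups[0].shape[1]
    n_total = sum(len(x) for x in groups)
    grand_mean = np.vstack(groups).mean(axis=0)

    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for x in groups:
        mu = x.mean(axis=0)
        xc = x - mu
        W += xc.T @ xc
        d = (mu - grand_mean)[:, None]
        B += len(x) * (d @ d.T)

    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError(
            "singular within-group scatter; reduce dimensions or add observations"
        )
    lam = float(np.exp(logdet_w - logdet_t))

    # Rao's F approximation
    q = g - 1
    if p**2 + q**2 - 5 > 0:
        t = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
    else:
        t = 1.0
    w = n_total - 1 - (p + g) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    f_stat = (1.0 - lam_t) / lam_t * df2 / df1
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return ManovaResult(lam, float(f_stat), float(df1), float(df2), p_value)


def manova_classifiers(panel: MetricsPanel, metric: str) -> ManovaResult:
    """MANOVA across classifiers on one metric's per-fold lead vectors.

    Each classifier contributes k fold observations of an n_leads-dim
    vector (the metric across leads).
    """
    groups = [panel.fold_vectors(c, metric) for c in panel.classifiers]
    return manova_oneway(groups)


@dataclass
class HotellingResult:
    t2: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    p_adjusted: float | None = None


def hotelling_t2(group1: np.ndarray, group2: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling T-squared test with pooled covariance.

    F = T^2 (n1+n2-p-1) / ((n1+n2-2) p) with (p, n1+n2-p-1) degrees of
    freedom. Requires n1 + n2 - 2 >= p and a nonsingular pooled covariance.
    """
    x1 = np.atleast_2d(np.asarray(group1, dtype=float))
    x2 = np.atleast_2d(np.asarray(group2, dtype=float))
    n1, p = x1.shape
    n2 = x2.shape[0]
    if x2.shape[1] != p:
        raise ValueError("groups must share dimensionality")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("observations contain undefined (NaN/inf) values")
    if n1 + n2 - 2 < p:
        raise ValueError(f"n1+n2-2 = {n1 + n2 - 2} < p = {p}")
    diff = x1.mean(axis=0) - x2.mean(axis=0)
    s1 = np.cov(x1, rowvar=False, ddof=1)
    s2 = np.cov(x2, rowvar=False, ddof=1)
    pooled = ((n1 - 1) * np.atleast_2d(s1) + (n2 - 1) * np.atleast_2d(s2)) / (
        n1 + n2 - 2
    )
    try:
        sol = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular pooled covariance") from e
    t2 = float(n1 * n2 / (n1 + n2) * diff @ sol)
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    p_value = float(stats.f.sf(f_stat, p, df2))
    return HotellingResult(t2, float(f_stat), p, df2, p_value)


def pairwise_hotelling(
    panel: MetricsPanel, metric: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise Hotelling tests across all classifier
    pairs for one metric. Returns one row per unordered pair."""
    names = panel.classifiers
    pairs = list(combinations(names, 2))
    rows = []
    for a, b in pairs:
        res = hotelling_t2(panel.fold_vectors(a, metric), panel.fold_vectors(b, metric))
        rows.append(
            {
                "classifier_1": a,
                "classifier_2": b,
                "t2": res.t2,
                "f": res.f_statistic,
                "p": res.p_value,
                "p_bonferroni": min(1.0, res.p_value * len(pairs)),
            }
        )
    df = pd.DataFrame(rows)
    df["significant"] = df["p_bonferroni"] < alpha
    return df


def classifier_comparison_table(
    panel: MetricsPanel, metrics: list[str] | None = None
) -> pd.DataFrame:
    """MANOVA + post hoc summary, one row per metric: overall F and p, the
    classifier ranking by mean metric, and the non-significant pairs."""
    metrics = metrics or panel.metrics
    rows = []
    for metric in metrics:
        try:
            man = manova_classifiers(panel, metric)
            post = pairwise_hotelling(panel, metric)
        except (ValueError, np.linalg.LinAlgError) as e:
            logger.warning("comparison for %s skipped: %s", metric, e)
            rows.append(
                {
                    "metric": metric,
                    "manova_f": float("nan"),
                    "manova_p": float("nan"),
                    "ranking": "",
                    "nonsignificant_pairs": "",
                }
            )
            continue
        means = {
            c: float(np.nanmean(panel.fold_vectors(c, metric))) for c in panel.classifiers
        }
        ranking = sorted(means, key=means.get, reverse=True)
        ns = post.loc[~post["significant"]]
        rows.append(
            {
                "metric": metric,
                "manova_f": man.f_statistic,
                "manova_p": man.p_value,
                "ranking": "; ".join(ranking),
                "nonsignificant_pairs": "; ".join(
                    f"{r.classifier_1}-{r.classifier_2}" for r in ns.itertuples()
                ),
            }
        )
    return pd.DataFrame(rows)


def compare_continuous(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test from summary statistics.

    Returns (t, df, two-sided p). Two zero-SD groups with equal means give
    p = 1 by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            logger.info("both groups constant and equal; p = 1 by convention")
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance with unequal means")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), float(n1 + n2 - 2), float(p)


def compare_counts(
    events1: int, n1: int, events2: int, n2: int
) -> tuple[float, float]:
    """Yates-corrected chi-square test on a 2x2 table of event counts.

    Returns (chi2, two-sided p); a zero margin gives p = 1 (degenerate).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    table = np.array([[events1, n1 - events1], [events2, n2 - events2]])
    if np.any(table < 0):
        raise ValueError("event counts exceed group sizes")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        logger.info("degenerate 2x2 margin; p = 1")
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def group_comparison_table(rows: list[dict]) -> pd.DataFrame:
    """Baseline-characteristics table from per-variable summary rows.

    Each row dict needs ``variable`` and ``kind`` ("continuous" with
    mean1/sd1/n1/mean2/sd2/n2, or "count" with events1/n1/events2/n2).
    """
    out = []
    for row in rows:
        if row["kind"] == "continuous":
            t, df, p = compare_continuous(
                row["mean1"], row["sd1"], row["n1"], row["mean2"], row["sd2"], row["n2"]
            )
            out.append(
                {"variable": row["variable"], "statistic": t, "p": p, "test": "pooled t"}
            )
        elif row["kind"] == "count":
            chi2, p = compare_counts(
                row["events1"], row["n1"], row["events2"], row["n2"]
            )
            out.append(
                {
                    "variable": row["variable"],
                    "statistic": chi2,
                    "p": p,
                    "test": "chi-square (Yates)",
                }
            )
        else:
            raise ValueError(f"unknown row kind {row['kind']!r}")
    return pd.DataFrame(out)
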