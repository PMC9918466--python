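"""Age-class comparisons and covariate relations.

Sites are binned into 5-year age classes with the oldest class spanning
20-40 years (sample sizes get thin past 20 years). Because carbon densities
are typically skewed and heteroscedastic, between-pathway comparisons use the
two-sided Wilcoxon rank-sum test and multi-group comparisons use
Kruskal-Wallis followed by Dunn's post hoc test with Bonferroni adjustment.
Covariate relations (e.g. aboveground carbon vs precipitation) are ordinary
least squares with a pointwise 95% band for the conditional mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import Pathway, SiteRecord

#: (lo, hi] age-class bounds in years; upper-inclusive half-open bins
AGE_CLASSES: list[tuple[float, float]] = [(0, 5), (5, 10), (10, 15), (15, 20), (20, 40)]
AGE_CLASS_LABELS = [f"{lo}–{hi}" for lo, hi in AGE_CLASSES]

#: exact Wilcoxon p when combined sample size is at most this and tie-free
EXACT_WILCOXON_MAX_N = 20


def assign_age_class(age: float) -> Optional[str]:
    """Age-class label for an age in (0, 40]; None (with notice) outside."""
    for (lo, hi), label in zip(AGE_CLASSES, AGE_CLASS_LABELS):
        if lo < age <= hi:
            return label
    warnings.warn(f"age {age} yr outside (0, 40]; site excluded from age classes",
                  stacklevel=2)
    return None


def wilcoxon_two_sided(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test between two independent samples.

    Returns (W, p) where W is the rank sum of ``x`` in the pooled ranking.
    The p-value is exact for small tie-free samples (n1 + n2 <= 20), otherwise
    from the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank sum of x
    return w, float(res.pvalue)


@dataclass
class DunnResult:
    """Kruskal-Wallis omnibus plus Bonferroni-adjusted Dunn pairwise table."""

    h: float
    p: float
    pairwise: pd.DataFrame  # columns: i, j, z, p_raw, p_adj


def kruskal_dunn_bonferroni(groups: Sequence[Sequence[float]]) -> DunnResult:
    """Kruskal-Wallis test with Dunn's post hoc z tests, Bonferroni-adjusted.

    Requires at least three groups of n >= 2 each; for two groups use
    :func:`wilcoxon_two_sided`. Dunn's z compares pooled mean ranks with the
    standard tie correction; adjusted p = min(1, p_raw x number of pairs).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use wilcoxon_two_sided for two")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    h, p = stats.kruskal(*groups)

    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start:start + len(g)])))
        sizes.append(len(g))
        start += len(g)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = list(combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"i": i, "j": j, "z": z, "p_raw": p_raw,
                     "p_adj": min(1.0, p_raw * len(pairs))})
    return DunnResult(h=float(h), p=float(p), pairwise=pd.DataFrame(rows))


@dataclass
class OLSRelation:
    """Simple linear relation y ~ x with t-based slope inference."""

    slope: float
    intercept: float
    r2: float
    p: float  # two-sided p for the slope
    slope_ci: tuple[float, float]
    n: int
    _model: object = None

    def band(self, x_grid: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pointwise mean prediction with its 95% confidence band."""
        import statsmodels.api as sm

        x_grid = np.asarray(x_grid, float)
        pred = self._model.get_prediction(sm.add_constant(x_grid, has_constant="add"))
        frame = pred.summary_frame(alpha=0.05)
        return (frame["mean"].to_numpy(), frame["mean_ci_lower"].to_numpy(),
                frame["mean_ci_upper"].to_numpy())


def ols_relation(x: Sequence[float], y: Sequence[float]) -> OLSRelation:
    """Ordinary least squares of y on x with slope t-test and 95% CI."""
    import statsmodels.api as sm

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError(f"need >= 3 finite (x, y) pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; regression design is degenerate")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return OLSRelation(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r2=float(model.rsquared), p=float(model.pvalues[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])), n=len(x), _model=model,
    )


def age_class_summary(records: Sequence[SiteRecord], pool: str) -> pd.DataFrame:
    """Per age-class x pathway mean, SE, n, and the between-pathway Wilcoxon p.

    Mirrors the annotation structure of a boxplot comparison: one row per
    age class and pathway, with the two-sided rank-sum p attached to each
    class that has both pathways present.
    """
    by_class: dict[str, dict[str, list[float]]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in records:
            if r.pathway is Pathway.control:
                continue
            v = getattr(r, pool)
            if v is None:
                continue
            label = assign_age_class(r.age_years)
            if label is None:
                continue
            by_class.setdefault(label, {}).setdefault(r.pathway.value, []).append(v)
    rows = []
    for label in AGE_CLASS_LABELS:
        paths = by_class.get(label, {})
        p_between = math.nan
        if {"reforestation", "afforestation"} <= set(paths):
            _, p_between = wilcoxon_two_sided(paths["reforestation"], paths["afforestation"])
        for pw, vals in sorted(paths.items()):
            arr = np.asarray(vals, float)
            se = float(np.std(arr, ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else math.nan
            rows.append({"age_class": label, "pathway": pw, "n": len(arr),
                         "mean": float(np.mean(arr)), "se": se, "wilcoxon_p": p_between})
    return pd.DataFrame(rows)
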