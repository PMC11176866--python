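"""Evaluation statistics for the HRV-IDH analysis.

Implements the statistics reported for the index and the cohort: rank-based
AUROC with the Youden operating point, classification metrics, 2x2 odds
ratios with Woolf confidence intervals, group comparisons (pooled t-test,
chi-square with Fisher fallback), Spearman test-retest correlation, and
logistic-model diagnostics (Nagelkerke R^2, Hosmer-Lemeshow).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .index import LogisticIndexModel

Z_95 = 1.959964  # two-sided 95 % normal quantile


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    youden_cutoff: float
    youden_index: float


@dataclass
class ContingencyTable2x2:
    """Counts: a = exposed cases, b = exposed controls,
    c = unexposed cases, d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class ClassificationMetrics:
    accuracy: float
    recall: float                       # sensitivity
    precision: Optional[float]
    f1: Optional[float]
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


def roc_auroc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC analysis with the rank (Mann-Whitney) AUROC and Youden cutoff.

    Ties between a case and a control score count one half.  The Youden
    cutoff is the observed score maximising sensitivity + specificity - 1;
    ties are broken toward the higher-specificity (higher-threshold) point.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels disagree in length")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(s)                       # mid-ranks handle ties
    auroc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    thresholds = np.unique(s)
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = s >= t
        sens[i] = np.sum(pred & (y == 1)) / n1
        spec[i] = np.sum(~pred & (y == 0)) / n0
    j = sens + spec - 1
    best = np.flatnonzero(j == j.max())
    best_i = best[np.argmax(spec[best])]            # tie -> higher specificity
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auroc=float(auroc),
        youden_cutoff=float(thresholds[best_i]),
        youden_index=float(j[best_i]),
    )


def classification_metrics(pred: Sequence[int], truth: Sequence[int]) -> ClassificationMetrics:
    p = np.asarray(pred, dtype=int)
    t = np.asarray(truth, dtype=int)
    if p.shape != t.shape:
        raise ValueError("pred and truth disagree in length")
    if t.sum() == 0:
        raise ValueError("no positive cases in truth")
    tp = int(np.sum((p == 1) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    recall = tp / (tp + fn)
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    precision = tp / (tp + fp) if (tp + fp) else None
    f1 = (2 * precision * recall / (precision + recall)
          if precision is not None and (precision + recall) > 0 else None)
    return ClassificationMetrics(
        accuracy=(tp + tn) / len(t), recall=recall, precision=precision,
        f1=f1, specificity=specificity, tp=tp, fp=fp, tn=tn, fn=fn)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    return 2 * precision * recall / (precision + recall)


def odds_ratio_ci(
    table: ContingencyTable2x2,
    level: float = 0.95,
    haldane: bool = False,
) -> tuple[float, tuple[float, float]]:
    """Odds ratio ad/bc with the Woolf (log-normal) confidence interval.

    Orientation: odds of being a case among the exposed over odds among the
    unexposed.  A zero cell is an error unless ``haldane`` adds the
    Haldane-Anscombe 0.5 correction to every cell.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:
        raise ValueError("zero cell: OR undefined (use haldane=True to correct)")
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return float(or_), (float(lo), float(hi))


def group_compare(values, groups=None, *, table: Optional[ContingencyTable2x2] = None,
                  method: str = "auto"):
    """Two-group comparison mirroring the cohort tables.

    Continuous data (``values`` + binary ``groups``): pooled-variance
    two-sample t-test.  Categorical data (``table``): Pearson chi-square
    without continuity correction, falling back to Fisher's exact test when
    any expected cell count is below 5 (``method`` forces ``"fisher"`` or
    ``"chi2"`` explicitly).

    Returns ``(statistic, p, test_name)``; Fisher reports statistic ``nan``.
    """
    if table is not None:
        arr = table.as_array()
        expected = stats.contingency.expected_freq(arr)
        use_fisher = (method == "fisher"
                      or (method == "auto" and (expected < 5).any()))
        if use_fisher:
            _, p = stats.fisher_exact(arr, alternative="two-sided")
            return np.nan, float(p), "fisher"
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return float(chi2), float(p), "chi2"

    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    x, y = v[g == labels[0]], v[g == labels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0, "t"        # degenerate: identical constants
        return np.inf, 0.0, "t"
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p), "t"


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Returns ``None`` when either vector is constant (rho undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def logistic_diagnostics(
    model: LogisticIndexModel,
    features,
    labels,
    n_groups: int = 10,
) -> dict:
    """Nagelkerke pseudo-R^2 and the Hosmer-Lemeshow calibration test.

    Nagelkerke R^2 = (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n)) with L0 the
    intercept-only likelihood.  Hosmer-Lemeshow groups observations into
    ``n_groups`` quantile bins of predicted risk (empty or duplicate bins
    merged), sums (O-E)^2/E over events and non-events, and refers the
    statistic to chi-square with g - 2 degrees of freedom."""
    import pandas as pd

    from .index import hrv_idh_index

    if isinstance(features, pd.DataFrame):
        rows = features.to_dict("records")
    else:
        X = np.asarray(features, dtype=float)
        names = list(model.feature_names)
        rows = [dict(zip(names, r)) for r in X]
    y = np.asarray(labels, dtype=float)
    p = np.array([hrv_idh_index(r, model) for r in rows])

    eps = 1e-12
    l1 = float(np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    pbar = float(np.mean(y))
    l0 = float(len(y) * (pbar * np.log(pbar + eps) + (1 - pbar) * np.log(1 - pbar + eps)))
    n = len(y)
    r2_cs = 1.0 - np.exp(2.0 * (l0 - l1) / n)
    r2_max = 1.0 - np.exp(2.0 * l0 / n)
    nagelkerke = float(r2_cs / r2_max) if r2_max > 0 else 0.0

    out = {"nagelkerke_r2": nagelkerke, "hosmer_lemeshow_stat": None,
           "hl_p": None, "n_groups": None, "reason": None}

    # deciles of risk, merging duplicate bin edges
    try:
        bins = pd.qcut(p, q=n_groups, duplicates="drop")
    except ValueError:
        out["reason"] = "could not form risk groups"
        return out
    df = pd.DataFrame({"y": y, "p": p, "bin": bins})
    grouped = df.groupby("bin", observed=True)
    g = grouped.ngroups
    if g < 3:
        out["reason"] = f"only {g} risk groups after merging"
        return out
    stat = 0.0
    for _, grp in grouped:
        o1, e1 = grp["y"].sum(), grp["p"].sum()
        o0, e0 = len(grp) - o1, len(grp) - e1
        if e1 > 0:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 0:
            stat += (o0 - e0) ** 2 / e0
    df_hl = g - 2
    out.update(
        hosmer_lemeshow_stat=float(stat),
        hl_p=float(stats.chi2.sf(stat, df_hl)),
        n_groups=g,
    )
    return out
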