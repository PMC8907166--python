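"""Classification metric panel and comparison statistics.

Percentages are kept at full precision internally; rounding to one decimal
happens only in the reporting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

PLR_INF = float("inf")


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise StatsError("counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN < 1:
            raise StatsError("empty confusion table")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == -1) & (y_pred == -1)).sum()),
        FP=int(((y_true == -1) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == -1)).sum()),
    )


@dataclass
class MetricPanel:
    sens: float
    spec: float
    bac: float
    ppv: float | None
    npv: float | None
    psi: float | None
    plr: float
    nlr: float
    auc: float | None = None

    def rounded(self) -> dict:
        def r1(x):
            return None if x is None else round(x, 1)

        out = {
            "sens": r1(self.sens),
            "spec": r1(self.spec),
            "bac": r1(self.bac),
            "ppv": r1(self.ppv),
            "npv": r1(self.npv),
            "psi": r1(self.psi),
            "nlr": r1(self.nlr),
            "plr": r1(self.plr) if math.isfinite(self.plr) else self.plr,
            "auc": None if self.auc is None else round(self.auc, 2),
        }
        return out


def metric_panel(c: ConfusionCounts, scores=None, labels=None) -> MetricPanel:
    """Sensitivity/specificity panel with predictive values and likelihood ratios."""
    if c.TP + c.FN < 1 or c.TN + c.FP < 1:
        raise StatsError("need at least one subject of each class")
    sens = 100.0 * c.TP / (c.TP + c.FN)
    spec = 100.0 * c.TN / (c.TN + c.FP)
    bac = (sens + spec) / 2.0
    ppv = 100.0 * c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    npv = 100.0 * c.TN / (c.TN + c.FN) if (c.TN + c.FN) > 0 else None
    psi = ppv + npv - 100.0 if (ppv is not None and npv is not None) else None
    plr = sens / (100.0 - spec) if spec < 100.0 else PLR_INF
    nlr = (1.0 - sens / 100.0) / (spec / 100.0) if spec > 0 else PLR_INF
    auc = auc_rank(scores, labels) if scores is not None and labels is not None else None
    return MetricPanel(sens=sens, spec=spec, bac=bac, ppv=ppv, npv=npv, psi=psi, plr=plr, nlr=nlr, auc=auc)


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: Mann-Whitney statistic / (n+ * n-), ties counted 1/2."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == -1]
    if pos.size == 0 or neg.size == 0:
        raise StatsError("both classes must be present for AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class PermutationResult:
    observed_bac: float
    null_bacs: np.ndarray
    p_value: float
    n_perm: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def permutation_test(pipeline, y: np.ndarray, n_perm: int = 1000, seed: int = 0, alpha: float = 0.05) -> PermutationResult:
    """Label-permutation significance of a training pipeline.

    ``pipeline(labels) -> out-of-fold BAC``; the full procedure is re-run per
    permutation.  p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise StatsError("n_perm must be at least 1")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    observed = float(pipeline(y))
    null = np.array([float(pipeline(rng.permutation(y))) for _ in range(n_perm)])
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return PermutationResult(observed_bac=observed, null_bacs=null, p_value=float(p), n_perm=n_perm, alpha=alpha)


def quade_test(perf: np.ndarray):
    """Quade blocked rank test with t-distribution post-hoc comparisons.

    ``perf`` is blocks x predictors.  Returns (F statistic, p, pairwise p
    matrix).  Identical columns give statistic 0 and p 1.
    """
    perf = np.asarray(perf, dtype=float)
    if perf.ndim != 2 or perf.shape[0] < 2 or perf.shape[1] < 2:
        raise StatsError("need >= 2 blocks and >= 2 predictors")
    if np.isnan(perf).any():
        raise StatsError("missing cells are not allowed")
    b, k = perf.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, perf)  # within-block ranks
    ranges = perf.max(axis=1) - perf.min(axis=1)
    q = stats.rankdata(ranges)  # block weights from ranked ranges
    s = q[:, None] * (ranks - (k + 1) / 2.0)
    s_j = s.sum(axis=0)
    a2 = (s**2).sum()
    bb = (s_j**2).sum() / b
    df1, df2 = k - 1, (b - 1) * (k - 1)
    if a2 - bb <= 1e-12:
        if bb <= 1e-12:
            return 0.0, 1.0, np.ones((k, k))
        statistic, p = float("inf"), (1.0 / math.factorial(k)) ** (b - 1)
    else:
        statistic = (b - 1) * bb / (a2 - bb)
        p = float(stats.f.sf(statistic, df1, df2))
    # post-hoc pairwise comparisons on weighted-rank sums
    se = math.sqrt(2 * b * (a2 - bb) / df2) if a2 - bb > 0 else 0.0
    pairwise = np.ones((k, k))
    for i, j in combinations(range(k), 2):
        if se == 0:
            pw = 0.0 if s_j[i] != s_j[j] else 1.0
        else:
            t = abs(s_j[i] - s_j[j]) / se
            pw = 2.0 * float(stats.t.sf(t, df2))
        pairwise[i, j] = pairwise[j, i] = pw
    return float(statistic), float(p), pairwise


def _ranksum_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group assignments (mid-ranks)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = a.size
    w_obs = ranks[:n1].sum()
    mu = n1 * (pooled.size + 1) / 2.0
    dev_obs = abs(w_obs - mu) - 1e-12
    count = 0
    total = 0
    for comb in combinations(range(pooled.size), n1):
        w = ranks[list(comb)].sum()
        if abs(w - mu) >= dev_obs:
            count += 1
        total += 1
    return count / total


def ranksum_test(a, b) -> tuple[float, float]:
    """Two-sided unpaired rank-sum test.

    Exact enumeration for pooled n <= 20 (handles ties via mid-ranks);
    normal approximation with tie correction and continuity correction
    otherwise.  Returns (rank-sum statistic of the first sample, p).
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, n2 = a.size, b.size
    n = n1 + n2
    w = float(ranks[:n1].sum())
    if n <= 20:
        return w, float(_ranksum_exact_p(a, b))
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return w, float(2.0 * stats.norm.sf(z))


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence for an r x c count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise StatsError("table must be 2-D")
    row, col, n = table.sum(axis=1), table.sum(axis=0), table.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise StatsError("zero margin")
    expected = np.outer(row, col) / n
    statistic = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return statistic, df, float(stats.chi2.sf(statistic, df))


def yates_chi2(table) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2 x 2 count table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise StatsError("Yates correction applies to 2 x 2 tables")
    (a, b), (c, d) = table
    n = table.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise StatsError("zero margin")
    num = n * max(0.0, abs(a * d - b * c) - n / 2.0) ** 2
    statistic = float(num / margins)
    return statistic, float(stats.chi2.sf(statistic, 1))
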