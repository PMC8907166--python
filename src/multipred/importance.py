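"""Feature-reliability statistics over an ensemble's base models.

Two indices: the cross-validation ratio (mean weight over its standard
error across base models, unselected features counting as weight 0) and
sign-based consistency (fraction of selecting models agreeing with the
majority weight sign, tested against a Bernoulli(1/2) null with BH false
discovery control).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cvlearn import EnsembleModel

CV_RATIO_CAP = 1e6


class ImportanceError(ValueError):
    pass


def weight_matrix(ensemble: EnsembleModel) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(features x models) weights and selection mask, keyed by original feature name."""
    names = list(ensemble.feature_names)
    index = {n: i for i, n in enumerate(names)}
    M = len(ensemble.base)
    W = np.zeros((len(names), M))
    sel = np.zeros((len(names), M), dtype=bool)
    for m, bm in enumerate(ensemble.base):
        for w, fname in zip(bm.linear.weights, bm.linear.feature_names):
            i = index[fname]
            W[i, m] = w
            sel[i, m] = True
    return W, sel, names


def cv_ratio(ensemble: EnsembleModel) -> pd.DataFrame:
    """mean(w) / (sd(w) / sqrt(M)) per feature; never-selected features get 0."""
    if len(ensemble.base) < 2:
        raise ImportanceError("need at least 2 base models")
    W, sel, names = weight_matrix(ensemble)
    M = W.shape[1]
    mean = W.mean(axis=1)
    sd = W.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean / (sd / np.sqrt(M))
    ratio = np.where(sd == 0, np.sign(mean) * CV_RATIO_CAP, ratio)
    ratio = np.clip(ratio, -CV_RATIO_CAP, CV_RATIO_CAP)
    ever = sel.any(axis=1)
    ratio[~ever] = 0.0
    return pd.DataFrame({"feature": names, "cv_ratio": ratio, "ever_selected": ever})


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_rev, idx in enumerate(order[::-1]):
        rank = m - rank_rev
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # feature, n_selected, consistency, z, p, q, significant
    untested: pd.DataFrame  # features selected in < min_models models
    fdr: float

    def significant_features(self) -> list[str]:
        return self.table.loc[self.table["significant"], "feature"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sign_consistency(ensemble: EnsembleModel, fdr: float = 0.05, min_models: int = 3) -> ImportanceReport:
    """Majority-sign consistency per feature with a binomial null and BH control."""
    if len(ensemble.base) < 10:
        raise ImportanceError("need at least 10 base models for a meaningful null")
    W, sel, names = weight_matrix(ensemble)
    rows, skipped = [], []
    for i, name in enumerate(names):
        models = np.flatnonzero(sel[i])
        m = models.size
        if m == 0:
            continue
        if m < min_models:
            skipped.append({"feature": name, "n_selected": m})
            continue
        signs = np.sign(W[i, models])
        n_pos = int((signs > 0).sum())
        majority = max(n_pos, m - n_pos)
        consistency = majority / m
        z = (2.0 * majority - m) / np.sqrt(m)
        p = float(stats.norm.sf(z))
        rows.append(
            {
                "feature": name,
                "n_selected": m,
                "consistency": consistency,
                "z": z,
                "p": p,
            }
        )
    table = pd.DataFrame(rows, columns=["feature", "n_selected", "consistency", "z", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] < fdr
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    untested = pd.DataFrame(skipped, columns=["feature", "n_selected"])
    return ImportanceReport(table=table, untested=untested, fdr=fdr)


def top_features(ensemble: EnsembleModel, k: int = 10) -> pd.DataFrame:
    """Top-k features by absolute cross-validation ratio."""
    df = cv_ratio(ensemble)
    df = df.reindex(df["cv_ratio"].abs().sort_values(ascending=False).index)
    return df.head(k).reset_index(drop=True)
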