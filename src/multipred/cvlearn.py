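"""Repeated nested cross-validation with linear SVMs and wrapper selection.

The outer cycle (default 10 folds x 5 permutations) provides the held-out
performance estimate; each outer training set is re-split into an inner
cycle (default 10 x 5) that drives greedy forward feature selection over
the C grid {2^-4 ... 2^4}.  The winning configuration per outer fold is
refit on the full outer training set; the 50 refit models form the
ensemble.  Out-of-fold decision scores (mean over the permutations in
which a subject was a test case) feed the stacked combiner.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .tabprep import FeatureMatrix, PreprocModel, apply_preproc, fit_preproc

C_GRID = tuple(2.0**k for k in range(-4, 5))


class CVError(ValueError):
    pass


@dataclass
class OuterSplit:
    perm: int
    fold: int
    train: np.ndarray
    test: np.ndarray


@dataclass
class CVScheme:
    outer: list[OuterSplit]
    inner: list[list[tuple[np.ndarray, np.ndarray]]]  # absolute indices, per outer split
    seed: int
    n_subjects: int
    outer_folds: int
    outer_perms: int
    inner_folds: int
    inner_perms: int
    stratified: bool = True


def build_cv_scheme(
    labels: np.ndarray,
    outer_folds: int = 10,
    outer_perms: int = 5,
    inner_folds: int = 10,
    inner_perms: int = 5,
    seed: int = 0,
) -> CVScheme:
    """Label-stratified nested fold assignments, deterministic given seed."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    _, class_counts = np.unique(labels, return_counts=True)
    if class_counts.min() < outer_folds:
        raise CVError("smallest class has fewer subjects than outer folds")
    ss = np.random.SeedSequence(seed)
    outer_seeds, inner_seeds = ss.spawn(2)
    outer_rs = outer_seeds.generate_state(outer_perms)
    idx = np.arange(n)

    outer: list[OuterSplit] = []
    inner: list[list[tuple[np.ndarray, np.ndarray]]] = []
    inner_states = iter(inner_seeds.generate_state(outer_perms * outer_folds * inner_perms * 4))
    for p in range(outer_perms):
        skf = StratifiedKFold(outer_folds, shuffle=True, random_state=int(outer_rs[p]) % (2**32))
        for f, (tr, te) in enumerate(skf.split(idx, labels)):
            outer.append(OuterSplit(perm=p, fold=f, train=tr, test=te))
            y_tr = labels[tr]
            if np.unique(y_tr, return_counts=True)[1].min() < inner_folds:
                raise CVError("smallest class in an outer training set below inner fold count")
            splits = []
            for ip in range(inner_perms):
                iskf = StratifiedKFold(
                    inner_folds, shuffle=True, random_state=int(next(inner_states)) % (2**32)
                )
                for itr, ite in iskf.split(tr, y_tr):
                    splits.append((tr[itr], tr[ite]))
            inner.append(splits)
    return CVScheme(
        outer=outer,
        inner=inner,
        seed=seed,
        n_subjects=n,
        outer_folds=outer_folds,
        outer_perms=outer_perms,
        inner_folds=inner_folds,
        inner_perms=inner_perms,
    )


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float
    C: float
    selected_features: list[int]
    feature_names: list[str] = field(default_factory=list)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.selected_features] @ self.weights + self.bias


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float, class_weight=None) -> LinearModel:
    """Soft-margin linear SVM (hinge-loss primal, libsvm solver).

    Decision value = w.x + b; the returned model also carries the dual
    coefficients and support vectors so optimality conditions can be audited.
    ``class_weight="balanced"`` applies inverse-prevalence weights (off by
    default: cohorts are near 50/50).
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise CVError("training labels contain a single class")
    clf = SVC(C=C, kernel="linear", tol=1e-5, class_weight=class_weight)
    clf.fit(X, y)
    model = LinearModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        C=C,
        selected_features=list(range(X.shape[1])),
    )
    model.dual_coef = clf.dual_coef_.ravel().copy()
    model.support = clf.support_.copy()
    return model


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    pos, neg = y_true == 1, y_true == -1
    sens = (y_pred[pos] == 1).mean() if pos.any() else np.nan
    spec = (y_pred[neg] == -1).mean() if neg.any() else np.nan
    return float((sens + spec) / 2.0)


def _scores_to_pred(scores: np.ndarray) -> np.ndarray:
    return np.where(scores > 0, 1, -1)


def _inner_objective(X: np.ndarray, y: np.ndarray, splits, C: float, class_weight=None) -> float:
    """Mean over inner folds of (train BAC + test BAC) / 2; degenerate folds skipped."""
    vals = []
    for tr, te in splits:
        y_tr = y[tr]
        if np.unique(y_tr).size < 2 or np.unique(y[te]).size < 2:
            continue
        model = train_linear_svm(X[tr], y_tr, C, class_weight=class_weight)
        bac_tr = balanced_accuracy(y_tr, _scores_to_pred(model.decision(X[tr])))
        bac_te = balanced_accuracy(y[te], _scores_to_pred(model.decision(X[te])))
        vals.append((bac_tr + bac_te) / 2.0)
    if not vals:
        raise CVError("all inner folds degenerate")
    return float(np.mean(vals))


@dataclass
class SelectionTrace:
    steps: list[dict] = field(default_factory=list)


def wrapper_forward_select(
    X: np.ndarray,
    y: np.ndarray,
    inner_splits,
    C_grid=C_GRID,
    budget: int | None = None,
    class_weight=None,
) -> tuple[LinearModel, SelectionTrace]:
    """Greedy sequential forward search jointly over features and C.

    For every C, features are added one at a time, each step picking the
    feature that maximizes the inner objective, until ``ceil(0.1 * d)``
    features (or ``budget``) are selected.  The winner is the (C, feature
    set) with the best final objective; ties break toward smaller C, then
    lexicographic feature order.  The returned model is refit on all of X.
    """
    d = X.shape[1]
    if budget is None:
        budget = math.ceil(0.1 * d)
    budget = min(budget, d)
    trace = SelectionTrace()
    best = (-np.inf, None, None)  # objective, C, features
    for C in sorted(C_grid):
        selected: list[int] = []
        obj = -np.inf
        remaining = list(range(d))
        while len(selected) < budget:
            step_best = (-np.inf, None)
            for f in remaining:
                cand = selected + [f]
                val = _inner_objective(X[:, cand], y, inner_splits, C, class_weight)
                if val > step_best[0]:
                    step_best = (val, f)
            obj, f = step_best
            selected.append(f)
            remaining.remove(f)
            trace.steps.append({"C": C, "added": f, "objective": obj, "k": len(selected)})
        if obj > best[0]:
            best = (obj, C, selected)
    obj, C, selected = best
    model = train_linear_svm(X[:, selected], y, C, class_weight=class_weight)
    model.selected_features = selected
    model.C = C
    return model, trace


def select_c_only(X: np.ndarray, y: np.ndarray, inner_splits, C_grid=C_GRID, class_weight=None) -> LinearModel:
    """Pick the best C on the inner cycle using all features (no wrapper)."""
    best = (-np.inf, None)
    for C in sorted(C_grid):
        val = _inner_objective(X, y, inner_splits, C, class_weight)
        if val > best[0]:
            best = (val, C)
    model = train_linear_svm(X, y, best[1], class_weight=class_weight)
    model.selected_features = list(range(X.shape[1]))
    return model


@dataclass
class BaseModel:
    preproc: PreprocModel
    linear: LinearModel
    perm: int
    fold: int


@dataclass
class EnsembleModel:
    base: list[BaseModel]
    modality: str
    feature_names: list[str]
    aggregation: str = "mean_score"


@dataclass
class DecisionScoreTable:
    scores: np.ndarray
    predicted: np.ndarray  # +1 / -1, zero scores map to -1
    n_models: np.ndarray
    # one entry per contributing base model: perm, fold, test indices, raw scores
    provenance: list[dict] = field(default_factory=list)

    def frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.scores.shape[0]),
                "score": self.scores,
                "predicted": self.predicted,
                "n_models": self.n_models,
            }
        )

    def fold_bacs(self, y: np.ndarray) -> np.ndarray:
        """Per outer-split test BAC, in provenance order (blocks for Quade)."""
        return np.array(
            [
                balanced_accuracy(y[p["test"]], _scores_to_pred(p["scores"]))
                for p in self.provenance
            ]
        )


def train_unimodal(
    X: FeatureMatrix,
    y: np.ndarray,
    scheme: CVScheme,
    feature_selection: bool | None = None,
    C_grid=C_GRID,
    class_weight=None,
) -> tuple[EnsembleModel, DecisionScoreTable]:
    """Nested-CV training of one modality; returns ensemble + out-of-fold scores."""
    y = np.asarray(y)
    if X.n_subjects != scheme.n_subjects:
        raise CVError("scheme was built for a different cohort size")
    if feature_selection is None:
        feature_selection = X.modality in ("clinical", "cognitive")

    score_sum = np.zeros(X.n_subjects)
    score_cnt = np.zeros(X.n_subjects, dtype=int)
    base: list[BaseModel] = []
    provenance: list[dict] = []
    for osplit, inner_abs in zip(scheme.outer, scheme.inner):
        tr, te = osplit.train, osplit.test
        try:
            pm = fit_preproc(X.subset(tr))
            Xtr = apply_preproc(pm, X.subset(tr)).values
            pos = {int(s): i for i, s in enumerate(tr)}
            splits = [
                (
                    np.array([pos[int(s)] for s in itr], dtype=int),
                    np.array([pos[int(s)] for s in ite], dtype=int),
                )
                for itr, ite in inner_abs
            ]
            if feature_selection and Xtr.shape[1] >= 10:
                model, _ = wrapper_forward_select(Xtr, y[tr], splits, C_grid, class_weight=class_weight)
            else:
                model = select_c_only(Xtr, y[tr], splits, C_grid, class_weight=class_weight)
            Xte = apply_preproc(pm, X.subset(te)).values
            te_scores = model.decision(Xte)
        except CVError as exc:
            raise CVError(
                f"outer perm {osplit.perm} fold {osplit.fold}: {exc}"
            ) from exc
        model.feature_names = [pm.kept_feature_names[j] for j in model.selected_features]
        base.append(BaseModel(preproc=pm, linear=model, perm=osplit.perm, fold=osplit.fold))
        provenance.append(
            {"perm": osplit.perm, "fold": osplit.fold, "test": te, "scores": te_scores}
        )
        score_sum[te] += te_scores
        score_cnt[te] += 1

    scores = np.divide(score_sum, score_cnt, out=np.zeros_like(score_sum), where=score_cnt > 0)
    oof = DecisionScoreTable(
        scores=scores,
        predicted=_scores_to_pred(scores),
        n_models=score_cnt,
        provenance=provenance,
    )
    ensemble = EnsembleModel(base=base, modality=X.modality, feature_names=list(X.feature_names))
    return ensemble, oof


def predict_external(model: EnsembleModel, X_new: FeatureMatrix) -> DecisionScoreTable:
    """Push every subject through all frozen base models; mean decision score."""
    if list(X_new.feature_names) != list(model.feature_names):
        raise CVError("feature names do not match the trained modality")
    total = np.zeros(X_new.n_subjects)
    for bm in model.base:
        Xp = apply_preproc(bm.preproc, X_new).values
        total += bm.linear.decision(Xp)
    scores = total / len(model.base)
    return DecisionScoreTable(
        scores=scores,
        predicted=_scores_to_pred(scores),
        n_models=np.full(X_new.n_subjects, len(model.base)),
    )


def oof_bac(oof: DecisionScoreTable, y: np.ndarray) -> float:
    return balanced_accuracy(y, oof.predicted)


def stack_scores(oof_tables: list[DecisionScoreTable], modality_names: list[str]) -> FeatureMatrix:
    n = oof_tables[0].scores.shape[0]
    values = np.full((n, len(oof_tables)), np.nan)
    for j, tab in enumerate(oof_tables):
        if tab.scores.shape[0] != n:
            raise CVError("mismatched subject sets across modalities")
        ok = tab.n_models > 0
        values[ok, j] = tab.scores[ok]
    return FeatureMatrix.from_values(values, modality_names, "stacked_scores")


def train_stacked(
    oof_tables: list[DecisionScoreTable],
    y: np.ndarray,
    scheme: CVScheme,
    modality_names: list[str] | None = None,
    C_grid=C_GRID,
) -> tuple[EnsembleModel, DecisionScoreTable]:
    """Stacked combiner over unimodal out-of-fold decision scores."""
    if len(oof_tables) < 2:
        raise CVError("stacking requires at least 2 unimodal score tables")
    if modality_names is None:
        modality_names = [f"m{j}" for j in range(len(oof_tables))]
    X = stack_scores(oof_tables, modality_names)
    use_wrapper = X.n_features > 3
    return train_unimodal(X, y, scheme, feature_selection=use_wrapper, C_grid=C_grid)


# ---------------------------------------------------------------------------
# serialization


def ensemble_to_json(model: EnsembleModel, path) -> None:
    payload = {
        "version": 1,
        "modality": model.modality,
        "aggregation": model.aggregation,
        "feature_names": model.feature_names,
        "base": [
            {
                "perm": bm.perm,
                "fold": bm.fold,
                "weights": bm.linear.weights.tolist(),
                "bias": bm.linear.bias,
                "C": bm.linear.C,
                "selected_features": bm.linear.selected_features,
                "selected_names": bm.linear.feature_names,
                "preproc": {
                    "center": bm.preproc.center.tolist(),
                    "spread": bm.preproc.spread.tolist(),
                    "keep_mask": bm.preproc.keep_mask.tolist(),
                    "minmax_lo": bm.preproc.minmax_lo.tolist(),
                    "minmax_hi": bm.preproc.minmax_hi.tolist(),
                    "feature_names": bm.preproc.feature_names,
                    "modality": bm.preproc.modality,
                    "knn_k": bm.preproc.knn_k,
                    "training_reference": np.where(
                        np.isnan(bm.preproc.training_reference),
                        None,
                        bm.preproc.training_reference,
                    ).tolist(),
                },
            }
            for bm in model.base
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def ensemble_from_json(path) -> EnsembleModel:
    with open(path) as fh:
        payload = json.load(fh)
    base = []
    for b in payload["base"]:
        pp = b["preproc"]
        ref = np.array(
            [[np.nan if v is None else v for v in row] for row in pp["training_reference"]],
            dtype=float,
        )
        preproc = PreprocModel(
            center=np.asarray(pp["center"], dtype=float),
            spread=np.asarray(pp["spread"], dtype=float),
            keep_mask=np.asarray(pp["keep_mask"], dtype=bool),
            minmax_lo=np.asarray(pp["minmax_lo"], dtype=float),
            minmax_hi=np.asarray(pp["minmax_hi"], dtype=float),
            feature_names=list(pp["feature_names"]),
            modality=pp["modality"],
            knn_k=int(pp["knn_k"]),
            training_reference=ref,
        )
        linear = LinearModel(
            weights=np.asarray(b["weights"], dtype=float),
            bias=float(b["bias"]),
            C=float(b["C"]),
            selected_features=list(b["selected_features"]),
            feature_names=list(b["selected_names"]),
        )
        base.append(BaseModel(preproc=preproc, linear=linear, perm=b["perm"], fold=b["fold"]))
    return EnsembleModel(
        base=base,
        modality=payload["modality"],
        feature_names=list(payload["feature_names"]),
        aggregation=payload["aggregation"],
    )
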