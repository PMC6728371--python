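"""Cost-sensitive random forest with forward feature selection.

The classifier is a bagged ensemble of CART trees (Gini splits, sqrt-of-
features candidates per split, 301 trees) in the scikit-learn estimator
idiom.  Class priors are uniform and asymmetric misclassification costs
enter as class weights (weight ratio = cost ratio), so raising the
false-negative cost shifts votes toward calling alarms true.

Feature selection follows the out-of-bag (OOB) permutation-importance
recipe: for every tree, the increase in OOB error when one feature is
permuted across that tree's OOB rows, averaged over the ensemble and
divided by the standard deviation over the ensemble.  Forward selection
adds features in importance order, scores each prefix with record-grouped
leave-one-out cross-validation (LOOCV), repeats the whole procedure with
fresh seeds, locates the plateau of the median score curve, and keeps 1.2x
the plateau point (rounded up), symmetrized so both ECG leads contribute
the same features.
"""

from __future__ import annotations

import json
import math
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .config import ModelConfig
from .evaluate import challenge_score
from .records import Arrhythmia, FeatureTable, Label

__all__ = [
    "CostSensitiveForest",
    "TrainedAlarmModel",
    "train_rf",
    "predict",
    "oob_importance",
    "loocv_score",
    "forward_selection",
    "tune_fn_cost",
    "build_final_model",
]


def _fit_forest(X32: np.ndarray, y: np.ndarray, sample_weight: np.ndarray,
                n_trees: int, seed: int, max_features) -> tuple[list, np.ndarray]:
    """Bagged CART fit on pre-validated float32 data (fast inner loop)."""
    n = X32.shape[0]
    tree_seeds = np.random.SeedSequence(
        [seed & 0x7FFFFFFF, 0xB0057]).generate_state(n_trees)
    trees = []
    inbag = np.zeros((n_trees, n), dtype=bool)
    for t in range(n_trees):
        rng = np.random.default_rng(tree_seeds[t])
        idx = rng.integers(0, n, n)
        inbag[t, np.unique(idx)] = True
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=max_features,
            random_state=int(tree_seeds[t] & 0x7FFFFFFF))
        tree.fit(X32[idx], y[idx], sample_weight=sample_weight[idx],
                 check_input=False)
        trees.append(tree)
    return trees, inbag


def _forest_votes(trees: list, X32: np.ndarray) -> np.ndarray:
    agg = np.zeros(X32.shape[0])
    for tree in trees:
        agg += tree.predict(X32, check_input=False)
    return agg / len(trees)


def _class_weights(y: np.ndarray, cost_fp: float, cost_fn: float) -> np.ndarray:
    """Uniform prior (inverse frequency) times misclassification cost."""
    n = y.size
    freq = np.bincount(y.astype(int), minlength=2) / n
    cost = np.array([cost_fp, cost_fn])
    class_w = cost / np.maximum(freq, 1e-12)
    class_w = class_w / class_w.sum()
    return class_w[y.astype(int)]


class CostSensitiveForest(BaseEstimator, ClassifierMixin):
    """Bagged CART ensemble with uniform prior and cost-ratio class weights.

    Parameters
    ----------
    n_trees : ensemble size (301 by default).
    cost_fp, cost_fn : misclassification costs; the positive class (true
        alarm) is weighted by ``cost_fn`` and the negative by ``cost_fp``,
        on top of a uniform prior (each class weighted inversely to its
        frequency).
    max_features : candidate features per split ("sqrt" rule).
    random_state : seed for bootstrap draws and tree randomness.

    NaN features are imputed with training-set medians (stored in
    ``medians_``).  ``predict`` is the unweighted mode of the tree votes.
    """

    def __init__(self, n_trees: int = 301, cost_fp: float = 1.0,
                 cost_fn: float = 1.0, max_features: str | int = "sqrt",
                 random_state: int = 0):
        self.n_trees = n_trees
        self.cost_fp = cost_fp
        self.cost_fn = cost_fn
        self.max_features = max_features
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                missing = set(self.feature_names_in_) - set(X.columns)
                extra = set(X.columns) - set(self.feature_names_in_)
                if missing or extra:
                    raise ValueError(
                        f"feature mismatch: missing={sorted(missing)}, "
                        f"unknown={sorted(extra)}")
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return X

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = X.copy()
        for j in range(X.shape[1]):
            col = X[:, j]
            bad = ~np.isfinite(col)
            if bad.any():
                col[bad] = self.medians_[j]
                X[:, j] = col
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values after imputation")
        return X

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        Xv = self._validate(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        if self.classes_.size > 2:
            raise ValueError("binary classification only")
        if not (self.cost_fn >= self.cost_fp > 0):
            raise ValueError("costs must satisfy cost_fn >= cost_fp > 0")
        finite = np.where(np.isfinite(Xv), Xv, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            med = np.nanmedian(finite, axis=0)
        self.medians_ = np.where(np.isfinite(med), med, 0.0)
        Xv = self._impute(Xv)
        n, self.n_features_in_ = Xv.shape

        # uniform prior (1/freq) times cost of misclassifying the class
        # (class 0 = false alarm, class 1 = true alarm)
        sample_weight = _class_weights(y_enc, self.cost_fp, self.cost_fn)

        X32 = np.ascontiguousarray(Xv, dtype=np.float32)
        self.estimators_, self.inbag_ = _fit_forest(
            X32, y_enc.astype(np.float64), sample_weight, self.n_trees,
            self.random_state, self.max_features)
        self._y_enc = y_enc
        self._X_fit = X32
        return self

    def _votes(self, Xv: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for the positive class, per row."""
        return _forest_votes(self.estimators_,
                             np.ascontiguousarray(Xv, dtype=np.float32))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        Xv = self._impute(self._validate(X))
        v = self._votes(Xv)
        return np.column_stack([1.0 - v, v])

    def predict(self, X):
        v = self.predict_proba(X)[:, 1]
        return self.classes_[(v >= 0.5).astype(int)]

    # -- OOB permutation importance --------------------------------------
    def oob_importance_(self) -> np.ndarray:
        """Per-feature importance: mean over trees of the OOB error increase
        under within-OOB permutation, divided by the std over trees."""
        check_is_fitted(self, "estimators_")
        X, y = self._X_fit, self._y_enc
        n_feat = X.shape[1]
        deltas = np.zeros((len(self.estimators_), n_feat))
        ss = np.random.SeedSequence([self.random_state & 0x7FFFFFFF, 0x1339])
        perm_seeds = ss.generate_state(len(self.estimators_))
        for t, tree in enumerate(self.estimators_):
            oob = ~self.inbag_[t]
            if not oob.any():
                continue
            Xo = np.ascontiguousarray(X[oob])
            yo = y[oob]
            base_err = np.mean(tree.predict(Xo, check_input=False) != yo)
            rng = np.random.default_rng(perm_seeds[t])
            Xp = Xo.copy()
            for j in range(n_feat):
                col = Xo[:, j]
                if np.all(col == col[0]):
                    continue  # permutation is a no-op
                Xp[:, j] = rng.permutation(col)
                deltas[t, j] = (
                    np.mean(tree.predict(Xp, check_input=False) != yo)
                    - base_err)
                Xp[:, j] = col
        mean = deltas.mean(axis=0)
        std = deltas.std(axis=0)
        return np.where(std > 0, mean / np.where(std > 0, std, 1.0), 0.0)


# ---------------------------------------------------------------------------
# module-level operations on feature tables


def _forest_from_cfg(cfg: ModelConfig, cost_fn: float, seed: int,
                     n_trees: int | None = None) -> CostSensitiveForest:
    return CostSensitiveForest(
        n_trees=n_trees or cfg.n_trees,
        cost_fp=cfg.cost_fp,
        cost_fn=cost_fn,
        random_state=seed,
    )


def train_rf(table: FeatureTable, cfg: ModelConfig | None = None,
             cost_fn: float = 1.0, seed: int = 0,
             n_trees: int | None = None) -> CostSensitiveForest:
    """Fit the cost-sensitive forest on a feature table."""
    cfg = cfg or ModelConfig()
    clf = _forest_from_cfg(cfg, cost_fn, seed, n_trees)
    clf.fit(table.features, table.y)
    return clf


def predict(model: CostSensitiveForest, vector: dict[str, float] | pd.Series
            ) -> tuple[Label, float]:
    """Classify one feature vector; returns (label, positive-vote fraction)."""
    row = pd.DataFrame([dict(vector)])
    vote = float(model.predict_proba(row)[0, 1])
    return (Label.TRUE_ALARM if vote >= 0.5 else Label.FALSE_ALARM), vote


def oob_importance(table: FeatureTable, cfg: ModelConfig | None = None,
                   cost_fn: float = 1.0, seed: int = 0,
                   n_trees: int | None = None) -> pd.Series:
    """OOB permutation importance per feature (TreeBagger-style scaling)."""
    clf = train_rf(table, cfg, cost_fn, seed, n_trees)
    return pd.Series(clf.oob_importance_(), index=table.feature_names)


def loocv_score(table: FeatureTable, cfg: ModelConfig | None = None,
                feature_subset: list[str] | None = None,
                cost_fn: float = 1.0, seed: int = 0,
                n_trees: int | None = None) -> dict[str, float]:
    """Record-grouped leave-one-out cross-validation.

    All rows of one record (the four augmented VF rows) are held out
    together; the held-out record's prediction is the mean positive-vote
    fraction over its rows (ties go to the fail-safe true-alarm side).
    Returns the challenge score and the confusion counts.
    """
    cfg = cfg or ModelConfig()
    sub = table.subset_features(feature_subset) if feature_subset else table
    rids = np.asarray(sub.record_ids)
    y = sub.y
    unique_rids = list(dict.fromkeys(sub.record_ids))
    if len(unique_rids) < 2:
        raise ValueError("need at least 2 records for LOOCV")
    tp = tn = fp = fn = 0
    Xall = sub.features.to_numpy(dtype=np.float32)
    n_trees = n_trees or cfg.n_trees_selection
    for rid in unique_rids:
        held = rids == rid
        ytr = y[~held]
        if np.unique(ytr).size < 2:
            # degenerate fold: predict the cost-weighted majority
            vote = 1.0 if ytr.mean() >= 0.5 else 0.0
        else:
            Xtr = np.ascontiguousarray(Xall[~held])
            # imputation medians from the training fold only
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(Xtr, axis=0)
            med = np.where(np.isfinite(med), med, 0.0).astype(np.float32)
            nan_tr = ~np.isfinite(Xtr)
            if nan_tr.any():
                Xtr[nan_tr] = np.broadcast_to(med, Xtr.shape)[nan_tr]
            Xte = np.ascontiguousarray(Xall[held])
            nan_te = ~np.isfinite(Xte)
            if nan_te.any():
                Xte[nan_te] = np.broadcast_to(med, Xte.shape)[nan_te]
            sw = _class_weights(ytr, cfg.cost_fp, cost_fn)
            trees, _ = _fit_forest(Xtr, ytr.astype(np.float64), sw, n_trees,
                                   seed, "sqrt")
            vote = float(_forest_votes(trees, Xte).mean())
        pred_true = vote >= 0.5
        truth_true = bool(y[held][0])
        if truth_true and pred_true:
            tp += 1
        elif truth_true:
            fn += 1
        elif pred_true:
            fp += 1
        else:
            tn += 1
    return {"score": challenge_score(tp, tn, fp, fn),
            "tp": tp, "tn": tn, "fp": fp, "fn": fn}


def _k_grid(n_features: int, max_points: int = 7) -> list[int]:
    """Evaluation prefixes for the score curve: dense small k, sparse large."""
    ks: list[int] = []
    k = 1
    while k <= n_features:
        ks.append(k)
        k = k + 1 if k < 5 else int(math.ceil(k * 1.6))
    if ks[-1] != n_features:
        ks.append(n_features)
    if len(ks) > max_points:
        head = ks[:4]
        tail = ks[4:]
        stride = max(1, math.ceil(len(tail) / (max_points - 4)))
        ks = head + tail[::stride]
        if ks[-1] != n_features:
            ks.append(n_features)
    return sorted(set(ks))


def _symmetrize_ecg(names: list[str], registry: list[str]) -> list[str]:
    """Any ecg1_* feature brings its ecg2_* twin and vice versa."""
    out = list(names)
    for name in names:
        for a, b in (("ecg1_", "ecg2_"), ("ecg2_", "ecg1_")):
            if name.startswith(a):
                twin = b + name[len(a):]
                if twin in registry and twin not in out:
                    out.append(twin)
    return out


def forward_selection(table: FeatureTable, cfg: ModelConfig | None = None,
                      cost_fn: float = 1.0, seed: int = 0,
                      repeats: int | None = None) -> dict:
    """Importance-ordered forward selection with LOOCV score curves.

    Each repeat ranks features by OOB permutation importance and scores
    top-k prefixes with LOOCV; the plateau point x is the smallest k whose
    median score (across repeats) is within ``plateau_tol`` of the best
    median, and the final set keeps ceil(1.2*x) features plus ECG twins.
    """
    cfg = cfg or ModelConfig()
    repeats = repeats or cfg.selection_repeats
    names = table.feature_names
    if len(names) < 2:
        raise ValueError("need at least 2 features for selection")
    ks = _k_grid(len(names))
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 0x5E1EC7])
    rep_seeds = ss.generate_state(repeats)
    curves = np.zeros((repeats, len(ks)))
    importances = np.zeros((repeats, len(names)))
    for r in range(repeats):
        rs = int(rep_seeds[r] & 0x7FFFFFFF)
        imp = oob_importance(table, cfg, cost_fn, rs, cfg.n_trees_selection)
        importances[r] = imp.to_numpy()
        order = list(imp.sort_values(ascending=False).index)
        for ki, k in enumerate(ks):
            res = loocv_score(table, cfg, order[:k], cost_fn, rs,
                              cfg.n_trees_selection)
            curves[r, ki] = res["score"]
    median_curve = np.median(curves, axis=0)
    mean_curve = curves.mean(axis=0)
    best = median_curve.max()
    x = next(k for k, m in zip(ks, median_curve)
             if m >= best - cfg.plateau_tol)
    mean_imp = pd.Series(importances.mean(axis=0), index=names)
    ranked = list(mean_imp.sort_values(ascending=False).index)
    n_final = min(len(names), int(math.ceil(cfg.expansion * x)))
    final = _symmetrize_ecg(ranked[:n_final], names)
    return {
        "ranked_features": ranked,
        "importance_mean": mean_imp.to_dict(),
        "k_grid": ks,
        "mean_curve": mean_curve.tolist(),
        "median_curve": median_curve.tolist(),
        "chosen_x": int(x),
        "final_features": final,
    }


def tune_fn_cost(table: FeatureTable, cfg: ModelConfig | None = None,
                 feature_subset: list[str] | None = None, seed: int = 0,
                 grid: tuple[float, ...] | None = None) -> dict:
    """Grid-search the false-negative cost maximizing the LOOCV score.

    Ties break toward the smallest cost; the full cost->score table is
    returned for diagnostics.
    """
    cfg = cfg or ModelConfig()
    grid = tuple(grid if grid is not None else cfg.cost_fn_grid)
    if not grid:
        raise ValueError("empty cost grid")
    results = {}
    for c in grid:
        results[float(c)] = loocv_score(table, cfg, feature_subset, float(c),
                                        seed, cfg.n_trees_selection)
    best_cost = max(sorted(results), key=lambda c: (results[c]["score"], -c))
    return {"best_cost_fn": float(best_cost),
            "best_score": results[best_cost]["score"],
            "curve": {c: r["score"] for c, r in results.items()},
            "detail": results}


@dataclass
class TrainedAlarmModel:
    """Final per-arrhythmia classifier bundle."""

    arrhythmia: Arrhythmia
    selected_features: list[str]
    forest: CostSensitiveForest
    cost_fn: float
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def predict_record(self, rows: list[dict[str, float]]) -> tuple[Label, float]:
        """Record-level label from one or more window rows (mean vote)."""
        X = pd.DataFrame(rows)[self.selected_features]
        vote = float(self.forest.predict_proba(X)[:, 1].mean())
        return (Label.TRUE_ALARM if vote >= 0.5 else Label.FALSE_ALARM), vote

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = self.arrhythmia.value.lower()
        meta = {
            "arrhythmia": self.arrhythmia.value,
            "selected_features": self.selected_features,
            "cost_fn": self.cost_fn,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
        }
        (out / f"{stem}.json").write_text(json.dumps(meta, indent=2))
        with open(out / f"{stem}.pkl", "wb") as fh:
            pickle.dump(self.forest, fh)
        return out / f"{stem}.json"

    @classmethod
    def load(cls, json_path: str | Path) -> "TrainedAlarmModel":
        path = Path(json_path)
        meta = json.loads(path.read_text())
        with open(path.with_suffix(".pkl"), "rb") as fh:
            forest = pickle.load(fh)
        return cls(
            arrhythmia=Arrhythmia(meta["arrhythmia"]),
            selected_features=meta["selected_features"],
            forest=forest,
            cost_fn=meta["cost_fn"],
            seed=meta["seed"],
            diagnostics=meta.get("diagnostics", {}),
        )


def build_final_model(table: FeatureTable, arrhythmia: Arrhythmia | None = None,
                      cfg: ModelConfig | None = None, seed: int = 0
                      ) -> TrainedAlarmModel:
    """Forward selection, cost tuning, then a full-data 301-tree forest."""
    cfg = cfg or ModelConfig()
    if len(table) == 0:
        raise ValueError("empty feature table")
    arr = Arrhythmia(arrhythmia or table.arrhythmia)
    sel = forward_selection(table, cfg, cost_fn=1.0, seed=seed)
    tuned = tune_fn_cost(table, cfg, sel["final_features"], seed=seed)
    forest = train_rf(table.subset_features(sel["final_features"]), cfg,
                      cost_fn=tuned["best_cost_fn"], seed=seed,
                      n_trees=cfg.n_trees)
    return TrainedAlarmModel(
        arrhythmia=arr,
        selected_features=sel["final_features"],
        forest=forest,
        cost_fn=tuned["best_cost_fn"],
        seed=seed,
        diagnostics={"selection": {k: v for k, v in sel.items()
                                   if k != "importance_mean"},
                     "cost_curve": tuned["curve"]},
    )
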