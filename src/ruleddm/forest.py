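"""From-scratch random forests with OOB-based permutation importance.

Classification (trial accuracy) uses Gini splitting with every feature
available at each node (pure bagging); regression (log RT of correct
trials) uses variance-reduction splitting with a third of the features
drawn per node.  Both share the regularisation of the study's models:
maximum depth 10, minimum leaf size 5, bootstrap resampling with stored
out-of-bag (OOB) index sets.  For binary 0/1 targets the Gini criterion
coincides with variance reduction, so a single split scorer serves both
tasks.

Generalisation is measured two ways — OOB aggregation and grouped K-fold
cross-validation split at the participant level — and feature importance
is the average OOB performance drop over repeated permutations of one
feature, normalised to sum to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .features import FEATURE_COLUMNS

__all__ = ["ForestConfig", "Forest", "train_forest", "group_kfold",
           "evaluate", "permutation_importance", "topk_refit",
           "gini_impurity", "ImportanceResult"]


def gini_impurity(y) -> float:
    """Gini impurity ``1 - sum_c p_c^2`` of a label vector."""
    y = np.asarray(y)
    if y.size == 0:
        return 0.0
    _, counts = np.unique(y, return_counts=True)
    p = counts / y.size
    return float(1.0 - np.sum(p * p))


@dataclass
class ForestConfig:
    """Forest hyperparameters (depth/leaf limits follow the study)."""

    task: str = "classification"        # or "regression"
    n_trees: int = 300
    max_depth: int = 10
    min_leaf: int = 5
    mtry: str | None = None             # "all" | "third"; None = task default
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        if self.mtry is None:
            self.mtry = "all" if self.task == "classification" else "third"

    def mtry_count(self, n_features: int) -> int:
        return n_features if self.mtry == "all" else int(math.ceil(n_features / 3))


@njit(cache=True)
def _build_tree(X, y, boot, max_depth, min_leaf, mtry,
                feat, thr, left, right, value):
    """Grow one CART tree on the bootstrap index set; returns node count.

    Splits minimise the summed child impurity n_l*imp_l + n_r*imp_r where
    imp is the variance-style score sum(y^2) - sum(y)^2/n (equal to n/2 x
    Gini for 0/1 targets).
    """
    n_feat = X.shape[1]
    idx = boot.copy()
    # stack of (node, lo, hi, depth)
    stack = np.empty((idx.shape[0] * 2 + 4, 4), dtype=np.int64)
    top = 0
    stack[top, 0] = 0
    stack[top, 1] = 0
    stack[top, 2] = idx.shape[0]
    stack[top, 3] = 0
    top += 1
    n_nodes = 1
    featbuf = np.empty(n_feat, dtype=np.int64)
    while top > 0:
        top -= 1
        node = stack[top, 0]
        lo = stack[top, 1]
        hi = stack[top, 2]
        depth = stack[top, 3]
        n = hi - lo
        s = 0.0
        s2 = 0.0
        for i in range(lo, hi):
            yv = y[idx[i]]
            s += yv
            s2 += yv * yv
        mean = s / n
        feat[node] = -1
        value[node] = mean
        if depth >= max_depth or n < 2 * min_leaf:
            continue
        parent_ss = s2 - s * s / n
        if parent_ss <= 1e-12:
            continue
        # candidate features: random subset of size mtry
        for f in range(n_feat):
            featbuf[f] = f
        for f in range(n_feat - 1, 0, -1):
            r = np.random.randint(0, f + 1)
            tmp = featbuf[f]
            featbuf[f] = featbuf[r]
            featbuf[r] = tmp
        best_score = parent_ss
        best_f = -1
        best_t = 0.0
        for fi in range(mtry):
            f = featbuf[fi]
            vals = np.empty(n)
            for i in range(n):
                vals[i] = X[idx[lo + i], f]
            order = np.argsort(vals)
            sl = 0.0
            sl2 = 0.0
            for pos in range(n - 1):
                yv = y[idx[lo + order[pos]]]
                sl += yv
                sl2 += yv * yv
                nl = pos + 1
                nr = n - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                vcur = vals[order[pos]]
                vnext = vals[order[pos + 1]]
                if vnext <= vcur:
                    continue
                sr = s - sl
                sr2 = s2 - sl2
                score = (sl2 - sl * sl / nl) + (sr2 - sr * sr / nr)
                if score < best_score - 1e-12:
                    best_score = score
                    best_f = f
                    best_t = 0.5 * (vcur + vnext)
        if best_f < 0:
            continue
        # partition idx[lo:hi] by the chosen split
        buf = np.empty(n, dtype=np.int64)
        nl = 0
        nr = 0
        for i in range(lo, hi):
            if X[idx[i], best_f] <= best_t:
                buf[nl] = idx[i]
                nl += 1
        for i in range(lo, hi):
            if X[idx[i], best_f] > best_t:
                buf[nl + nr] = idx[i]
                nr += 1
        for i in range(n):
            idx[lo + i] = buf[i]
        feat[node] = best_f
        thr[node] = best_t
        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        left[node] = lchild
        right[node] = rchild
        stack[top, 0] = lchild
        stack[top, 1] = lo
        stack[top, 2] = lo + nl
        stack[top, 3] = depth + 1
        top += 1
        stack[top, 0] = rchild
        stack[top, 1] = lo + nl
        stack[top, 2] = hi
        stack[top, 3] = depth + 1
        top += 1
    return n_nodes


@njit(cache=True)
def _predict_tree(X, rows, feat, thr, left, right, value, out):
    for ri in range(rows.shape[0]):
        i = rows[ri]
        node = 0
        while feat[node] >= 0:
            if X[i, feat[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[ri] = value[node]


@njit(cache=True)
def _build_forest(X, y, n_trees, max_depth, min_leaf, mtry, seed,
                  feat, thr, left, right, value, oob):
    n = X.shape[0]
    np.random.seed(seed)
    for t in range(n_trees):
        boot = np.random.randint(0, n, n)
        inbag = np.zeros(n, dtype=np.bool_)
        for i in range(n):
            inbag[boot[i]] = True
        for i in range(n):
            oob[t, i] = not inbag[i]
        _build_tree(X, y, boot, max_depth, min_leaf, mtry,
                    feat[t], thr[t], left[t], right[t], value[t])


@njit(cache=True)
def _oob_aggregate(X, feat, thr, left, right, value, oob, perm_f, perm_rows):
    """Sum of per-tree OOB predictions and counts per sample.

    ``perm_f >= 0`` substitutes feature perm_f with its values taken from
    the row indices in ``perm_rows`` (a permutation), emulating permuting
    that feature within the OOB samples.
    """
    n_trees = feat.shape[0]
    n = X.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for t in range(n_trees):
        for i in range(n):
            if not oob[t, i]:
                continue
            node = 0
            while feat[t, node] >= 0:
                f = feat[t, node]
                if f == perm_f:
                    xv = X[perm_rows[i], f]
                else:
                    xv = X[i, f]
                if xv <= thr[t, node]:
                    node = left[t, node]
                else:
                    node = right[t, node]
            sums[i] += value[t, node]
            counts[i] += 1
    return sums, counts


@dataclass
class Forest:
    """A trained forest: tree arrays plus per-tree OOB index sets."""

    cfg: ForestConfig
    feature_names: list
    feat: np.ndarray
    thr: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    oob: np.ndarray           # (n_trees, n_train) bool
    X_train: np.ndarray = field(repr=False, default=None)
    y_train: np.ndarray = field(repr=False, default=None)

    @property
    def n_trees(self) -> int:
        return self.feat.shape[0]

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Mean tree output: class-1 probability or regression mean."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        rows = np.arange(X.shape[0], dtype=np.int64)
        out = np.zeros(X.shape[0])
        buf = np.empty(X.shape[0])
        for t in range(self.n_trees):
            _predict_tree(X, rows, self.feat[t], self.thr[t], self.left[t],
                          self.right[t], self.value[t], buf)
            out += buf
        return out / self.n_trees

    def predict(self, X: np.ndarray) -> np.ndarray:
        raw = self.predict_raw(X)
        if self.cfg.task == "classification":
            return (raw >= 0.5).astype(int)
        return raw

    def oob_predictions(self, perm_f: int = -1,
                        perm_rows: np.ndarray | None = None):
        """OOB-aggregated predictions; samples never OOB are masked out."""
        if perm_rows is None:
            perm_rows = np.arange(self.X_train.shape[0], dtype=np.int64)
        sums, counts = _oob_aggregate(self.X_train, self.feat, self.thr,
                                      self.left, self.right, self.value,
                                      self.oob, perm_f, perm_rows)
        mask = counts > 0
        pred = np.full(sums.shape, np.nan)
        pred[mask] = sums[mask] / counts[mask]
        return pred, mask


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        names = feature_names or [c for c in FEATURE_COLUMNS if c in X.columns]
        return np.ascontiguousarray(X[names].to_numpy(dtype=np.float64)), list(names)
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


def train_forest(X, y, cfg: ForestConfig, feature_names=None) -> Forest:
    """Train a forest of CART trees on bootstrap resamples.

    ``X`` may be a feature DataFrame (the 11 canonical columns are picked
    out) or a plain matrix.  Reproducible under ``cfg.seed``.
    """
    Xm, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=np.float64)
    if np.any(~np.isfinite(Xm)) or np.any(~np.isfinite(y)):
        raise ValueError("features and targets must be finite")
    if cfg.task == "classification" and np.unique(y).size < 2:
        raise ValueError("degenerate classification target: single class")
    n, n_feat = Xm.shape
    mtry = cfg.mtry_count(n_feat)
    max_nodes = 2 ** (cfg.max_depth + 1) + 1
    feat = np.full((cfg.n_trees, max_nodes), -1, dtype=np.int64)
    thr = np.zeros((cfg.n_trees, max_nodes))
    left = np.zeros((cfg.n_trees, max_nodes), dtype=np.int64)
    right = np.zeros((cfg.n_trees, max_nodes), dtype=np.int64)
    value = np.zeros((cfg.n_trees, max_nodes))
    oob = np.zeros((cfg.n_trees, n), dtype=np.bool_)
    _build_forest(Xm, y, cfg.n_trees, cfg.max_depth, cfg.min_leaf, mtry,
                  cfg.seed & 0x7FFFFFFF, feat, thr, left, right, value, oob)
    return Forest(cfg=cfg, feature_names=names, feat=feat, thr=thr, left=left,
                  right=right, value=value, oob=oob, X_train=Xm, y_train=y)


def group_kfold(groups, K: int = 5, seed: int = 0) -> np.ndarray:
    """Participant-level fold assignment: no group straddles folds.

    Groups are shuffled under ``seed`` and dealt into K folds whose sizes
    (in groups) differ by at most one.  Returns a fold label per sample.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if K < 2:
        raise ValueError("K must be >= 2")
    if uniq.size < K:
        raise ValueError(f"need at least K={K} distinct groups, got {uniq.size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    fold_of_group = {g: i % K for i, g in enumerate(perm)}
    return np.array([fold_of_group[g] for g in groups])


def _metrics(task: str, y_true, y_pred_raw) -> dict:
    y_true = np.asarray(y_true, dtype=float)
    if task == "classification":
        pred = (np.asarray(y_pred_raw) >= 0.5).astype(int)
        acc = float(np.mean(pred == y_true))
        tp = float(np.sum((pred == 1) & (y_true == 1)))
        fp = float(np.sum((pred == 1) & (y_true == 0)))
        fn = float(np.sum((pred == 0) & (y_true == 1)))
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        return {"accuracy": acc, "f1": f1}
    resid = np.asarray(y_pred_raw) - y_true
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return {"rmse": rmse, "r2": r2}


def evaluate(forest: Forest, X=None, y=None, scheme: str = "oob",
             groups=None, K: int = 5, seed: int = 0) -> dict:
    """Generalisation metrics by OOB aggregation or grouped K-fold CV.

    ``scheme='oob'`` scores the training data using only out-of-bag trees.
    ``scheme='group_cv'`` retrains a clone of the forest per fold with the
    participant-level splits of :func:`group_kfold` and scores the held-out
    participants; requires ``X``, ``y`` and ``groups``.
    """
    if scheme == "oob":
        pred, mask = forest.oob_predictions()
        return _metrics(forest.cfg.task, forest.y_train[mask], pred[mask])
    if scheme != "group_cv":
        raise ValueError("scheme must be 'oob' or 'group_cv'")
    Xm, names = _as_matrix(X, forest.feature_names)
    y = np.asarray(y, dtype=np.float64)
    folds = group_kfold(groups, K=K, seed=seed)
    per_fold = []
    for f in range(K):
        tr = folds != f
        te = folds == f
        clone = train_forest(Xm[tr], y[tr], forest.cfg, feature_names=names)
        per_fold.append(_metrics(forest.cfg.task, y[te], clone.predict_raw(Xm[te])))
    out = {k: float(np.mean([m[k] for m in per_fold])) for k in per_fold[0]}
    out["per_fold"] = per_fold
    return out


@dataclass
class ImportanceResult:
    table: pd.DataFrame    # feature, mean_drop, normalized
    metric: str
    repeats: int

    def ranking(self) -> list:
        return list(self.table.sort_values("normalized", ascending=False)["feature"])


def permutation_importance(forest: Forest, repeats: int = 50,
                           seed: int = 0) -> ImportanceResult:
    """OOB permutation importance, averaged over repeats and normalised.

    Per repeat and feature, the feature's values are permuted within the
    OOB sample set, OOB predictions are re-aggregated and the performance
    drop (accuracy drop for classification, RMSE increase for regression)
    is recorded.  Mean drops are floored at zero and divided by the sum of
    positive drops so the normalised scores sum to one.
    """
    task = forest.cfg.task
    metric = "accuracy" if task == "classification" else "rmse"
    base_pred, mask = forest.oob_predictions()
    base = _metrics(task, forest.y_train[mask], base_pred[mask])[metric]
    n = forest.X_train.shape[0]
    n_feat = len(forest.feature_names)
    rng = np.random.default_rng(seed)
    drops = np.zeros((repeats, n_feat))
    for r in range(repeats):
        for f in range(n_feat):
            perm_rows = rng.permutation(n).astype(np.int64)
            pred, m = forest.oob_predictions(perm_f=f, perm_rows=perm_rows)
            score = _metrics(task, forest.y_train[m], pred[m])[metric]
            drops[r, f] = (base - score) if metric == "accuracy" else (score - base)
    mean_drop = drops.mean(axis=0)
    pos = np.clip(mean_drop, 0.0, None)
    total = pos.sum()
    norm = pos / total if total > 0 else pos
    table = pd.DataFrame({"feature": forest.feature_names,
                          "mean_drop": mean_drop, "normalized": norm})
    return ImportanceResult(table=table, metric=metric, repeats=repeats)


def topk_refit(X, y, cfg: ForestConfig, importance: ImportanceResult,
               k: int = 8, groups=None, K: int = 5, seed: int = 0) -> pd.DataFrame:
    """Side-by-side metrics of the full-feature and Top-k forests."""
    Xm, names = _as_matrix(X)
    if not (1 <= k <= len(names)):
        raise ValueError(f"k must be in 1..{len(names)}")
    top = set(importance.ranking()[:k])
    top = [f for f in names if f in top]   # canonical column order
    rows = []
    for label, feats in (("full", names), (f"top{k}", top)):
        cols = [names.index(f) for f in feats]
        fr = train_forest(Xm[:, cols], y, cfg, feature_names=feats)
        row = {"model": label, "n_features": len(feats)}
        row.update({f"oob_{k_}": v for k_, v in evaluate(fr, scheme="oob").items()})
        if groups is not None:
            cv = evaluate(fr, Xm[:, cols], y, scheme="group_cv", groups=groups,
                          K=K, seed=seed)
            row.update({f"cv_{k_}": v for k_, v in cv.items() if k_ != "per_fold"})
        rows.append(row)
    return pd.DataFrame(rows)
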