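"""Boosted regression trees for hourly air-quality modelling.

The ensemble is the classic gradient-boosting machine for squared error:
shallow regression trees grown on the current residuals, each scaled by a
learning rate (shrinkage) lambda and added to the model,

    f(x) = sum_{b=1..n_trees} lambda * f_b(x),

with the residuals updated after every tree, r_i <- r_i - lambda * f_b(x_i).
The ensemble starts from zero (no intercept); the shrunken trees absorb the
response mean within a few iterations, which keeps the residual identity
r_i = y_i - f(x_i) exact by construction.

Each tree is grown greedily: every split is the (predictor j, cutpoint s)
pair that maximally reduces the residual sum of squares

    RSS(j, s) = sum_{x_i in R1} (r_i - rbar_R1)^2 + sum_{x_i in R2} (r_i - rbar_R2)^2

over the regions R1 = {x_j < s}, R2 = {x_j >= s}; candidate cutpoints are
the midpoints between consecutive distinct sorted predictor values. A tree
stops after ``interaction_depth`` splits (gbm's interaction depth counts
splits, so a depth-6 tree has at most 7 leaves); splits are allocated
best-first across the current leaves. Ties are broken deterministically:
lowest RSS, then lowest predictor index, then lowest cutpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from ._predict import ensemble_predict


@dataclass(frozen=True)
class SplitCandidate:
    """Best binary split of one continuous predictor against a response."""

    cutpoint: float
    rss: float
    left_mean: float
    right_mean: float
    feature: int = 0


@dataclass
class ModelMetrics:
    """Hold-out performance: Pearson's r, RMSE and mean bias (pred - obs)."""

    pearson_r: float
    rmse: float
    mean_bias: float
    n_test: int


def _exact_split(x, r, s):
    """RSS and region means of the split {x < s} | {x >= s}.

    Computed with the direct two-region formula in original row order; this
    is the definitive value, bitwise comparable with an exhaustive scan.
    """
    mask = x < s
    rl = r[mask]
    rr = r[~mask]
    left_mean = rl.mean()
    right_mean = rr.mean()
    rss = float(np.sum((rl - left_mean) ** 2) + np.sum((rr - right_mean) ** 2))
    return rss, float(left_mean), float(right_mean)


def best_split(x, r):
    """Best RSS-minimising cutpoint of a single continuous predictor.

    Candidate cutpoints are midpoints between consecutive distinct sorted
    values of ``x``. Returns ``None`` when all ``x`` are identical (no valid
    split; callers treat the node as a leaf). On RSS ties the smallest
    cutpoint wins.
    """
    x = np.asarray(x, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if x.shape != r.shape or x.ndim != 1:
        raise ValueError("x and r must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations to split")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    rs = r[order]
    boundaries = np.nonzero(xs[1:] > xs[:-1])[0]  # split after position k
    if boundaries.size == 0:
        return None

    cs = np.cumsum(rs)
    cs2 = np.cumsum(rs * rs)
    total = cs[-1]
    total2 = cs2[-1]
    nl = boundaries + 1.0
    nr = n - nl
    sl = cs[boundaries]
    sl2 = cs2[boundaries]
    rss_approx = (sl2 - sl * sl / nl) + ((total2 - sl2) - (total - sl) ** 2 / nr)

    # The cumulative-sum scan can lose precision by cancellation; shortlist
    # near-minimal candidates and settle them with the exact formula.
    tol = max(1e-9 * (abs(total2) + 1.0), 1e-12)
    shortlist = np.nonzero(rss_approx <= rss_approx.min() + tol)[0]
    if shortlist.size > 256:
        shortlist = shortlist[np.argsort(rss_approx[shortlist], kind="stable")[:256]]
        shortlist.sort()

    best = None
    for k in shortlist:
        b = boundaries[k]
        s = 0.5 * (xs[b] + xs[b + 1])
        rss, lm, rm = _exact_split(x, r, s)
        if best is None or rss < best.rss or (rss == best.rss and s < best.cutpoint):
            best = SplitCandidate(cutpoint=float(s), rss=rss,
                                  left_mean=lm, right_mean=rm)
    return best


def _best_split_frame(X, r, row_idx):
    """Best split over all predictor columns of X restricted to row_idx."""
    best = None
    rr = r[row_idx]
    for j in range(X.shape[1]):
        cand = best_split(X[row_idx, j], rr)
        if cand is None:
            continue
        cand = SplitCandidate(cutpoint=cand.cutpoint, rss=cand.rss,
                              left_mean=cand.left_mean,
                              right_mean=cand.right_mean, feature=j)
        if (best is None or cand.rss < best.rss
                or (cand.rss == best.rss and cand.feature < best.feature)
                or (cand.rss == best.rss and cand.feature == best.feature
                    and cand.cutpoint < best.cutpoint)):
            best = cand
    return best


@dataclass
class RegressionTree:
    """Flattened depth-limited regression tree (node-parallel arrays)."""

    feature: np.ndarray   # int32, -1 for leaves
    threshold: np.ndarray
    left: np.ndarray      # int32 child indices
    right: np.ndarray
    value: np.ndarray     # leaf/region mean response
    n_splits: int

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        return ensemble_predict(X, self.feature[None, :], self.threshold[None, :],
                                self.left[None, :], self.right[None, :],
                                self.value[None, :], 1.0)


def fit_tree(X, residuals, n_splits):
    """Grow a regression tree with at most ``n_splits`` RSS-optimal splits.

    Splits are taken best-first: at each step the (leaf, predictor, cutpoint)
    with the largest RSS reduction over the whole frontier is realised.
    Growth stops early at nodes of size < 2, when no predictor admits a valid
    split, or when no split reduces the RSS (constant response).
    """
    X = np.asarray(X, dtype=np.float64)
    residuals = np.asarray(residuals, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training frame must be a non-empty 2-D array")
    if n_splits < 1:
        raise ValueError("interaction depth must be >= 1")

    feature = [-1]
    threshold = [0.0]
    left = [-1]
    right = [-1]
    value = [float(residuals.mean())]

    def node_rss(rows):
        rr = residuals[rows]
        return float(np.sum((rr - rr.mean()) ** 2))

    root_rows = np.arange(X.shape[0])
    frontier = {0: (root_rows,
                    _best_split_frame(X, residuals, root_rows) if root_rows.size >= 2 else None,
                    node_rss(root_rows))}
    splits_done = 0
    while splits_done < n_splits:
        best_node, best_gain = None, 0.0
        for node_id in sorted(frontier):
            rows, cand, rss0 = frontier[node_id]
            if cand is None:
                continue
            gain = rss0 - cand.rss
            if gain > best_gain:
                best_node, best_gain = node_id, gain
        if best_node is None:
            break
        rows, cand, _ = frontier.pop(best_node)
        mask = X[rows, cand.feature] < cand.cutpoint
        left_rows = rows[mask]
        right_rows = rows[~mask]

        feature[best_node] = cand.feature
        threshold[best_node] = cand.cutpoint
        for child_rows, child_mean, side in ((left_rows, cand.left_mean, "L"),
                                             (right_rows, cand.right_mean, "R")):
            child_id = len(feature)
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            value.append(float(child_mean))
            if side == "L":
                left[best_node] = child_id
            else:
                right[best_node] = child_id
            if child_rows.size >= 2:
                child_cand = _best_split_frame(X, residuals, child_rows)
                frontier[child_id] = (child_rows, child_cand, node_rss(child_rows))
        splits_done += 1

    return RegressionTree(feature=np.asarray(feature, dtype=np.int32),
                          threshold=np.asarray(threshold, dtype=np.float64),
                          left=np.asarray(left, dtype=np.int32),
                          right=np.asarray(right, dtype=np.int32),
                          value=np.asarray(value, dtype=np.float64),
                          n_splits=splits_done)


class BoostedTreeRegressor(BaseEstimator, RegressorMixin):
    """Least-squares gradient boosting with depth-limited regression trees.

    Parameters
    ----------
    n_estimators : int, default 1000
        Number of trees in the additive ensemble.
    learning_rate : float, default 0.1
        Shrinkage lambda applied to every tree, 0 < lambda <= 1.
    interaction_depth : int, default 6
        Number of splits per tree (controls the order of predictor
        interactions a single tree can represent).
    bag_fraction : float, default 1.0
        Fraction of rows subsampled (without replacement) to grow each tree.
        1.0 means fully deterministic boosting; the residual update always
        runs over all rows.
    random_state : int or None
        Seed for the bagging subsample. Unused when ``bag_fraction == 1``.

    Attributes
    ----------
    trees_ : list of RegressionTree
    feature_names_in_ : ndarray of str, when fitted from a DataFrame
    residuals_ : ndarray, final training residuals (y - prediction)
    train_rss_path_ : ndarray, training RSS after each boosting iteration
    """

    def __init__(self, n_estimators=1000, learning_rate=0.1,
                 interaction_depth=6, bag_fraction=1.0, random_state=None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.interaction_depth = interaction_depth
        self.bag_fraction = bag_fraction
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _validate_params_(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.interaction_depth < 1:
            raise ValueError("interaction_depth must be >= 1")
        if not 0.0 < self.bag_fraction <= 1.0:
            raise ValueError("bag_fraction must be in (0, 1]")

    def _coerce_X(self, X, fitting):
        if isinstance(X, pd.DataFrame):
            if fitting:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            else:
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise KeyError(f"missing predictor column(s): {missing}")
                X = X[list(self.feature_names_in_)]
            return np.ascontiguousarray(X.to_numpy(dtype=np.float64))
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        if not fitting and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} predictors, got {X.shape[1]}")
        return X

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        self._validate_params_()
        y = np.asarray(y, dtype=np.float64)
        if not np.isfinite(y).all():
            raise ValueError("response contains non-finite values")
        if not isinstance(X, pd.DataFrame):
            self.feature_names_in_ = None
        Xv = self._coerce_X(X, fitting=True)
        if not np.isfinite(Xv).all():
            raise ValueError("predictors contain non-finite values; drop or "
                             "impute missing rows before fitting")
        n = Xv.shape[0]
        if n < 2:
            raise ValueError("need at least two training rows")
        if Xv.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = Xv.shape[1]

        rng = np.random.default_rng(self.random_state)
        residuals = y.copy()
        trees = []
        rss_path = np.empty(self.n_estimators)
        for b in range(self.n_estimators):
            if self.bag_fraction < 1.0:
                m = max(2, int(np.floor(self.bag_fraction * n)))
                rows = rng.choice(n, size=m, replace=False)
                tree = fit_tree(Xv[rows], residuals[rows], self.interaction_depth)
            else:
                tree = fit_tree(Xv, residuals, self.interaction_depth)
            residuals -= self.learning_rate * tree.predict(Xv)
            rss_path[b] = np.sum(residuals ** 2)
            trees.append(tree)

        self.trees_ = trees
        self.residuals_ = residuals
        self.train_rss_path_ = rss_path
        self._stack_trees()
        return self

    def _stack_trees(self):
        width = max(t.feature.size for t in self.trees_)
        B = len(self.trees_)
        self._feat = np.full((B, width), -1, dtype=np.int32)
        self._thr = np.zeros((B, width), dtype=np.float64)
        self._left = np.zeros((B, width), dtype=np.int32)
        self._right = np.zeros((B, width), dtype=np.int32)
        self._val = np.zeros((B, width), dtype=np.float64)
        for b, t in enumerate(self.trees_):
            k = t.feature.size
            self._feat[b, :k] = t.feature
            self._thr[b, :k] = t.threshold
            self._left[b, :k] = t.left
            self._right[b, :k] = t.right
            self._val[b, :k] = t.value

    def predict(self, X):
        if not hasattr(self, "trees_") or not self.trees_:
            Xv = np.asarray(X, dtype=np.float64)
            return np.zeros(Xv.shape[0])  # empty ensemble: the empty sum
        Xv = self._coerce_X(X, fitting=False)
        if not np.isfinite(Xv).all():
            raise ValueError("prediction rows contain missing/non-finite "
                             "predictor values")
        return ensemble_predict(Xv, self._feat, self._thr, self._left,
                                self._right, self._val, self.learning_rate)

    def staged_predict(self, X):
        """Yield cumulative predictions after each boosting iteration."""
        Xv = self._coerce_X(X, fitting=False)
        acc = np.zeros(Xv.shape[0])
        for tree in self.trees_:
            acc = acc + self.learning_rate * tree.predict(Xv)
            yield acc

    # -- serialisation ---------------------------------------------------
    def to_json(self):
        payload = {
            "params": self.get_params(),
            "feature_names": (None if self.feature_names_in_ is None
                              else list(self.feature_names_in_)),
            "n_features": int(self.n_features_in_),
            "trees": [{
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "value": t.value.tolist(),
                "n_splits": int(t.n_splits),
            } for t in self.trees_],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text):
        payload = json.loads(text)
        model = cls(**payload["params"])
        model.n_features_in_ = payload["n_features"]
        model.feature_names_in_ = (None if payload["feature_names"] is None
                                   else np.asarray(payload["feature_names"],
                                                   dtype=object))
        model.trees_ = [RegressionTree(
            feature=np.asarray(t["feature"], dtype=np.int32),
            threshold=np.asarray(t["threshold"], dtype=np.float64),
            left=np.asarray(t["left"], dtype=np.int32),
            right=np.asarray(t["right"], dtype=np.int32),
            value=np.asarray(t["value"], dtype=np.float64),
            n_splits=t["n_splits"]) for t in payload["trees"]]
        model._stack_trees()
        return model

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_json(fh.read())


def split_train_test(frame, train_fraction=0.8, seed=0):
    """Uniform random row partition into train/test without replacement.

    The train part has ``floor(train_fraction * n)`` rows, matching the
    80/20 protocol used for model assessment.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(frame)
    if n < 2:
        raise ValueError("need at least two rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    if isinstance(frame, (pd.DataFrame, pd.Series)):
        return frame.iloc[train_idx], frame.iloc[test_idx]
    frame = np.asarray(frame)
    return frame[train_idx], frame[test_idx]


def evaluate(model, X_test, y_test):
    """Hold-out metrics: Pearson's r, RMSE, mean bias (predicted - observed).

    With zero variance in either vector, r is reported as NaN (undefined)
    while RMSE and MB are still computed.
    """
    y_test = np.asarray(y_test, dtype=np.float64)
    if y_test.size == 0:
        raise ValueError("empty test set")
    pred = model.predict(X_test)
    diff = pred - y_test
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    mb = float(np.mean(diff))
    if np.std(pred) == 0.0 or np.std(y_test) == 0.0:
        r = float("nan")
    else:
        r = float(np.corrcoef(pred, y_test)[0, 1])
    return ModelMetrics(pearson_r=r, rmse=rmse, mean_bias=mb,
                        n_test=int(y_test.size))
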