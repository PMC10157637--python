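"""Random-forest variable importance for Up-autoantibody ranking.

The two classic importance measures are computed exactly as defined for
bagged classification forests:

* Mean Decrease Accuracy (MDA): for each tree, out-of-bag (OOB) accuracy
  minus OOB accuracy after permuting one feature within the OOB rows,
  averaged over trees. Unscaled (not divided by its standard error).
* Mean Decrease Gini (MDG): the total Gini impurity decrease contributed
  by splits on the feature, averaged over trees.

Trees are CART classifiers with per-node random feature subsampling
(mtry = floor(sqrt(p)) by default) grown on bootstrap samples; the forest
bookkeeping — bootstraps, OOB sets, permutations, aggregation — lives
here, the node-splitting is delegated to scikit-learn's tree learner.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier

from .io import ValidationError


class ForestImportanceRanker(BaseEstimator):
    """Bagged-forest feature importance (scikit-learn style estimator).

    Parameters
    ----------
    n_trees : number of bootstrap trees (default 500).
    mtry : features tried per split; ``None`` means floor(sqrt(p)).
    random_state : seed driving bootstraps, per-tree learners and
        permutations; a fixed seed makes the output bit-identical.

    Fitted attributes: ``importances_`` (DataFrame with mda, mdg,
    rank_mda, rank_mdg per feature, sorted by MDA), ``oob_score_``.
    """

    def __init__(
        self,
        n_trees: int = 500,
        mtry: int | None = None,
        random_state: int | None = 0,
    ):
        self.n_trees = n_trees
        self.mtry = mtry
        self.random_state = random_state

    def fit(self, X, y):
        feature_names = (
            list(X.columns)
            if isinstance(X, pd.DataFrame)
            else [f"feature_{i}" for i in range(np.shape(X)[1])]
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValidationError("need at least two classes for ranking")
        if np.min(np.bincount(y_enc)) < 2:
            raise ValidationError("need at least 2 samples per class")
        mtry = self.mtry or max(1, int(np.floor(np.sqrt(p))))
        rng = np.random.default_rng(self.random_state)

        mda_sum = np.zeros(p)
        mdg_sum = np.zeros(p)
        n_oob_trees = 0
        oob_votes = np.zeros((n, classes.size))
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeClassifier(
                max_features=mtry,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[boot], y_enc[boot])
            mdg_sum += tree.tree_.compute_feature_importances(normalize=False)
            if oob.size == 0:
                continue
            n_oob_trees += 1
            # One batched predict: the intact OOB block followed by p
            # blocks with one column permuted each.
            X_oob = X[oob]
            blocks = [X_oob]
            for j in range(p):
                perm = rng.permutation(oob.size)
                Xp = X_oob.copy()
                Xp[:, j] = X_oob[perm, j]
                blocks.append(Xp)
            pred = tree.predict(np.vstack(blocks)).reshape(p + 1, oob.size)
            acc0 = np.mean(pred[0] == y_enc[oob])
            oob_votes[oob, :] += np.eye(classes.size)[pred[0]]
            mda_sum += acc0 - np.mean(pred[1:] == y_enc[oob], axis=1)

        mda = mda_sum / max(n_oob_trees, 1)
        mdg = mdg_sum / self.n_trees
        order_mda = np.argsort(-mda, kind="stable")
        order_mdg = np.argsort(-mdg, kind="stable")
        rank_mda = np.empty(p, dtype=int)
        rank_mdg = np.empty(p, dtype=int)
        rank_mda[order_mda] = np.arange(1, p + 1)
        rank_mdg[order_mdg] = np.arange(1, p + 1)

        table = pd.DataFrame(
            {
                "feature": feature_names,
                "mda": mda,
                "mdg": mdg,
                "rank_mda": rank_mda,
                "rank_mdg": rank_mdg,
            }
        ).sort_values("rank_mda", kind="mergesort", ignore_index=True)

        voted = oob_votes.sum(axis=1) > 0
        oob_pred = oob_votes.argmax(axis=1)
        self.oob_score_ = (
            float(np.mean(oob_pred[voted] == y_enc[voted])) if voted.any() else np.nan
        )
        self.importances_ = table
        self.classes_ = classes
        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(feature_names)
        return self


def rf_importance(
    feature_matrix,
    labels,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Importance table (feature, mda, mdg, rank_mda, rank_mdg), MDA-sorted."""
    ranker = ForestImportanceRanker(n_trees=n_trees, mtry=mtry, random_state=seed)
    return ranker.fit(feature_matrix, labels).importances_
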