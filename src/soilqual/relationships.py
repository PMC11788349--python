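"""Yield-driver analysis: simple linear regressions and random-forest
permutation importance.

``linear_fit`` is ordinary least squares of one response on one
predictor, the model used for the SQI-EMF-yield relationship panel.

``rf_importance`` mirrors the importance measure popularized by the R
``randomForest`` package: a regression forest is grown on bootstrap
samples, and each feature's importance is the mean over trees of the
relative increase in out-of-bag (OOB) mean squared error after randomly
permuting that feature among the tree's OOB cases (reported in percent,
%IncMSE).

Randomization scheme (documented so column-order invariance is
testable): features are canonicalized by sorted name before any random
draw; the bootstrap/tree stream is seeded from the run seed alone, and
each feature's permutation stream is seeded from the run seed combined
with a hash of the feature name.  Importance therefore depends on the
seed and the feature *names*, never on the column order supplied.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

__all__ = ["RegressionFit", "ImportanceTable", "linear_fit", "rf_importance"]


@dataclass
class RegressionFit:
    """Simple OLS fit ``response = intercept + slope * predictor``."""

    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


def linear_fit(x, y, predictor: str = "x", response: str = "y") -> RegressionFit:
    """Ordinary least squares of ``y`` on ``x``.

    ``p_slope`` is the two-sided t test of slope = 0 with n - 2 df;
    ``r_squared`` is the squared Pearson correlation.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("linear fit needs at least 3 observations")
    if np.all(xv == xv[0]):
        raise ValueError(f"predictor {predictor!r} is constant; slope undefined")
    res = stats.linregress(xv, yv)
    return RegressionFit(
        predictor=predictor,
        response=response,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        n=int(xv.size),
    )


@dataclass
class ImportanceTable:
    """Permutation importances (%IncMSE) with the forest settings used."""

    importance: pd.Series  # feature -> %IncMSE, in the input column order
    n_trees: int
    seed: int
    max_features: int
    n_oob_trees: int

    def ranking(self) -> pd.Series:
        """Features sorted by decreasing importance."""
        return self.importance.sort_values(ascending=False)


def _feature_seed(seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rf_importance(
    features: pd.DataFrame,
    target,
    n_trees: int = 500,
    seed: int = 0,
    max_features: int | None = None,
) -> ImportanceTable:
    """Out-of-bag permutation importance of a regression forest.

    Parameters
    ----------
    features
        Plots x properties table of candidate predictors.
    target
        Response vector (e.g. grain yield), one entry per plot.
    n_trees
        Number of bootstrap trees (default 500).
    seed
        Seed for bootstraps, tree randomization and permutations.
    max_features
        Candidate features per split; default ``ceil(p / 3)``, the
        regression-forest convention.

    Returns
    -------
    ImportanceTable
        Per-feature mean over trees of
        ``100 * (OOB MSE permuted - OOB MSE) / OOB MSE``.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y = np.asarray(target, dtype=float)
    n, p = features.shape
    if p < 2:
        raise ValueError("importance needs at least 2 features")
    if y.size != n:
        raise ValueError("target length must match the feature table")
    if n < 5:
        warnings.warn(
            f"only {n} observations: OOB importance will be extremely noisy",
            stacklevel=2,
        )
    input_order = list(features.columns)
    names = sorted(input_order)
    X = features[names].to_numpy(dtype=float)
    mtry = max_features if max_features is not None else math.ceil(p / 3)
    mtry = min(max(1, mtry), p)

    rng = np.random.default_rng(seed)
    perm_rngs = {name: np.random.default_rng(_feature_seed(seed, name)) for name in names}
    raw = np.zeros(p)
    n_oob_trees = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        if oob.size == 0:
            # keep permutation streams aligned across trees
            for name in names:
                perm_rngs[name].permutation(1)
            continue
        tree = DecisionTreeRegressor(max_features=mtry, random_state=tree_seed)
        tree.fit(X[boot], y[boot])
        pred = tree.predict(X[oob])
        err = float(np.mean((y[oob] - pred) ** 2))
        for j, name in enumerate(names):
            order = perm_rngs[name].permutation(oob.size)
            Xp = X[oob].copy()
            Xp[:, j] = Xp[order, j]
            err_p = float(np.mean((y[oob] - tree.predict(Xp)) ** 2))
            if err > 0:
                raw[j] += (err_p - err) / err
            # err == 0: tree fits OOB cases perfectly; no relative scale,
            # contribute 0 rather than an infinite ratio
        n_oob_trees += 1
    if n_oob_trees == 0:
        raise ValueError("no tree had out-of-bag samples; increase n or n_trees")
    imp_sorted = pd.Series(100.0 * raw / n_oob_trees, index=names)
    return ImportanceTable(
        importance=imp_sorted.reindex(input_order),
        n_trees=n_trees,
        seed=seed,
        max_features=mtry,
        n_oob_trees=n_oob_trees,
    )
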