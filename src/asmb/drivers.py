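"""Deterministic vs stochastic drivers of beta-diversity.

Variation partitioning decomposes the variance of a vectorized
beta-diversity matrix into the unique environmental fraction (a), the shared
fraction (b), the unique spatial fraction (c) and the residual (d) by
multiple regression on distance matrices. The deterministic percentage is
the unique environmental share of the two unique fractions, 100*a/(a+c),
and the stochastic percentage its spatial complement.

Random-forest importance ranks the spatial distance and the six per-group
environmental distances by the mean percentage increase in out-of-bag MSE
when each predictor is permuted — the classic %IncMSE of regression forests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from ._matrix import PairwiseMatrix, check_same_labels

logger = logging.getLogger(__name__)


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of an OLS fit with intercept."""
    Xd = np.column_stack([np.ones(y.size), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("response has zero variance over pairs")
    return 1.0 - float(np.sum(resid**2) / ss_tot)


def _adjust(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment, 1 - (1-R^2)(n-1)/(n-p-1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass(frozen=True)
class VarpartFractions:
    """Four-fraction decomposition of beta-diversity variance.

    ``env_unique + shared + spatial_unique + residual == 1`` exactly (the raw
    decomposition identity; the shared fraction may be negative). Percentages
    are computed from the unique fractions floored at zero.
    """

    env_unique: float       # a
    shared: float           # b
    spatial_unique: float   # c
    residual: float         # d
    r2_full: float
    r2_env: float
    r2_spatial: float
    r2_full_adj: float
    r2_env_adj: float
    r2_spatial_adj: float
    deterministic_pct: float
    stochastic_pct: float
    collinear: bool
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def variation_partition(
    beta: PairwiseMatrix,
    env_dist: PairwiseMatrix,
    spatial_dist: PairwiseMatrix,
) -> VarpartFractions:
    """Partition beta-diversity into environmental vs spatial components.

    Over vectorized upper triangles: ``r2_full = R^2(beta ~ env + spa)``,
    ``a = r2_full - R^2(beta ~ spa)``, ``c = r2_full - R^2(beta ~ env)``,
    ``b = r2_full - a - c``, ``d = 1 - r2_full``.
    """
    if beta.role not in ("dissimilarity", "distance"):
        raise ValueError("beta must be supplied as a dissimilarity")
    check_same_labels(beta, env_dist, spatial_dist)
    y = beta.condensed()
    env = env_dist.condensed()
    spa = spatial_dist.condensed()
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 pairs")

    r2_full = _r2(y, np.column_stack([env, spa]))
    r2_env = _r2(y, env[:, None])
    r2_spa = _r2(y, spa[:, None])

    corr = np.corrcoef(env, spa)[0, 1]
    collinear = bool(abs(corr) > 1 - 1e-10)
    if collinear:
        logger.warning(
            "environmental and spatial distances are collinear to machine "
            "precision; the shared fraction is unstable"
        )

    a = r2_full - r2_spa
    c = r2_full - r2_env
    b = r2_full - a - c
    d = 1.0 - r2_full

    a_f, c_f = max(a, 0.0), max(c, 0.0)
    if (a < 0) or (c < 0):
        logger.info("negative unique fraction floored at 0 for percentages (a=%g, c=%g)", a, c)
    if a_f + c_f > 0:
        det = 100.0 * a_f / (a_f + c_f)
        sto = 100.0 * c_f / (a_f + c_f)
    else:
        det = sto = float("nan")

    return VarpartFractions(
        env_unique=float(a),
        shared=float(b),
        spatial_unique=float(c),
        residual=float(d),
        r2_full=float(r2_full),
        r2_env=float(r2_env),
        r2_spatial=float(r2_spa),
        r2_full_adj=float(_adjust(r2_full, n, 2)),
        r2_env_adj=float(_adjust(r2_env, n, 1)),
        r2_spatial_adj=float(_adjust(r2_spa, n, 1)),
        deterministic_pct=float(det),
        stochastic_pct=float(sto),
        collinear=collinear,
        n_pairs=n,
    )


def rf_importance(
    beta: PairwiseMatrix,
    predictors: dict[str, PairwiseMatrix],
    n_trees: int = 500,
    seed: int | None = None,
) -> pd.DataFrame:
    """Out-of-bag permutation importance (%IncMSE) of distance predictors.

    A regression forest is fit to the vectorized beta-diversity with one
    column per predictor distance matrix. For every tree, the MSE on its
    out-of-bag pairs is compared with the MSE after permuting one predictor
    column; the importance is the mean percentage increase across trees.
    Returns a DataFrame (predictor, importance_pct_inc_mse, rank), rank 1 =
    most important. Deterministic given ``seed``.
    """
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    names = list(predictors)
    check_same_labels(beta, *predictors.values())
    y = beta.condensed()
    X = np.column_stack([predictors[k].condensed() for k in names])
    if y.size < 10:
        raise ValueError("too few pairs to grow a forest")

    rng = np.random.default_rng(seed)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1.0 / 3.0,
        min_samples_leaf=5,
        bootstrap=True,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(X, y)

    inc = np.zeros((n_trees, len(names)))
    valid = np.zeros(n_trees, dtype=bool)
    n_rows = y.size
    for t, (tree, sample_idx) in enumerate(zip(forest.estimators_, forest.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n_rows), sample_idx, assume_unique=False)
        if oob.size < 2:
            continue
        X_oob = X[oob]
        y_oob = y[oob]
        base = np.mean((tree.predict(X_oob) - y_oob) ** 2)
        if base == 0:
            continue
        valid[t] = True
        for j in range(len(names)):
            Xp = X_oob.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            mse = np.mean((tree.predict(Xp) - y_oob) ** 2)
            inc[t, j] = 100.0 * (mse - base) / base
    if not valid.any():
        raise ValueError("no usable out-of-bag samples; increase pair count")
    importance = inc[valid].mean(axis=0)
    order = np.argsort(-importance, kind="stable")
    rank = np.empty(len(names), dtype=int)
    rank[order] = np.arange(1, len(names) + 1)
    return pd.DataFrame(
        {"predictor": names, "importance_pct_inc_mse": importance, "rank": rank}
    ).sort_values("rank", ignore_index=True)
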