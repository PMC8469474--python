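"""Distance-decay relationships: spatial and composite environmental
distances, OLS decay fits with Mantel significance, and slope comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import mantel as _skbio_mantel

from ._matrix import PairwiseMatrix, check_same_labels
from .io import ENV_GROUPS, SampleMetadata

EARTH_RADIUS_KM = 6371.0088


def spatial_distance(metadata: SampleMetadata) -> PairwiseMatrix:
    """Great-circle (haversine) distance in km between sample coordinates."""
    lat = np.radians(metadata.data["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata.data["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(d, metadata.sample_ids, "spatial_km")


def group_composites(metadata: SampleMetadata, groups=None) -> pd.DataFrame:
    """One composite column per environment group: the mean of the group's
    z-scored variables. Constant variables are dropped with a warning."""
    if groups is None or groups == "all":
        groups = [g for g in ENV_GROUPS if g in metadata.groups_present()]
    groups = list(groups)
    unknown = set(groups) - set(ENV_GROUPS)
    if unknown:
        raise ValueError(f"unknown environment groups: {sorted(unknown)}")
    df = metadata.data
    out = {}
    for g in groups:
        cols = metadata.variables_in_group(g)
        if not cols:
            raise ValueError(f"no variables mapped to group {g!r}")
        keep = []
        for c in cols:
            sd = df[c].std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                warnings.warn(f"dropping constant environmental variable {c!r}")
                continue
            keep.append((df[c] - df[c].mean()) / sd)
        if not keep:
            raise ValueError(f"all variables in group {g!r} are constant")
        out[g] = pd.concat(keep, axis=1).mean(axis=1)
    return pd.DataFrame(out, index=df.index)


def environmental_distance(metadata: SampleMetadata, groups=None) -> PairwiseMatrix:
    """Euclidean distance over the normalized group composites.

    ``groups`` defaults to all groups present; a single-group list gives the
    per-driver distances used by the importance analysis.
    """
    comp = group_composites(metadata, groups)
    d = squareform(pdist(comp.to_numpy(), metric="euclidean"))
    return PairwiseMatrix(d, metadata.sample_ids, "env_distance")


def mantel_test(
    m1: PairwiseMatrix, m2: PairwiseMatrix, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Two-sided Mantel test: Pearson r of the upper triangles, significance
    by simultaneous row/column permutation; p = (1 + #more extreme)/(1 + n_perm)."""
    check_same_labels(m1, m2)
    r, p, _ = _skbio_mantel(
        m1.to_skbio(), m2.to_skbio(), method="pearson",
        permutations=n_perm, alternative="two-sided", seed=seed,
    )
    return float(r), float(p)


@dataclass(frozen=True)
class DdrFit:
    """OLS distance-decay fit of pairwise similarity on pairwise distance."""

    slope: float
    intercept: float
    pearson_r: float
    mantel_r: float
    mantel_p: float
    n_pairs: int
    standardized: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _standardize_pairs(vec: np.ndarray) -> np.ndarray:
    sd = vec.std(ddof=1)
    if sd == 0:
        raise ValueError("distance is constant over pairs")
    return (vec - vec.mean()) / sd


def fit_distance_decay(
    similarity: PairwiseMatrix,
    distance: PairwiseMatrix,
    standardize: bool = True,
    n_perm: int = 999,
    seed: int | None = None,
) -> DdrFit:
    """Distance-decay regression: similarity ~ distance over sample pairs.

    Distances are standardized to zero mean / unit sd over pairs by default so
    slopes are comparable between spatial and environmental axes. Mantel r/p
    quantify significance with the pair non-independence respected.
    """
    if similarity.role == "dissimilarity":
        similarity = similarity.to_similarity()
    if similarity.role != "similarity":
        raise ValueError("first argument must be a similarity (or dissimilarity) matrix")
    check_same_labels(similarity, distance)
    if len(similarity) < 3:
        raise ValueError("need at least 3 samples (3 pairs)")
    y = similarity.condensed()
    x = distance.condensed()
    if standardize:
        x = _standardize_pairs(x)
    slope, intercept = np.polyfit(x, y, 1)
    sy = y.std(ddof=1)
    pearson_r = float(np.corrcoef(x, y)[0, 1]) if sy > 0 else 0.0
    diss = similarity.to_dissimilarity()
    r, p = mantel_test(diss, distance, n_perm=n_perm, seed=seed)
    # mantel was run on dissimilarity; similarity flips the sign of r
    return DdrFit(
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=pearson_r,
        mantel_r=-r,
        mantel_p=p,
        n_pairs=y.size,
        standardized=standardize,
    )


@dataclass(frozen=True)
class SlopeComparison:
    """Between-group contrast of distance-decay slopes."""

    slope_a: float
    slope_b: float
    interaction: float      # slope_b - slope_a in the pooled model
    p_permutation: float    # sample-level label permutation, two-sided
    p_classical: float      # OLS Wald p, ignores pair non-independence
    n_perm: int
    groups: tuple[str, str]


def compare_slopes(
    similarity: PairwiseMatrix,
    distance: PairwiseMatrix,
    grouping: dict[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
    standardize: bool = True,
) -> SlopeComparison:
    """Test whether two sample groups decay at different rates.

    Pools the within-group (similarity, distance) pairs into one model
    ``similarity ~ distance * group`` and compares the observed interaction
    coefficient with a null built by permuting group labels at the level of
    whole samples — not pairs — since pairwise similarities sharing a sample
    are not independent. The classical OLS Wald p is reported for reference.
    """
    if similarity.role == "dissimilarity":
        similarity = similarity.to_similarity()
    check_same_labels(similarity, distance)
    grouping = pd.Series(grouping)
    labels = similarity.labels
    missing = set(labels) - set(grouping.index)
    if missing:
        raise KeyError(f"samples without group labels: {sorted(missing)}")
    gvals = grouping.loc[labels]
    names = sorted(gvals.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    member = (gvals == names[1]).to_numpy().astype(int)
    if min((member == 0).sum(), (member == 1).sum()) < 3:
        raise ValueError("each group needs at least 3 samples")

    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    y_all = similarity.condensed()
    x_all = distance.condensed()
    if standardize:
        x_all = _standardize_pairs(x_all)

    def interaction_coef(m):
        same = m[iu] == m[ju]
        xi, yi = x_all[same], y_all[same]
        is_b = (m[iu][same] == 1).astype(float)
        X = np.column_stack([np.ones(xi.size), xi, is_b, xi * is_b])
        beta, *_ = np.linalg.lstsq(X, yi, rcond=None)
        return beta

    beta_obs = interaction_coef(member)
    obs = beta_obs[3]

    rng = np.random.default_rng(seed)
    more_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(member)
        if perm[iu].size and min((perm == 0).sum(), (perm == 1).sum()) >= 2:
            b = interaction_coef(perm)[3]
        else:  # pragma: no cover - permutation preserves group sizes
            b = 0.0
        if abs(b) >= abs(obs) - 1e-15:
            more_extreme += 1
    p_perm = (1 + more_extreme) / (1 + n_perm)

    same = member[iu] == member[ju]
    xi, yi = x_all[same], y_all[same]
    is_b = (member[iu][same] == 1).astype(float)
    X = sm.add_constant(np.column_stack([xi, is_b, xi * is_b]))
    ols = sm.OLS(yi, X).fit()
    p_classical = float(ols.pvalues[3])

    return SlopeComparison(
        slope_a=float(beta_obs[1]),
        slope_b=float(beta_obs[1] + beta_obs[3]),
        interaction=float(obs),
        p_permutation=float(p_perm),
        p_classical=p_classical,
        n_perm=n_perm,
        groups=(str(names[0]), str(names[1])),
    )
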