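"""Permutation tests for between-group community differences.

PERMANOVA (Adonis), ANOSIM and PERMDISP are delegated to scikit-bio; MRPP is
implemented here. All four operate directly on a dissimilarity matrix, and
`taxon_abundance_contrast` provides the per-taxon-group paired layer contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import anosim as _sk_anosim
from skbio.stats.distance import permanova as _sk_permanova
from skbio.stats.distance import permdisp as _sk_permdisp

from ._matrix import PairwiseMatrix
from .io import OtuTable, SampleMetadata


@dataclass(frozen=True)
class GroupTestResult:
    test: str          # permanova | anosim | mrpp | permdisp
    statistic: float   # pseudo-F, R, A, or dispersion F
    p: float
    n_perm: int
    seed: int | None
    extras: dict

    def to_frame(self) -> pd.DataFrame:
        row = {k: v for k, v in self.__dict__.items() if k != "extras"}
        row.update(self.extras)
        return pd.DataFrame([row])


def _check_grouping(beta: PairwiseMatrix, grouping) -> pd.Series:
    grouping = pd.Series(grouping)
    missing = set(beta.labels) - set(grouping.index)
    if missing:
        raise KeyError(f"samples without group labels: {sorted(missing)}")
    g = grouping.loc[beta.labels].astype(str)
    counts = g.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError(f"singleton group(s): {list(counts[counts < 2].index)}")
    return g


def permanova(
    beta: PairwiseMatrix, grouping, n_perm: int = 999, seed: int | None = None
) -> GroupTestResult:
    """Permutational multivariate ANOVA (Adonis) on a dissimilarity matrix."""
    g = _check_grouping(beta, grouping)
    res = _sk_permanova(beta.to_skbio(), g.to_numpy(), permutations=n_perm, seed=seed)
    return GroupTestResult(
        "permanova", float(res["test statistic"]), float(res["p-value"]),
        n_perm, seed, {"n_groups": int(g.nunique())},
    )


def anosim(
    beta: PairwiseMatrix, grouping, n_perm: int = 999, seed: int | None = None
) -> GroupTestResult:
    """Analysis of similarities: rank-based between/within contrast R."""
    g = _check_grouping(beta, grouping)
    res = _sk_anosim(beta.to_skbio(), g.to_numpy(), permutations=n_perm, seed=seed)
    return GroupTestResult(
        "anosim", float(res["test statistic"]), float(res["p-value"]),
        n_perm, seed, {"n_groups": int(g.nunique())},
    )


def permdisp(
    beta: PairwiseMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
    measure: str = "centroid",
) -> GroupTestResult:
    """Homogeneity of multivariate dispersions in PCoA space.

    Distances to the group centroid by default (``measure='median'`` for the
    spatial median); F tested by label permutation. Negative eigenvalues are
    handled by scikit-bio's standard correction.
    """
    if measure not in ("centroid", "median"):
        raise ValueError("measure must be 'centroid' or 'median'")
    g = _check_grouping(beta, grouping)
    res = _sk_permdisp(
        beta.to_skbio(), g.to_numpy(), permutations=n_perm, test=measure,
        seed=seed, warn_neg_eigval=False,
    )
    return GroupTestResult(
        "permdisp", float(res["test statistic"]), float(res["p-value"]),
        n_perm, seed, {"measure": measure, "n_groups": int(g.nunique())},
    )


def mrpp(
    beta: PairwiseMatrix, grouping, n_perm: int = 999, seed: int | None = None
) -> GroupTestResult:
    """Multiresponse permutation procedure.

    delta is the group-size-weighted mean within-group dissimilarity;
    chance-corrected effect size A = 1 - delta / mean(delta_perm); p is the
    left-tail permutation probability of delta.
    """
    g = _check_grouping(beta, grouping)
    codes = pd.Categorical(g).codes
    n = len(codes)
    vals = beta.values

    def delta(c):
        tot = 0.0
        for k in np.unique(c):
            idx = np.flatnonzero(c == k)
            sub = vals[np.ix_(idx, idx)]
            iu = np.triu_indices(idx.size, k=1)
            tot += (idx.size / n) * sub[iu].mean()
        return tot

    obs = delta(codes)
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    for i in range(n_perm):
        perm_deltas[i] = delta(rng.permutation(codes))
    p = (1 + np.count_nonzero(perm_deltas <= obs + 1e-15)) / (1 + n_perm)
    expected = perm_deltas.mean()
    a = 1.0 - obs / expected if expected > 0 else float("nan")
    return GroupTestResult(
        "mrpp", float(a), float(p), n_perm, seed,
        {"delta": float(obs), "expected_delta": float(expected)},
    )


def taxon_abundance_contrast(
    table: OtuTable,
    taxon_groups: dict[str, str],
    metadata: SampleMetadata,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-taxon-group relative-abundance contrast between layers.

    For each taxon group, computes the mean per-site difference in summed
    relative abundance (topsoil minus subsoil) and a two-sided paired
    sign-flip permutation p-value. Every site must be present in both layers.
    Returns a DataFrame (taxon_group, delta, p, significant).
    """
    pairing = metadata.site_pairing()
    all_sites = set(metadata.data["site_id"])
    unpaired = all_sites - set(pairing)
    if unpaired:
        raise ValueError(f"sites missing a layer: {sorted(unpaired)[:5]}")
    rel = pd.DataFrame(
        table.relative_abundance(), index=table.sample_ids, columns=table.otu_ids
    )
    unknown = set(taxon_groups) - set(table.otu_ids)
    if unknown:
        raise KeyError(f"taxon map references unknown OTUs: {sorted(unknown)[:5]}")
    groups = sorted(set(taxon_groups.values()))
    rng = np.random.default_rng(seed)
    rows = []
    sites = sorted(pairing)
    top_ids = [pairing[s]["topsoil"] for s in sites]
    sub_ids = [pairing[s]["subsoil"] for s in sites]
    for grp in groups:
        otus = [o for o, g in taxon_groups.items() if g == grp]
        top = rel.loc[top_ids, otus].sum(axis=1).to_numpy()
        sub = rel.loc[sub_ids, otus].sum(axis=1).to_numpy()
        diff = top - sub
        obs = diff.mean()
        if np.allclose(diff, 0):
            rows.append((grp, 0.0, 1.0, False))
            continue
        flips = rng.choice([-1.0, 1.0], size=(n_perm, diff.size))
        perm_means = (flips * diff).mean(axis=1)
        p = (1 + np.count_nonzero(np.abs(perm_means) >= abs(obs) - 1e-15)) / (1 + n_perm)
        rows.append((grp, float(obs), float(p), p < alpha))
    return pd.DataFrame(rows, columns=["taxon_group", "delta", "p", "significant"])
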