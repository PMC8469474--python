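"""Rarefaction, abundant/rare partitioning, and taxonomic/phylogenetic beta-diversity."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity

from ._matrix import PairwiseMatrix
from .io import OtuTable, check_tree_table_ids


def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Uses multivariate hypergeometric draws per sample, the exact
    distribution of rarefaction without replacement.
    """
    depth = int(depth)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    sums = table.sample_sums()
    short = [s for s, t in zip(table.sample_ids, sums) if t < depth]
    if short:
        raise ValueError(f"depth {depth} exceeds total reads of samples: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.shape[0]):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return OtuTable(list(table.sample_ids), list(table.otu_ids), out)


@dataclass(frozen=True)
class AbundancePartition:
    """Disjoint abundant / rare / intermediate OTU id sets.

    Thresholds are relative-abundance fractions: OTUs at >= ``abundant_min``
    (default 0.1%) are abundant, at <= ``rare_max`` (default 0.01%) rare, and
    everything in between intermediate.
    """

    abundant_ids: tuple[str, ...]
    rare_ids: tuple[str, ...]
    intermediate_ids: tuple[str, ...]
    abundant_min: float
    rare_max: float
    mode: str

    def __post_init__(self):
        sets = [set(self.abundant_ids), set(self.rare_ids), set(self.intermediate_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("partition sets overlap")


def partition_by_abundance(
    table: OtuTable,
    abundant_min: float = 0.001,
    rare_max: float = 0.0001,
    mode: str = "pooled",
) -> AbundancePartition:
    """Classify OTUs as abundant / rare / intermediate by relative abundance.

    ``mode='pooled'`` (default) applies the thresholds to each OTU's share of
    the pooled reads across all samples. ``mode='every_sample'`` requires the
    per-sample relative abundance to satisfy the threshold in every sample
    (the literal "in all samples" reading).
    """
    if not abundant_min > rare_max:
        raise ValueError("abundant_min must exceed rare_max")
    if mode == "pooled":
        p = table.otu_sums() / table.counts.sum()
        abundant = p >= abundant_min
        rare = p <= rare_max
    elif mode == "every_sample":
        rel = table.relative_abundance()
        abundant = np.all(rel >= abundant_min, axis=0)
        rare = np.all(rel <= rare_max, axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    inter = ~(abundant | rare)
    ids = np.asarray(table.otu_ids)
    return AbundancePartition(
        tuple(ids[abundant]),
        tuple(ids[rare]),
        tuple(ids[inter]),
        abundant_min,
        rare_max,
        mode,
    )


def bray_curtis(table: OtuTable) -> PairwiseMatrix:
    """Bray-Curtis dissimilarity, sum|x-y| / sum(x+y), over sample pairs.

    Computed on the counts as given (rarefy to equal depth first to keep
    pairs comparable); errors on zero-total samples.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    table.relative_abundance()  # raises on zero-total samples
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return PairwiseMatrix(d, table.sample_ids, "dissimilarity")


def weighted_unifrac(
    table: OtuTable, tree: TreeNode, normalized: bool = True
) -> PairwiseMatrix:
    """Weighted UniFrac between samples: branch lengths weighted by the
    difference in descendant relative abundance; normalized form lies in [0, 1].
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    table.relative_abundance()  # raises on zero-total samples
    check_tree_table_ids(table, tree)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns when tree tips ⊃ table OTUs
        dm = beta_diversity(
            "weighted_unifrac",
            table.counts,
            ids=table.sample_ids,
            taxa=table.otu_ids,
            tree=tree,
            normalized=normalized,
        )
    values = dm.data
    if normalized:
        role = "dissimilarity"
        values = np.clip(values, 0.0, 1.0)
        return PairwiseMatrix(values, table.sample_ids, role)
    # raw weighted UniFrac is unbounded above: a plain distance
    return PairwiseMatrix(values, table.sample_ids, "distance")
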