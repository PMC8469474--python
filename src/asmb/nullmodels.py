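"""Phylogenetic and taxonomic null models for community-assembly inference.

Two standardized scores are computed per sample pair:

* **betaNTI** — the standardized effect size of abundance-weighted betaMNTD
  (between-community mean nearest-taxon distance) against a null built by
  shuffling tip labels across the supplied tree, i.e. randomizing
  phylogenetic relationships while holding abundances and occupancies fixed.
  |betaNTI| > 2 signals selection: variable selection when > 2 (more
  phylogenetic turnover than expected), homogeneous selection when < -2.

* **RC_Bray** — the modified Raup-Crick index on Bray-Curtis. Null community
  pairs preserve each sample's observed richness and read total: OTUs are
  drawn from the regional pool with probability proportional to occupancy
  frequency, then reads are allocated multinomially with probability
  proportional to regional relative abundance. RC is the rank position of
  the observed Bray-Curtis within the null set rescaled to [-1, 1];
  RC > 0.95 signals dispersal limitation, RC < -0.95 homogenizing dispersal.

Pairs with |betaNTI| <= 2 and |RC| <= 0.95 are classed as undominated
(weak selection, weak dispersal, diversification, drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._matrix import PairwiseMatrix
from .io import OtuTable, check_tree_table_ids

BNTI_CUT = 2.0
RC_CUT = 0.95

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "undominated",
)


# ---------------------------------------------------------------------------
# betaMNTD
# ---------------------------------------------------------------------------
def _patristic_matrix(table: OtuTable, tree: TreeNode) -> np.ndarray:
    """Tip-to-tip patristic distances in table OTU order."""
    td = tree.tip_tip_distances()
    idx = [td.ids.index(o) if o in td.ids else None for o in table.otu_ids]
    missing = [o for o, i in zip(table.otu_ids, idx) if i is None]
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing[:5]}")
    sel = np.asarray(idx, dtype=int)
    return td.data[np.ix_(sel, sel)]


def _beta_mntd_condensed(
    freq: np.ndarray,
    presence: np.ndarray,
    dist: np.ndarray,
    exclude_conspecifics: bool,
) -> np.ndarray:
    """betaMNTD for all sample pairs, upper-triangle order.

    freq: samples x OTUs weights (relative abundance, or presence/richness
    for the unweighted variant); presence: boolean samples x OTUs; dist:
    OTU x OTU patristic distances.
    """
    n_samp, n_otu = freq.shape
    big = np.inf
    # nearest[s, i] = min distance from OTU i to any OTU present in sample s
    nearest = np.empty((n_samp, n_otu))
    for s in range(n_samp):
        cols = np.flatnonzero(presence[s])
        if cols.size == 0:
            raise ValueError(f"sample index {s} is empty")
        d = dist[:, cols]
        if exclude_conspecifics:
            d = d.copy()
            # mask the zero self-match of OTU i against itself in the other
            # community so cosmopolitan taxa do not pin betaMNTD at 0
            rows = cols
            d[rows, np.arange(cols.size)] = big
            nearest[s] = d.min(axis=1)
            # a sample with a single OTU matched against itself has no
            # non-self neighbour; fall back to including the self match
            bad = ~np.isfinite(nearest[s])
            if np.any(bad):
                nearest[s, bad] = dist[bad][:, cols].min(axis=1)
        else:
            nearest[s] = d.min(axis=1)
    iu, ju = np.triu_indices(n_samp, k=1)
    # 0.5 * (sum_i f_iA * nearest_B(i) + sum_j f_jB * nearest_A(j))
    out = 0.5 * (
        np.einsum("pk,pk->p", freq[iu], nearest[ju])
        + np.einsum("pk,pk->p", freq[ju], nearest[iu])
    )
    return out


def beta_mntd(
    table: OtuTable,
    tree: TreeNode,
    abundance_weighted: bool = True,
    exclude_conspecifics: bool = False,
) -> PairwiseMatrix:
    """Between-community mean nearest-taxon distance (betaMNTD).

    For samples A, B: the average over taxa in A (weighted by relative
    abundance when ``abundance_weighted``) of the patristic distance to the
    nearest taxon present in B, symmetrized. ``exclude_conspecifics`` removes
    the zero-distance self-match of a taxon present in both communities.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    check_tree_table_ids(table, tree)
    dist = _patristic_matrix(table, tree)
    presence = table.presence()
    if abundance_weighted:
        freq = table.relative_abundance()
    else:
        rich = presence.sum(axis=1)
        if np.any(rich == 0):
            raise ValueError("empty sample")
        freq = presence / rich[:, None]
    vec = _beta_mntd_condensed(freq, presence, dist, exclude_conspecifics)
    return PairwiseMatrix.from_condensed(vec, table.sample_ids, "distance")


# ---------------------------------------------------------------------------
# null model results
# ---------------------------------------------------------------------------
@dataclass
class NullModelResult:
    """Per-pair observed statistic, null summary and standardized score."""

    kind: str  # 'bnti' or 'rc'
    labels: list[str]
    pairs: list[tuple[str, str]]
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    score: np.ndarray
    n_randomizations: int
    seed: int | None
    degenerate: np.ndarray = field(default=None)  # True where null sd == 0

    def __post_init__(self):
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.degenerate is None:
            self.degenerate = np.zeros(len(self.pairs), dtype=bool)

    def score_matrix(self) -> PairwiseMatrix:
        return PairwiseMatrix.from_condensed(
            np.where(self.degenerate, np.nan, self.score), self.labels, self.kind
        ) if self.kind in ("bnti", "rc") else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_a": [a for a, _ in self.pairs],
                "sample_b": [b for _, b in self.pairs],
                "observed": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "score": np.where(self.degenerate, np.nan, self.score),
                "degenerate": self.degenerate,
            }
        )


def bnti(
    table: OtuTable,
    tree: TreeNode,
    n_rand: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = True,
    exclude_conspecifics: bool = False,
) -> NullModelResult:
    """betaNTI: standardized effect size of betaMNTD under tip-label shuffling.

    The null randomizes phylogenetic relationships (a permutation of the
    patristic matrix rows/columns) while preserving every sample's abundances
    and occupancies. Pairs whose null sd is zero are flagged degenerate and
    their score left NaN.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    check_tree_table_ids(table, tree)
    dist = _patristic_matrix(table, tree)
    presence = table.presence()
    if abundance_weighted:
        freq = table.relative_abundance()
    else:
        freq = presence / presence.sum(axis=1)[:, None]
    obs = _beta_mntd_condensed(freq, presence, dist, exclude_conspecifics)

    rng = np.random.default_rng(seed)
    n_otu = table.shape[1]
    nulls = np.empty((n_rand, obs.size))
    for k in range(n_rand):
        perm = rng.permutation(n_otu)
        dperm = dist[np.ix_(perm, perm)]
        nulls[k] = _beta_mntd_condensed(freq, presence, dperm, exclude_conspecifics)
    mu = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (obs - mu) / sd
    score[degenerate] = np.nan
    iu, ju = np.triu_indices(table.shape[0], k=1)
    pairs = [(table.sample_ids[i], table.sample_ids[j]) for i, j in zip(iu, ju)]
    return NullModelResult(
        "bnti", list(table.sample_ids), pairs, obs, mu, sd, score, n_rand, seed, degenerate
    )


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------
def _bray_curtis_counts(x: np.ndarray, y: np.ndarray) -> float:
    s = x.sum() + y.sum()
    return float(np.abs(x - y).sum() / s)


def _draw_null_sample(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occupancy: np.ndarray,
    regional_p: np.ndarray,
    pool: np.ndarray,
    n_rand: int,
) -> np.ndarray:
    """n_rand null count vectors preserving richness and total reads.

    Species identity: weighted sampling without replacement, occupancy-
    weighted, via exponential sort keys (Efraimidis-Spirtes). Reads:
    multinomial with regional relative-abundance weights over the drawn set.
    """
    n_otu = occupancy.size
    keys = rng.exponential(size=(n_rand, pool.size)) / occupancy[pool]
    order = np.argpartition(keys, richness - 1, axis=1)[:, :richness]
    out = np.zeros((n_rand, n_otu), dtype=np.int64)
    for k in range(n_rand):
        sel = pool[order[k]]
        p = regional_p[sel]
        out[k, sel] = rng.multinomial(total, p / p.sum())
    return out


def raup_crick_bray(
    table: OtuTable, n_rand: int = 999, seed: int | None = None
) -> NullModelResult:
    """Modified Raup-Crick index on Bray-Curtis dissimilarity.

    RC = 2 * [ (#null BC < observed BC) + 0.5 * (#null BC = observed BC) ]
    / n_rand - 1, bounded in [-1, 1]. Counts should be rarefied to equal
    depth beforehand so read totals are comparable.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    counts = table.counts
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional_p = counts.sum(axis=0) / counts.sum()
    pool = np.flatnonzero(occupancy > 0)
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    if np.any(richness > pool.size):
        raise ValueError("sample richness exceeds regional pool size")
    if np.any(richness == 0):
        raise ValueError("empty sample")

    rng = np.random.default_rng(seed)
    n = table.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    obs = np.empty(iu.size)
    rc = np.empty(iu.size)
    null_mean = np.empty(iu.size)
    null_sd = np.empty(iu.size)
    eps = 1e-12
    for p_idx, (i, j) in enumerate(zip(iu, ju)):
        obs_bc = _bray_curtis_counts(counts[i].astype(float), counts[j].astype(float))
        null_a = _draw_null_sample(
            rng, int(richness[i]), int(totals[i]), occupancy, regional_p, pool, n_rand
        )
        null_b = _draw_null_sample(
            rng, int(richness[j]), int(totals[j]), occupancy, regional_p, pool, n_rand
        )
        diff = np.abs(null_a - null_b).sum(axis=1)
        tot = null_a.sum(axis=1) + null_b.sum(axis=1)
        null_bc = diff / tot
        less = np.count_nonzero(null_bc < obs_bc - eps)
        ties = np.count_nonzero(np.abs(null_bc - obs_bc) <= eps)
        rc[p_idx] = 2.0 * (less + 0.5 * ties) / n_rand - 1.0
        obs[p_idx] = obs_bc
        null_mean[p_idx] = null_bc.mean()
        null_sd[p_idx] = null_bc.std(ddof=1) if n_rand > 1 else 0.0
    pairs = [(table.sample_ids[i], table.sample_ids[j]) for i, j in zip(iu, ju)]
    return NullModelResult(
        "rc", list(table.sample_ids), pairs, obs, null_mean, null_sd, rc, n_rand, seed
    )


# ---------------------------------------------------------------------------
# five-way process classification
# ---------------------------------------------------------------------------
@dataclass
class ProcessSummary:
    """Per-pair assembly-process labels and the five process fractions.

    Pairs whose betaNTI is degenerate (zero null sd) are excluded from the
    fractions and reported via ``n_degenerate``.
    """

    per_pair: pd.DataFrame
    fractions: dict[str, float]
    n_degenerate: int
    bnti_cut: float
    rc_cut: float

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.per_pair["label"].notna().any() and abs(total - 1.0) > 1e-12:
            raise ValueError("process fractions must sum to 1")


def classify_pair(b: float, r: float, bnti_cut: float = BNTI_CUT, rc_cut: float = RC_CUT) -> str:
    """Five-way assignment for one (betaNTI, RC_Bray) pair.

    Strict inequalities for the extreme classes: scores exactly at a cutoff
    fall to the stochastic/undominated side.
    """
    if b > bnti_cut:
        return "variable_selection"
    if b < -bnti_cut:
        return "homogeneous_selection"
    if r < -rc_cut:
        return "homogenizing_dispersal"
    if r > rc_cut:
        return "dispersal_limitation"
    return "undominated"


def classify_processes(
    bnti_result: NullModelResult,
    rc_result: NullModelResult,
    bnti_cut: float = BNTI_CUT,
    rc_cut: float = RC_CUT,
) -> ProcessSummary:
    """Combine betaNTI and RC_Bray into the five-way process summary."""
    if bnti_result.pairs != rc_result.pairs:
        raise ValueError("betaNTI and RC results cover different sample pairs")
    rows = []
    for (a, b), bn, deg, rc in zip(
        bnti_result.pairs, bnti_result.score, bnti_result.degenerate, rc_result.score
    ):
        label = None if deg else classify_pair(float(bn), float(rc), bnti_cut, rc_cut)
        rows.append((a, b, np.nan if deg else float(bn), float(rc), label))
    per_pair = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "bnti", "rc", "label"]
    )
    valid = per_pair["label"].notna()
    n_deg = int((~valid).sum())
    counts = per_pair.loc[valid, "label"].value_counts()
    n_valid = int(valid.sum())
    fractions = {
        lab: (int(counts.get(lab, 0)) / n_valid if n_valid else 0.0)
        for lab in PROCESS_LABELS
    }
    return ProcessSummary(per_pair, fractions, n_deg, bnti_cut, rc_cut)
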