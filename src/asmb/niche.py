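"""Levins' habitat niche breadth and between-community comparisons.

For OTU *i* with distribution ``p_ij`` of its reads over samples *j*,
Levins' breadth is ``B_i = 1 / sum_j p_ij^2`` — the effective number of
habitats the OTU occupies, between 1 (a single sample) and the number of
samples (perfectly even occupancy). Community breadth aggregates the
per-OTU values over an OTU subset (unweighted mean by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable

logger = logging.getLogger(__name__)


def levins_breadth(table: OtuTable) -> pd.Series:
    """Per-OTU Levins' niche breadth B = 1 / sum_j p_ij^2.

    OTUs absent from every sample are excluded (logged), so every returned
    value lies in [1, n_samples].
    """
    totals = table.otu_sums().astype(float)
    present = totals > 0
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info("levins_breadth: excluded %d OTUs with zero total reads", n_dropped)
    counts = table.counts[:, present].astype(float)
    p = counts / counts.sum(axis=0)
    b = 1.0 / (p**2).sum(axis=0)
    ids = [o for o, keep in zip(table.otu_ids, present) if keep]
    return pd.Series(b, index=ids, name="levins_b")


def community_breadth(table: OtuTable, otu_subset, weighted: bool = False) -> float:
    """Aggregate niche breadth of a community subset.

    Unweighted mean of the per-OTU breadths by default; ``weighted=True``
    weights each OTU by its total read count.
    """
    otu_subset = [str(o) for o in otu_subset]
    if not otu_subset:
        raise ValueError("empty OTU subset")
    b = levins_breadth(table)
    missing = [o for o in otu_subset if o not in b.index]
    subset = [o for o in otu_subset if o in b.index]
    if missing:
        logger.info("community_breadth: %d subset OTUs absent/empty", len(missing))
    if not subset:
        raise ValueError("no subset OTU has any reads")
    if not weighted:
        return float(b.loc[subset].mean())
    totals = pd.Series(table.otu_sums(), index=table.otu_ids, dtype=float).loc[subset]
    return float(np.average(b.loc[subset], weights=totals))


def _compact_letters(names: list[str], sig: np.ndarray) -> dict[str, str]:
    """Compact letter display from a boolean significance matrix.

    Greedy insert-absorb: groups that are *not* significantly different share
    a letter.
    """
    k = len(names)
    letters_sets: list[set[int]] = []
    for i in range(k):
        placed = False
        for s in letters_sets:
            if all(not sig[i, j] for j in s):
                s.add(i)
                placed = True
        if not placed:
            letters_sets.append({i})
    # second pass: a group joins every earlier-created compatible set too
    for s in letters_sets:
        for i in range(k):
            if i not in s and all(not sig[i, j] for j in s):
                s.add(i)
    # drop sets fully contained in another (absorption)
    letters_sets = [
        s for s in letters_sets
        if not any(s < t for t in letters_sets)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, s in zip(alphabet, letters_sets):
        for i in sorted(s):
            out[names[i]] += letter
    return out


@dataclass(frozen=True)
class BreadthComparison:
    """Paired layer t-tests per class plus Tukey letters across classes."""

    layer_tests: pd.DataFrame    # class, mean_topsoil, mean_subsoil, t, p
    class_tests: pd.DataFrame    # layer, class, mean, letter
    anova: pd.DataFrame          # layer, F, p
    alpha: float


def compare_breadths(
    breadths: dict[str, dict[str, pd.Series]], alpha: float = 0.05
) -> BreadthComparison:
    """Compare niche breadths between layers and across community classes.

    ``breadths[class][layer]`` holds per-OTU Levins' breadths indexed by OTU
    id (e.g. classes overall/abundant/rare, layers topsoil/subsoil). Per
    class, a paired t-test contrasts layers over OTUs present in both; per
    layer, one-way ANOVA plus Tukey HSD across classes yields a compact
    letter display at ``alpha``.
    """
    classes = list(breadths)
    if len(classes) < 2:
        raise ValueError("need at least 2 community classes")
    layers = sorted({l for d in breadths.values() for l in d})
    if len(layers) != 2:
        raise ValueError("expected exactly 2 layers")

    rows = []
    for cls in classes:
        d = breadths[cls]
        if set(d) != set(layers):
            raise ValueError(f"class {cls!r} missing a layer")
        a, b = d[layers[0]], d[layers[1]]
        shared = a.index.intersection(b.index)
        if len(shared) < 2:
            raise ValueError(f"class {cls!r}: fewer than 2 OTUs shared between layers")
        x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x, y)
        rows.append((cls, float(x.mean()), float(y.mean()), float(t), float(p), len(shared)))
    layer_tests = pd.DataFrame(
        rows,
        columns=["class", f"mean_{layers[0]}", f"mean_{layers[1]}", "t", "p", "n_pairs"],
    )

    class_rows = []
    anova_rows = []
    for layer in layers:
        samples = [breadths[cls][layer].to_numpy(dtype=float) for cls in classes]
        if any(s.size < 2 for s in samples):
            raise ValueError("each class needs >= 2 OTUs for the Tukey comparison")
        f, p_anova = stats.f_oneway(*samples)
        anova_rows.append((layer, float(f), float(p_anova)))
        hsd = stats.tukey_hsd(*samples)
        sig = hsd.pvalue < alpha
        np.fill_diagonal(sig, False)
        letters = _compact_letters(classes, sig)
        for cls, s in zip(classes, samples):
            class_rows.append((layer, cls, float(s.mean()), letters[cls]))
    class_tests = pd.DataFrame(class_rows, columns=["layer", "class", "mean", "letter"])
    anova = pd.DataFrame(anova_rows, columns=["layer", "F", "p"])
    return BreadthComparison(layer_tests, class_tests, anova, alpha)


def breadths_by_class_and_layer(
    table: OtuTable, metadata, class_otus: dict[str, list[str]]
) -> dict[str, dict[str, pd.Series]]:
    """Per-OTU breadths computed within each layer, for each community class.

    ``class_otus`` maps class names (overall/abundant/rare) to OTU id lists;
    breadths are computed from the layer's samples only.
    """
    out: dict[str, dict[str, pd.Series]] = {}
    for cls, otus in class_otus.items():
        out[cls] = {}
        for layer in ("topsoil", "subsoil"):
            md = metadata.subset_layer(layer)
            sub = table.subset_samples(md.sample_ids)
            b = levins_breadth(sub)
            keep = [o for o in otus if o in b.index]
            if not keep:
                raise ValueError(f"class {cls!r} has no OTUs with reads in {layer}")
            out[cls][layer] = b.loc[keep]
    return out
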