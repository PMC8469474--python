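"""Independent brute-force reference implementations used only by tests.

These deliberately use naive per-element loops over an explicit tree/matrix
representation so they share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def bray_curtis_naive(x, y) -> float:
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def weighted_unifrac_naive(tree, rel_a: dict, rel_b: dict, normalized: bool = True) -> float:
    """Per-branch loop: sum l_b * |A_b - B_b| over every non-root branch,
    where A_b/B_b are summed relative abundances of the tips below b.
    Normalization divides by sum l_b * (A_b + B_b)."""
    num = 0.0
    den = 0.0
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in node.tips()] or [node.name]
        a = sum(rel_a.get(t, 0.0) for t in tips)
        b = sum(rel_b.get(t, 0.0) for t in tips)
        num += node.length * abs(a - b)
        den += node.length * (a + b)
    if not normalized:
        return num
    return num / den if den > 0 else 0.0


def patristic_naive(tree) -> tuple[list[str], np.ndarray]:
    """Tip-tip distances by summing branch lengths along root paths."""
    tips = list(tree.tips())
    names = [t.name for t in tips]

    def path_to_root(node):
        out = []
        while node.parent is not None:
            out.append(node)
            node = node.parent
        return out

    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = path_to_root(tips[i])
            pj = path_to_root(tips[j])
            si, sj = set(map(id, pi)), set(map(id, pj))
            dist = sum(x.length for x in pi if id(x) not in sj)
            dist += sum(x.length for x in pj if id(x) not in si)
            d[i, j] = d[j, i] = dist
    return names, d


def beta_mntd_naive(freq_a: dict, freq_b: dict, names, dmat) -> float:
    """Exhaustive nearest-taxon search, abundance-weighted, symmetrized."""
    idx = {n: i for i, n in enumerate(names)}
    pres_a = [n for n, f in freq_a.items() if f > 0]
    pres_b = [n for n, f in freq_b.items() if f > 0]
    s1 = sum(
        f * min(dmat[idx[n], idx[m]] for m in pres_b)
        for n, f in freq_a.items()
        if f > 0
    )
    s2 = sum(
        f * min(dmat[idx[n], idx[m]] for m in pres_a)
        for n, f in freq_b.items()
        if f > 0
    )
    return 0.5 * (s1 + s2)


def raup_crick_naive(counts: np.ndarray, i: int, j: int, n_rand: int, rng) -> float:
    """Naive RC_Bray for one sample pair: per-draw weighted choice without
    replacement by occupancy, multinomial fill by regional abundance."""
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    regional_p = regional / regional.sum()
    pool = np.flatnonzero(occupancy > 0)
    obs = bray_curtis_naive(counts[i], counts[j])

    def null_sample(row):
        richness = int((row > 0).sum())
        total = int(row.sum())
        w = occupancy[pool] / occupancy[pool].sum()
        chosen = rng.choice(pool, size=richness, replace=False, p=w)
        p = regional_p[chosen]
        out = np.zeros(counts.shape[1])
        out[chosen] = rng.multinomial(total, p / p.sum())
        return out

    less = ties = 0
    for _ in range(n_rand):
        bc = bray_curtis_naive(null_sample(counts[i]), null_sample(counts[j]))
        if bc < obs - 1e-12:
            less += 1
        elif abs(bc - obs) <= 1e-12:
            ties += 1
    return 2.0 * (less + 0.5 * ties) / n_rand - 1.0
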