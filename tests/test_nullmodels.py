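import numpy as np
import pytest

import asmb
from asmb.io import OtuTable
from asmb.nullmodels import PROCESS_LABELS, classify_pair

from .oracles import beta_mntd_naive, patristic_naive, raup_crick_naive
from .conftest import random_fixture


class TestBetaMntd:
    def test_identical_samples_zero(self, cherry_tree):
        t = OtuTable(["a", "b"], ["A", "B"], np.array([[2, 3], [2, 3]]))
        m = asmb.beta_mntd(t, cherry_tree)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_singleton_samples(self):
        """Single-OTU communities: betaMNTD equals the patristic distance."""
        tree = asmb.read_newick("((A:1,B:3):0,C:5);")
        t = OtuTable(["a", "b"], ["A", "B", "C"], np.array([[4, 0, 0], [0, 9, 0]]))
        m = asmb.beta_mntd(t, tree)
        assert m.values[0, 1] == pytest.approx(4.0, abs=1e-12)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_exhaustive_oracle(self, weighted):
        for seed in range(8):
            table, tree = random_fixture(seed, max_tips=8)
            m = asmb.beta_mntd(table, tree, abundance_weighted=weighted)
            names, dmat = patristic_naive(tree)
            pres = table.presence()
            if weighted:
                freq = table.relative_abundance()
            else:
                freq = pres / pres.sum(axis=1)[:, None]
            for i in range(table.shape[0]):
                for j in range(i + 1, table.shape[0]):
                    fa = dict(zip(table.otu_ids, freq[i]))
                    fb = dict(zip(table.otu_ids, freq[j]))
                    expect = beta_mntd_naive(fa, fb, names, dmat)
                    assert m.values[i, j] == pytest.approx(expect, abs=1e-10)

    def test_exclude_conspecifics_removes_self_matches(self):
        """Cosmopolitan taxa: with conspecifics excluded, shared OTUs match
        their nearest non-self relative instead of themselves."""
        tree = asmb.read_newick("((A:1,B:1):1,C:2);")
        t = OtuTable(["a", "b"], ["A", "B", "C"], np.array([[1, 0, 0], [1, 0, 0]]))
        inc = asmb.beta_mntd(t, tree, exclude_conspecifics=False)
        exc = asmb.beta_mntd(t, tree, exclude_conspecifics=True)
        assert inc.values[0, 1] == pytest.approx(0.0)
        # A's nearest non-self neighbour in a one-OTU sample falls back to A
        assert exc.values[0, 1] == pytest.approx(0.0)
        t2 = OtuTable(["a", "b"], ["A", "B", "C"], np.array([[1, 1, 0], [1, 1, 0]]))
        exc2 = asmb.beta_mntd(t2, tree, exclude_conspecifics=True)
        # every OTU matches its sibling at patristic distance 2
        assert exc2.values[0, 1] == pytest.approx(2.0)


class TestBnti:
    def test_deterministic_given_seed(self, small_dataset):
        table, tree, *_ = small_dataset
        sub = table.subset_samples(table.sample_ids[:5]).drop_empty_otus()
        a = asmb.bnti(sub, tree, n_rand=19, seed=42)
        b = asmb.bnti(sub, tree, n_rand=19, seed=42)
        assert np.array_equal(a.score, b.score)

    def test_degenerate_null_flagged(self, cherry_tree):
        """On a 2-tip cherry every tip shuffle is an automorphism, so the
        null is constant and the score undefined."""
        t = OtuTable(["a", "b"], ["A", "B"], np.array([[3, 1], [1, 3]]))
        res = asmb.bnti(t, cherry_tree, n_rand=9, seed=0)
        assert res.degenerate.all()
        assert np.isnan(res.score).all()

    def test_neutral_scores_standardized(self):
        """No phylogenetic signal in abundances: betaNTI behaves like a
        z-score. Pairs within one dataset share the dominant taxa and are
        strongly correlated, so the moments are pooled over datasets."""
        scores = []
        for seed in (21, 22, 23, 24):
            cfg = asmb.SimulationConfig(
                n_sites=6, n_otus=120, reads_per_sample=2000, seed=seed
            ).with_regime("neutral")
            table, tree, md = asmb.simulate_dataset(cfg)
            res = asmb.bnti(table, tree, n_rand=99, seed=1)
            scores.append(res.score[~res.degenerate])
        pooled = np.concatenate(scores)
        assert abs(pooled.mean()) < 0.5
        assert 0.5 < pooled.std() < 1.6

    def test_selection_regime_shifts_scores(self):
        cfg = asmb.SimulationConfig(
            n_sites=6, n_otus=120, reads_per_sample=2000, seed=22
        ).with_regime("selection")
        table, tree, md = asmb.simulate_dataset(cfg)
        res = asmb.bnti(table, tree, n_rand=99, seed=2)
        assert np.mean(np.abs(res.score[~res.degenerate]) > 2) > 0.3


class TestRaupCrick:
    def test_identical_samples_give_minus_one(self):
        """Identical communities: observed BC = 0 sits below every null."""
        rng = np.random.default_rng(5)
        row = rng.integers(1, 50, size=12)
        counts = np.vstack([row, row, rng.integers(1, 50, size=12)])
        t = OtuTable(["a", "b", "c"], [f"o{i}" for i in range(12)], counts)
        res = asmb.raup_crick_bray(t, n_rand=49, seed=1)
        pair = res.pairs.index(("a", "b"))
        assert res.score[pair] == pytest.approx(-1.0)

    def test_bounds_and_determinism(self, small_dataset):
        table, *_ = small_dataset
        sub = table.subset_samples(table.sample_ids[:5]).drop_empty_otus()
        a = asmb.raup_crick_bray(sub, n_rand=29, seed=7)
        b = asmb.raup_crick_bray(sub, n_rand=29, seed=7)
        assert np.array_equal(a.score, b.score)
        assert a.score.min() >= -1 and a.score.max() <= 1

    def test_matches_naive_null_construction(self):
        """The vectorized null agrees with an independently coded naive
        implementation of the same two-stage draw (statistical equality)."""
        table, _ = random_fixture(13, max_tips=8, max_samples=3, min_samples=3)
        res = asmb.raup_crick_bray(table, n_rand=400, seed=3)
        rng = np.random.default_rng(99)
        for p_idx, (a, b) in enumerate(res.pairs):
            i = table.sample_ids.index(a)
            j = table.sample_ids.index(b)
            naive = raup_crick_naive(table.counts, i, j, 400, rng)
            assert res.score[p_idx] == pytest.approx(naive, abs=0.25)

    def test_rank_formula_midpoint(self):
        """With every null draw equal to the observed value the rank formula
        lands exactly at 0 (all ties, weight one half)."""
        t = OtuTable(["a", "b"], ["x"], np.array([[5], [5]]))
        # single shared OTU: observed BC = 0 and every null BC = 0
        res = asmb.raup_crick_bray(t, n_rand=99, seed=0)
        assert res.score[0] == pytest.approx(0.0)


class TestClassification:
    @pytest.mark.parametrize(
        "b,r,label",
        [
            (2.5, 0.1, "variable_selection"),
            (-3.0, 0.0, "homogeneous_selection"),
            (0.3, 0.99, "dispersal_limitation"),
            (1.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            # boundary convention: exactly at a cutoff falls inward
            (2.0, 0.0, "undominated"),
            (-2.0, 0.0, "undominated"),
            (0.0, 0.95, "undominated"),
            (0.0, -0.95, "undominated"),
        ],
    )
    def test_five_way_rules(self, b, r, label):
        assert classify_pair(b, r) == label

    def test_fractions_sum_to_one(self, small_dataset):
        table, tree, *_ = small_dataset
        sub = table.subset_samples(table.sample_ids[:6]).drop_empty_otus()
        bn = asmb.bnti(sub, tree, n_rand=29, seed=1)
        rc = asmb.raup_crick_bray(sub, n_rand=29, seed=2)
        summary = asmb.classify_processes(bn, rc)
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert set(summary.fractions) == set(PROCESS_LABELS)
        assert len(summary.per_pair) == len(bn.pairs)

    def test_mismatched_pairs_rejected(self, small_dataset):
        table, tree, *_ = small_dataset
        a = table.subset_samples(table.sample_ids[:5]).drop_empty_otus()
        b = table.subset_samples(table.sample_ids[1:6]).drop_empty_otus()
        bn = asmb.bnti(a, tree, n_rand=9, seed=1)
        rc = asmb.raup_crick_bray(b, n_rand=9, seed=2)
        with pytest.raises(ValueError, match="different sample pairs"):
            asmb.classify_processes(bn, rc)
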