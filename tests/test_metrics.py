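from itertools import combinations

import numpy as np
import pytest

from ssber.io_preprocess import GeneSet
from ssber.metrics import (ari, cell_cycle_conservation, hvg_conservation,
                           hvg_overlap, isolated_label_score, kbet, lisi,
                           median_lisi, silhouette_asw)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def ari_pair_counting(a, b):
    """ARI via the raw pair-counting contingency formula."""
    n = len(a)
    same_a = {(i, j) for i, j in combinations(range(n), 2) if a[i] == a[j]}
    same_b = {(i, j) for i, j in combinations(range(n), 2) if b[i] == b[j]}
    n11 = len(same_a & same_b)
    n00 = len({(i, j) for i, j in combinations(range(n), 2)}
              - same_a - same_b)
    total = n * (n - 1) / 2
    expected = (len(same_a) * len(same_b) + (total - len(same_a))
                * (total - len(same_b))) / total
    return (n11 + n00 - expected) / (total - expected)


def silhouette_brute(X, labels):
    n = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
    out = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            out[i] = 0.0
            continue
        a = d[i, own].mean()
        b = min(d[i, [j for j in range(n) if labels[j] == lab]].mean()
                for lab in set(labels) if lab != labels[i])
        out[i] = (b - a) / max(a, b)
    return out.mean()


class TestAri:
    def test_identical_labelings(self):
        assert ari([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_crossed_pairs_hand_value(self):
        assert ari([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 3, 20)
            b = rng.integers(0, 4, 20)
            assert ari(a, b) == pytest.approx(ari_pair_counting(a, b),
                                              abs=1e-12)

    def test_invariant_under_label_renaming(self, rng):
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        renamed = np.array(["xyz"[v] for v in b])
        assert ari(a, b) == pytest.approx(ari(a, renamed), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ari([1, 2], [1, 2, 3])


class TestSilhouette:
    def test_far_separated_clusters_near_one(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (30, 2)),
                       rng.normal(50, 0.1, (30, 2))])
        labels = ["a"] * 30 + ["b"] * 30
        assert silhouette_asw(X, labels, "celltype") > 0.9

    def test_random_batch_labels_near_zero(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(1000, 5))
        labels = rng.choice(["a", "b"], 1000)
        assert abs(silhouette_asw(X, labels, "batch")) < 0.05

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(40, 3))
        labels = rng.choice(["a", "b", "c"], 40)
        assert silhouette_asw(X, labels) == pytest.approx(
            silhouette_brute(X, labels), abs=1e-12)

    def test_single_label_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette_asw(rng.normal(size=(5, 2)), ["a"] * 5)


class TestLisi:
    def test_single_category_scores_one_everywhere(self, rng):
        X = rng.normal(size=(50, 3))
        np.testing.assert_array_equal(lisi(X, ["a"] * 50), 1.0)

    def test_bounded_by_category_count(self, rng):
        X = rng.normal(size=(300, 4))
        labels = rng.choice(["a", "b", "c"], 300)
        scores = lisi(X, labels)
        assert scores.max() <= 3.0 + 1e-9
        assert scores.min() >= 1.0 - 1e-9

    def test_pure_separated_clusters_give_clisi_one(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (120, 3)),
                       rng.normal(60, 0.2, (120, 3))])
        labels = ["a"] * 120 + ["b"] * 120
        assert median_lisi(X, labels) == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(150, 3))
        labels = rng.choice(["a", "b"], 150)
        perm = rng.permutation(150)
        np.testing.assert_allclose(lisi(X, labels)[perm],
                                   lisi(X[perm], labels[perm]), atol=1e-9)


class TestKbet:
    def test_separated_blocks_reject_everywhere(self, rng):
        X = np.vstack([rng.normal(0, 1, (200, 4)), rng.normal(30, 1, (200, 4))])
        labels = ["a"] * 200 + ["b"] * 200
        med, by_frac = kbet(X, labels)
        assert med >= 0.95
        assert set(by_frac) == {0.05, 0.10, 0.15, 0.20, 0.25}

    def test_well_mixed_low_rejection(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(1000, 6))
        labels = rng.choice(["a", "b"], 1000)
        med, _ = kbet(X, labels)
        assert med <= 0.05 + 0.02

    def test_single_batch_rejected(self, rng):
        with pytest.raises(ValueError):
            kbet(rng.normal(size=(100, 2)), ["a"] * 100)

    def test_tiny_fractions_skipped_with_warning(self, rng):
        X = rng.normal(size=(60, 2))
        labels = rng.choice(["a", "b"], 60)
        with pytest.warns(UserWarning, match="skipped"):
            med, by_frac = kbet(X, labels)
        assert 0.05 not in by_frac


class TestIsolatedLabel:
    def test_far_isolated_label_scores_high(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (60, 3)),
                       rng.normal(8, 0.3, (60, 3)),
                       rng.normal(40, 0.3, (30, 3))])
        cell = ["a"] * 60 + ["b"] * 60 + ["rare"] * 30
        batch = (["b1", "b2"] * 30) + (["b1", "b2"] * 30) + ["b1"] * 30
        score = isolated_label_score(X, cell, batch)
        assert score > 0.9

    def test_score_within_unit_interval(self, rng):
        X = rng.normal(size=(90, 3))
        cell = rng.choice(["a", "b", "c"], 90)
        batch = rng.choice(["b1", "b2"], 90)
        with pytest.warns(UserWarning):
            s = isolated_label_score(X, cell, batch)
        assert 0.0 <= s <= 1.0


class TestHvgOverlap:
    def test_identity_disjoint_and_hand_value(self):
        a, b = GeneSet("abc"), GeneSet("bcd")
        assert hvg_overlap(a, a) == 1.0
        assert hvg_overlap(a, b) == pytest.approx(2 / 3)
        assert hvg_overlap(GeneSet("ab"), GeneSet("cd")) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            hvg_overlap(GeneSet(), GeneSet("a"))


class TestHvgConservation:
    def _batch(self, rng, batch, n=60, g=200):
        X = rng.normal(2.0, 1.0, (n, g)).clip(min=0)
        X[:, :30] *= 3.0  # a stable high-variance block
        return make_matrix(X, batch=batch, layer="lognorm")

    def test_identity_scores_one(self, rng):
        from ssber.io_preprocess import concat
        b1, b2 = self._batch(rng, "b1"), self._batch(rng, "b2")
        merged = concat([b1, b2])
        assert hvg_conservation([b1, b2], merged) == pytest.approx(1.0)

    def test_variance_destruction_lowers_score(self, rng):
        from ssber.io_preprocess import concat
        b1, b2 = self._batch(rng, "b1"), self._batch(rng, "b2")
        merged = concat([b1, b2])
        wrecked = merged.copy()
        X = wrecked.dense()
        X[:, 100:] = rng.normal(0, 50.0, X[:, 100:].shape)  # new fake HVGs
        wrecked.values = X
        score = hvg_conservation([b1, b2], wrecked)
        assert score < 1.0
        assert 0.0 <= score <= 1.0


class TestCellCycle:
    def _cycling(self, rng, n=400, g=300):
        s_latent = rng.normal(size=n)
        g2m_latent = rng.normal(size=n)
        X = rng.normal(1.0, 0.3, (n, g))
        X[:, :25] += 1.5 * s_latent[:, None]
        X[:, 25:50] += 1.5 * g2m_latent[:, None]
        m = make_matrix(X, layer="lognorm")
        s = GeneSet(f"g{i}" for i in range(25))
        g2m = GeneSet(f"g{i}" for i in range(25, 50))
        return m, s, g2m

    def test_identity_scores_one(self, rng):
        m, s, g2m = self._cycling(rng)
        assert cell_cycle_conservation(m, m, s, g2m) == pytest.approx(1.0)

    def test_shuffling_cycle_genes_destroys_score(self, rng):
        m, s, g2m = self._cycling(rng)
        after = m.copy()
        X = after.dense()
        X[:, :50] = X[rng.permutation(m.n_cells), :50]
        after.values = X
        assert cell_cycle_conservation(m, after, s, g2m) < 0.1

    def test_score_clamped_to_unit_interval(self, rng):
        m, s, g2m = self._cycling(rng, n=200)
        after = m.copy()
        after.values = after.dense() * 3.0
        score = cell_cycle_conservation(m, after, s, g2m)
        assert 0.0 <= score <= 1.0


def test_metrics_are_cell_permutation_invariant(rng):
    X = rng.normal(size=(200, 4))
    cell = rng.choice(["a", "b"], 200)
    batch = rng.choice(["x", "y"], 200)
    perm = rng.permutation(200)
    assert ari(cell, batch) == pytest.approx(ari(cell[perm], batch[perm]))
    assert silhouette_asw(X, cell) == pytest.approx(
        silhouette_asw(X[perm], cell[perm]), abs=1e-12)
    assert kbet(X, batch)[0] == pytest.approx(kbet(X[perm], batch[perm])[0],
                                              abs=1e-12)
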