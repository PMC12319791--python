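"""Cross-run pattern similarity, Dice overlap, UPGMA and the cutoff."""

import itertools

import numpy as np
import pandas as pd
import pytest

from emokinetics.clustering import (EmotionClusterer, cluster_cut,
                                    cross_run_similarity,
                                    dice_similarity_matrix, emotion_pattern,
                                    generalized_dice, hcluster)
from emokinetics.config import ValidationError
from emokinetics.mapping import fisher_z


class TestEmotionPattern:
    def test_single_participant_single_run_is_their_z_map(self, rng):
        r = rng.uniform(-0.8, 0.8, size=(1, 5, 3, 2))
        pat = emotion_pattern(r, ["run1", "run2"], ("run1",))
        np.testing.assert_allclose(pat, fisher_z(r[0, :, :, 0]).T)

    def test_two_identical_runs_idempotent(self, rng):
        r1 = rng.uniform(-0.8, 0.8, size=(3, 5, 4))
        r = np.stack([r1, r1], axis=3)
        both = emotion_pattern(r, ["a", "b"], ("a", "b"))
        one = emotion_pattern(r, ["a", "b"], ("a",))
        np.testing.assert_allclose(both, one)

    def test_matches_nested_mean_oracle(self, rng):
        r = rng.uniform(-0.9, 0.9, size=(4, 6, 3, 5))
        pat = emotion_pattern(r, list("abcde"), ("b", "d"))
        for e in range(3):
            for roi in range(6):
                vals = [fisher_z(r[p, roi, e, k]) for p in range(4)
                        for k in (1, 3)]
                assert pat[e, roi] == pytest.approx(np.mean(vals))

    def test_empty_run_set_rejected(self, rng):
        with pytest.raises(ValidationError):
            emotion_pattern(rng.random((2, 3, 2, 2)), ["a", "b"], ())


class TestCrossRunSimilarity:
    def test_toy_matches_correlation_oracle(self, rng):
        # 2 runs -> 2 splits; patterns computable by hand
        r = rng.uniform(-0.8, 0.8, size=(2, 4, 3, 2))
        sym, raw = cross_run_similarity(r, ["a", "b"], 1, ["e1", "e2", "e3"])
        z = fisher_z(r)
        pa = z[:, :, :, 0].mean(axis=0).T       # emotion x ROI, run a
        pb = z[:, :, :, 1].mean(axis=0).T
        oracle = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                oracle[i, j] = (np.corrcoef(pa[i], pb[j])[0, 1]
                                + np.corrcoef(pb[i], pa[j])[0, 1]) / 2
        np.testing.assert_allclose(raw.to_numpy(), oracle, atol=1e-12)
        np.testing.assert_allclose(sym.to_numpy(),
                                   (oracle + oracle.T) / 2, atol=1e-12)

    def test_anticorrelated_pattern_gives_minus_one(self):
        base = np.array([0.1, -0.2, 0.3, 0.15])
        r = np.zeros((1, 4, 2, 2))
        for k in range(2):
            r[0, :, 0, k] = base
            r[0, :, 1, k] = -base
        sym, _ = cross_run_similarity(r, ["a", "b"], 1, ["e1", "e2"])
        assert sym.loc["e1", "e2"] == pytest.approx(-1.0, abs=1e-6)

    def test_diagonal_is_between_run_reliability(self, rng):
        common = rng.uniform(-0.5, 0.5, size=(4, 2))   # ROI x emotion
        r = np.zeros((1, 4, 2, 2))
        for k in range(2):
            r[0, :, :, k] = common + rng.normal(0, 0.02, size=(4, 2))
        sym, _ = cross_run_similarity(r, ["a", "b"], 1, ["e1", "e2"])
        assert np.diag(sym.to_numpy()).min() > 0.9
        assert not np.allclose(np.diag(sym.to_numpy()), 1.0)


class TestGeneralizedDice:
    def test_identical_nonempty_masks(self):
        m = np.array([1, -1, 0, 1])
        assert generalized_dice(m, m) == 1.0

    def test_disjoint_supports(self):
        assert generalized_dice(np.array([1, 0, 0]),
                                np.array([0, 1, 0])) == 0.0

    def test_set_count_arithmetic(self):
        # P_a = {1,2}, P_b = {2,3}: 2*1 / 4 = 0.5
        a = np.array([0, 1, 1, 0])
        b = np.array([0, 0, 1, 1])
        assert generalized_dice(a, b) == 0.5

    def test_opposite_signs_do_not_count(self):
        assert generalized_dice(np.array([1, -1]), np.array([-1, 1])) == 0.0

    def test_empty_masks_defined_as_zero(self):
        assert generalized_dice(np.zeros(3, int), np.zeros(3, int)) == 0.0

    def test_non_ternary_rejected(self):
        with pytest.raises(ValidationError):
            generalized_dice(np.array([2, 0]), np.array([0, 1]))

    def test_matrix_symmetric_unit_diagonal(self, rng):
        masks = pd.DataFrame(rng.choice([-1, 0, 1], size=(6, 3)),
                             columns=list("xyz"))
        D = dice_similarity_matrix(masks)
        np.testing.assert_allclose(D.to_numpy(), D.to_numpy().T)


def manual_upgma_4(d):
    """Hand-rolled UPGMA for a 4-point distance matrix: returns merge
    heights in order."""
    clusters = {i: [i] for i in range(4)}
    heights = []
    dd = {frozenset((i, j)): d[i][j] for i in range(4) for j in range(i + 1, 4)}

    def dist(a, b):
        return np.mean([d[i][j] for i in clusters[a] for j in clusters[b]])

    next_id = 4
    while len(clusters) > 1:
        pairs = list(itertools.combinations(sorted(clusters), 2))
        best = min(pairs, key=lambda p: (dist(*p), p))
        heights.append(dist(*best))
        clusters[next_id] = clusters.pop(best[0]) + clusters.pop(best[1])
        next_id += 1
    return heights


class TestHcluster:
    def test_two_block_structure(self):
        sim = np.full((6, 6), 0.1)
        sim[:3, :3] = 0.9
        sim[3:, 3:] = 0.9
        np.fill_diagonal(sim, 1.0)
        Z, order = hcluster(pd.DataFrame(sim))
        # first 4 merges stay within blocks; final merge joins the blocks
        assert Z[:4, 2].max() < 0.2
        assert Z[4, 2] == pytest.approx(0.9)
        labels = cluster_cut(Z, 0.7)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_merge_heights_match_manual_upgma(self):
        sim = np.array([[1.0, 0.8, 0.3, 0.1],
                        [0.8, 1.0, 0.2, 0.15],
                        [0.3, 0.2, 1.0, 0.6],
                        [0.1, 0.15, 0.6, 1.0]])
        Z, _ = hcluster(pd.DataFrame(sim))
        d = 1.0 - sim
        np.testing.assert_allclose(sorted(Z[:, 2]),
                                   sorted(manual_upgma_4(d)), atol=1e-12)

    def test_leaf_order_maximizes_adjacent_similarity(self, rng):
        sim = rng.uniform(0, 1, size=(5, 5))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        Z, order = hcluster(pd.DataFrame(sim))
        got = sum(sim[order[i], order[i + 1]] for i in range(4))

        # brute force over all orders consistent with the tree: enumerate
        # all 2^(n-1) flips of internal nodes
        from scipy.cluster import hierarchy

        def orders(node):
            if node.is_leaf():
                return [[node.id]]
            out = []
            for lo in orders(node.left):
                for ro in orders(node.right):
                    out.append(lo + ro)
                    out.append(ro + lo)
            return out

        tree = hierarchy.to_tree(Z)
        best = max(sum(sim[o[i], o[i + 1]] for i in range(4))
                   for o in orders(tree))
        assert got == pytest.approx(best)

    def test_nan_entries_rejected(self):
        sim = np.eye(3)
        sim[0, 1] = sim[1, 0] = np.nan
        with pytest.raises(ValidationError, match="NaN"):
            hcluster(pd.DataFrame(sim, index=list("abc"),
                                  columns=list("abc")))


class TestClusterCut:
    def _z(self):
        sim = np.full((6, 6), 0.1)
        sim[:3, :3] = 0.9
        sim[3:, 3:] = 0.9
        np.fill_diagonal(sim, 1.0)
        return hcluster(pd.DataFrame(sim))[0]

    def test_two_blocks_at_seventy_percent(self):
        labels = cluster_cut(self._z(), 0.70)
        assert len(set(labels)) == 2 and 0 not in labels

    def test_fraction_one_excludes_top_merge(self):
        # strict inequality: the merge at exactly the cut height stays split
        labels = cluster_cut(self._z(), 1.0)
        assert len(set(labels)) == 2

    def test_tiny_fraction_gives_all_singletons(self):
        labels = cluster_cut(self._z(), 1e-6)
        assert (labels == 0).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValidationError):
            cluster_cut(self._z(), 0.0)
        with pytest.raises(ValidationError):
            cluster_cut(self._z(), 1.5)

    def test_estimator_wrapper(self):
        sim = np.full((4, 4), 0.2)
        sim[:2, :2] = 0.9
        sim[2:, 2:] = 0.9
        np.fill_diagonal(sim, 1.0)
        df = pd.DataFrame(sim, index=list("abcd"), columns=list("abcd"))
        model = EmotionClusterer(0.7).fit(df)
        assert model.labels_.tolist() == [1, 1, 2, 2]
        struct = model.structure(df)
        assert struct.n_clusters == 2
        assert struct.to_newick().endswith(";")


class TestPlantedClusterRecovery:
    def test_planted_blocks_recovered_with_perfect_ari(self):
        """Planted response-pattern blocks are recovered exactly by UPGMA
        with the 70% cutoff at high snr."""
        from sklearn.metrics import adjusted_rand_score

        from emokinetics.clustering import cross_run_beta_similarity
        from emokinetics.simulate import SimulationSpec, simulate_study

        for k, seed in [(2, 0), (3, 1), (4, 2)]:
            spec = SimulationSpec(n_raters=3, n_emotions=8, n_reliable=8,
                                  n_runs=3, n_timepoints_per_run=200,
                                  n_participants=6, n_rois=40, snr=5.0,
                                  rng_seed=600 + seed, n_pattern_blocks=k,
                                  beta_sparsity=0.0)
            st = simulate_study(spec, tasks=("perceived",))
            d = {run: st.designs[(run, "perceived")]
                 for run in st.dataset.runs}
            sym, _ = cross_run_beta_similarity(st.dataset, d, 2)
            model = EmotionClusterer(0.70).fit(sym)
            truth = st.truth.noise["block_labels"]["perceived"]
            ari = adjusted_rand_score(truth.to_numpy(), model.labels_)
            assert ari == 1.0, f"k={k}: ARI {ari}"
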