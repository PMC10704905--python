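"""Evaluation metrics against independent brute-force oracles."""

import itertools
import math
from math import comb, log

import numpy as np
import pytest

from blobsieve import FeatureMatrix, SimulationConfig, adjusted_rand, \
    f1_score, pca_2d, pcc_matrix, silhouette, standardize, v_measure
from blobsieve.evaluate import confusion
from blobsieve.geometry import FEATURE_NAMES


# ---------------------------------------------------------------- oracles

def ari_oracle(truth, pred):
    """Pair-counting ARI: explicit enumeration of all sample pairs plus the
    permutation-model expectation from the contingency marginals."""
    n = len(truth)
    same_t = same_p = same_both = 0
    for i, j in itertools.combinations(range(n), 2):
        st, sp = truth[i] == truth[j], pred[i] == pred[j]
        same_t += st
        same_p += sp
        same_both += st and sp
    total = comb(n, 2)
    expected = same_t * same_p / total
    max_index = (same_t + same_p) / 2
    if max_index == expected:
        return 1.0
    return (same_both - expected) / (max_index - expected)


def v_oracle(truth, pred, beta=1.0):
    """V-measure from conditional entropies of the contingency table."""
    n = len(truth)
    t_classes, p_classes = sorted(set(truth)), sorted(set(pred))
    cont = np.array([[sum(1 for t, p in zip(truth, pred) if t == tc and p == pc)
                      for pc in p_classes] for tc in t_classes], dtype=float)

    def entropy(counts):
        probs = counts[counts > 0] / n
        return -float(np.sum(probs * np.log(probs)))

    h_t, h_p = entropy(cont.sum(axis=1)), entropy(cont.sum(axis=0))
    h_t_given_p = -sum(
        cont[i, j] / n * log(cont[i, j] / cont[:, j].sum())
        for i in range(len(t_classes)) for j in range(len(p_classes))
        if cont[i, j] > 0)
    h_p_given_t = -sum(
        cont[i, j] / n * log(cont[i, j] / cont[i, :].sum())
        for i in range(len(t_classes)) for j in range(len(p_classes))
        if cont[i, j] > 0)
    hom = 1.0 if h_t == 0 else 1.0 - h_t_given_p / h_t
    com = 1.0 if h_p == 0 else 1.0 - h_p_given_t / h_p
    if hom + com == 0:
        return 0.0
    return (1 + beta) * hom * com / (beta * hom + com)


def silhouette_oracle(X, labels):
    """Per-sample silhouette from explicit distance means, then averaged."""
    X, labels = np.asarray(X, float), np.asarray(labels)
    scores = []
    for i in range(len(X)):
        own = labels[i]
        same = [j for j in range(len(X)) if labels[j] == own and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j])
                     for j in range(len(X)) if labels[j] == other])
            for other in set(labels) if other != own)
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def _fm(values, standardized=False):
    values = np.asarray(values, float)
    return FeatureMatrix(track_ids=list(range(len(values))), values=values,
                         standardized=standardized)


# ------------------------------------------------------------------ tests

class TestF1:
    def test_one_false_positive_out_of_500(self):
        truth = ["blob"] * 250 + ["free"] * 250
        pred = ["blob"] * 251 + ["free"] * 249  # one free flagged as blob
        assert f1_score(truth, pred) == pytest.approx(500 / 501, abs=1e-12)

    def test_perfect_and_degenerate(self):
        truth = ["blob", "free", "blob"]
        assert f1_score(truth, truth) == 1.0
        assert f1_score(truth, ["free"] * 3) == 0.0
        with pytest.raises(ValueError):
            f1_score(["free", "free"], ["free", "free"])

    def test_confusion_matrix_sums(self):
        truth = ["blob"] * 3 + ["free"] * 4
        pred = ["blob", "free", "blob", "free", "blob", "free", "free"]
        cm = confusion(truth, pred)
        assert cm.sum() == 7
        assert cm[0, 0] == 2 and cm[0, 1] == 1
        assert cm[1, 0] == 1 and cm[1, 1] == 3


class TestARI:
    def test_identical_partitions(self):
        assert adjusted_rand([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(8)
        vals = [adjusted_rand(rng.integers(0, 2, 1000).tolist(),
                              rng.integers(0, 2, 1000).tolist())
                for _ in range(100)]
        assert abs(np.mean(vals)) < 0.02

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            t = rng.integers(0, 3, n).tolist()
            p = rng.integers(0, 3, n).tolist()
            if len(set(t)) < 2 or len(set(p)) < 2:
                continue
            assert adjusted_rand(t, p) == pytest.approx(ari_oracle(t, p),
                                                        abs=1e-12)

    def test_one_element_moved(self):
        t = [0] * 250 + [1] * 250
        p = list(t)
        p[0] = 1
        assert adjusted_rand(t, p) == pytest.approx(ari_oracle(t, p), abs=1e-12)


class TestVMeasure:
    def test_identical_partitions(self):
        assert v_measure(["a", "b", "a"], [1, 0, 1]) == pytest.approx(1.0)

    def test_single_predicted_cluster(self):
        assert v_measure([0, 0, 1, 1], [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_matches_entropy_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            t = rng.integers(0, 3, n).tolist()
            p = rng.integers(0, 3, n).tolist()
            assert v_measure(t, p) == pytest.approx(v_oracle(t, p), abs=1e-12)

    def test_single_flip_in_500(self):
        t = [0] * 250 + [1] * 250
        p = list(t)
        p[10] = 1
        assert v_measure(t, p) == pytest.approx(v_oracle(t, p), abs=1e-12)


class TestSilhouette:
    def test_two_tight_clusters_near_one(self):
        X = np.vstack([np.zeros((5, 5)) + 1e-9 * np.arange(5)[:, None],
                       np.full((5, 5), 100.0) + 1e-9 * np.arange(5)[:, None]])
        fm = _fm(X, standardized=True)
        assert silhouette(fm, [0] * 5 + [1] * 5) == pytest.approx(1.0, abs=1e-6)

    def test_arbitrary_split_of_one_cluster_nonpositive(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(10, 5))
        fm = _fm(X)
        labels = [0, 1] * 5
        val = silhouette(fm, labels)
        assert val == pytest.approx(silhouette_oracle(X, labels), abs=1e-12)
        assert val <= 0.1  # arbitrary split of one blob: no real structure

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            X = rng.normal(size=(12, 5))
            labels = rng.integers(0, 2, 12)
            if len(set(labels.tolist())) < 2:
                continue
            assert silhouette(_fm(X), labels) == pytest.approx(
                silhouette_oracle(X, labels), abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(10, 5))
        labels = [0] * 5 + [1] * 5
        fm = _fm(X)
        assert silhouette(fm, labels) == pytest.approx(
            silhouette(fm, [1 - c for c in labels]), abs=1e-12)


class TestMetricRanges:
    def test_ranges_on_random_label_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            t = ["blob" if b else "free" for b in rng.integers(0, 2, n)]
            p = ["blob" if b else "free" for b in rng.integers(0, 2, n)]
            if "blob" in t or "blob" in p:
                assert 0.0 <= f1_score(t, p) <= 1.0
            assert adjusted_rand(t, p) <= 1.0
            assert 0.0 <= v_measure(t, p) <= 1.0

    def test_ari_v_invariant_under_relabeling(self):
        rng = np.random.default_rng(18)
        t = rng.integers(0, 2, 50).tolist()
        p = rng.integers(0, 2, 50).tolist()
        q = [1 - c for c in p]
        assert adjusted_rand(t, p) == pytest.approx(adjusted_rand(t, q))
        assert v_measure(t, p) == pytest.approx(v_measure(t, q))


class TestPCC:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(19)
        col = rng.normal(size=40)
        vals = np.column_stack([col, col, -col, rng.normal(size=40),
                                rng.normal(size=40)])
        pcc = pcc_matrix(_fm(vals))
        assert pcc[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert pcc[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(pcc, pcc.T)
        assert np.allclose(np.diag(pcc), 1.0)

    def test_zero_variance_column_rejected(self):
        vals = np.random.default_rng(0).normal(size=(10, 5))
        vals[:, 0] = 2.0
        with pytest.raises(ValueError, match="d_max"):
            pcc_matrix(_fm(vals))


class TestPCA:
    def test_rank_one_data_evr(self):
        t = np.linspace(-1, 1, 20)
        vals = np.outer(t, np.array([1.0, 2.0, 0.0, 0.0, 0.0]))
        vals[:, 2] = t**2 * 1e-3  # independent direction: rank 2, tiny variance
        fm = _fm(vals, standardized=True)
        _, evr, _ = pca_2d(fm)
        assert evr[0] == pytest.approx(1.0, abs=1e-5)
        assert evr[1] == pytest.approx(0.0, abs=1e-5)

    def test_projection_preserves_rank2_distances(self):
        rng = np.random.default_rng(20)
        # exactly rank-2 data: distances must be reproduced by the projection
        basis = rng.normal(size=(2, 5))
        coeffs = rng.normal(size=(30, 2))
        X = coeffs @ basis
        fm = _fm(X, standardized=True)
        _, _, proj = pca_2d(fm)
        d_full = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        d_proj = np.linalg.norm(proj[:, None] - proj[None, :], axis=-1)
        assert d_proj == pytest.approx(d_full, abs=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(25, 5))
        fm = _fm(X, standardized=True)
        vecs, _, _ = pca_2d(fm)
        for row in vecs:
            assert row[np.argmax(np.abs(row))] > 0


@pytest.fixture(scope="module")
def default_features():
    from blobsieve import extract_features, generate_ground_truth
    tracks = generate_ground_truth(SimulationConfig(seed=23))
    items = [(t.track_id, extract_features(t)) for t in tracks]
    return FeatureMatrix.from_features(items)


class TestFeatureSpaceStructure:
    def test_correlation_sign_pattern(self, default_features):
        """d_max and hull area correlate; both anti-correlate with
        density, sphericality and ellipticity."""
        pcc = pcc_matrix(default_features)
        i = {name: k for k, name in enumerate(FEATURE_NAMES)}
        assert pcc[i["d_max"], i["hull_measure"]] > 0
        for feat in ("density", "sphericality", "ellipticity"):
            assert pcc[i["d_max"], i[feat]] < 0
            assert pcc[i["hull_measure"], i[feat]] < 0

    def test_first_component_dominates(self, default_features):
        fm_std = standardize(default_features)
        _, evr, _ = pca_2d(fm_std)
        assert 0.6 <= evr[0] <= 0.9
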