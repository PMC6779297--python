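"""Undersampling by Ward clustering and per-cell-line SVM training."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import AgglomerativeClustering

import cellfishing as cf
from cellfishing.balancing import _largest_remainder_quotas
from cellfishing.curation import RESISTANT, SENSITIVE


class TestIsBalanced:
    @pytest.mark.parametrize(
        "n_maj, n_min, balanced",
        [
            (100, 90, True),  # 100 <= 1.2 * 90
            (120, 100, True),  # exactly 1.2x is NOT "more than"
            (121, 100, False),
            (50, 50, True),
        ],
    )
    def test_ratio_rule(self, n_maj, n_min, balanced):
        assert cf.is_balanced(n_maj, n_min) is balanced

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            cf.is_balanced(10, 0)


class TestWardClusters:
    def test_identical_compounds_form_one_cluster(self):
        dm = np.zeros((2, 2))
        assert cf.ward_clusters(dm, height=4.5).max() == 1

    def test_all_zero_distances_form_one_cluster(self):
        dm = np.zeros((8, 8))
        assert cf.ward_clusters(dm, height=4.5).max() == 1

    def test_two_distant_blocks_split_at_default_height(self):
        """Two tight 25-point groups far apart cut into exactly 2 clusters."""
        n = 25
        dm = np.full((2 * n, 2 * n), 10.0)
        dm[:n, :n] = 0.05
        dm[n:, n:] = 0.05
        np.fill_diagonal(dm, 0.0)
        labels = cf.ward_clusters(dm, height=4.5)
        assert labels.max() == 2
        assert len(set(labels[:n])) == 1 and len(set(labels[n:])) == 1

    def test_agrees_with_independent_agglomerative_implementation(self):
        """Cutting at a height reproduces sklearn's Ward partition on points."""
        rng = np.random.default_rng(5)
        pts = np.vstack(
            [rng.normal(c, 0.3, size=(15, 4)) for c in (0.0, 5.0, 10.0)]
        )
        dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ours = cf.ward_clusters(dm, height=4.0)
        oracle = AgglomerativeClustering(
            n_clusters=None, distance_threshold=4.0, linkage="ward"
        ).fit_predict(pts)
        # same partition up to label renaming
        same_ours = ours[:, None] == ours[None, :]
        same_oracle = oracle[:, None] == oracle[None, :]
        assert np.array_equal(same_ours, same_oracle)

    def test_asymmetric_matrix_rejected(self):
        dm = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(cf.DimensionError):
            cf.ward_clusters(dm)


class TestQuotas:
    def test_proportional_arithmetic(self):
        # two clusters of 30 and 10, Nm = 20 -> 15 and 5
        assert _largest_remainder_quotas(np.array([30, 10]), 20).tolist() == [15, 5]

    def test_quotas_sum_and_respect_sizes(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sizes = rng.integers(1, 30, size=rng.integers(2, 8))
            total = int(rng.integers(1, sizes.sum()))
            q = _largest_remainder_quotas(sizes, total)
            assert q.sum() == total and (q <= sizes).all() and (q >= 0).all()


def _family_fps(rng, sizes, n_bits=256):
    """Random fingerprints in loose families (shared core bits)."""
    ids, fps = [], []
    k = 0
    for fam, size in enumerate(sizes):
        core = rng.random(n_bits) < 0.15
        for _ in range(size):
            bits = (core | (rng.random(n_bits) < 0.05)).astype(np.uint8)
            ids.append(f"m{k:03d}")
            fps.append(cf.Fingerprint(bits=bits, radius=8, n_bits=n_bits))
            k += 1
    return ids, fps


def oracle_reduce(ids, fps, nm, height=4.5):
    """Independent re-implementation of the written selection rules."""
    dm = cf.tanimoto_distance_matrix(fps)
    tree = linkage(squareform(dm, checks=False), method="ward")
    labels = fcluster(tree, t=height, criterion="distance")
    nc = labels.max()

    def medoid_order(members):
        sums = [dm[i, members].sum() for i in members]
        return [m for _, _, m in sorted(zip(sums, [ids[m] for m in members], members))]

    if nc < nm:
        sizes = {c: (labels == c).sum() for c in range(1, nc + 1)}
        ideal = {c: sizes[c] * nm / len(ids) for c in sizes}
        quotas = {c: int(np.floor(ideal[c])) for c in sizes}
        left = nm - sum(quotas.values())
        for c in sorted(sizes, key=lambda c: (-(ideal[c] - quotas[c]), -sizes[c], c)):
            if left == 0:
                break
            if quotas[c] < sizes[c]:
                quotas[c] += 1
                left -= 1
        chosen = []
        for c in range(1, nc + 1):
            members = list(np.flatnonzero(labels == c))
            chosen += medoid_order(members)[: quotas[c]]
    else:
        if nc > nm:
            labels = fcluster(tree, t=nm, criterion="maxclust")
        chosen = [
            medoid_order(list(np.flatnonzero(labels == c)))[0]
            for c in range(1, labels.max() + 1)
        ]
    return sorted(ids[i] for i in chosen)


class TestReduceMajority:
    def test_selection_matches_independent_oracle(self):
        rng = np.random.default_rng(11)
        ids, fps = _family_fps(rng, sizes=(20, 15, 15))
        report = cf.reduce_majority(ids, fps, n_minority=20)
        assert report.selected_ids == oracle_reduce(ids, fps, 20)

    def test_exactly_nm_unique_members_selected(self):
        rng = np.random.default_rng(2)
        ids, fps = _family_fps(rng, sizes=(25, 25))
        for nm in (5, 10, 30, 49):
            report = cf.reduce_majority(ids, fps, n_minority=nm)
            assert len(report.selected_ids) == nm
            assert len(set(report.selected_ids)) == nm
            assert set(report.selected_ids) <= set(ids)
            assert report.branch in ("proportional", "centroid")

    def test_deterministic_across_reruns(self):
        rng = np.random.default_rng(3)
        ids, fps = _family_fps(rng, sizes=(30, 20))
        a = cf.reduce_majority(ids, fps, n_minority=12)
        b = cf.reduce_majority(ids, fps, n_minority=12)
        assert a.selected_ids == b.selected_ids and a.branch == b.branch

    def test_nm_not_smaller_than_majority_rejected(self):
        rng = np.random.default_rng(4)
        ids, fps = _family_fps(rng, sizes=(5,))
        with pytest.raises(ValueError):
            cf.reduce_majority(ids, fps, n_minority=5)

    def test_balance_holds_after_reduction(self, small_db):
        """Every processed cell line satisfies the 1.2 rule afterwards."""
        lookup = {
            cid: cf.morgan_fingerprint(smi, 8, 1024)
            for cid, smi in small_db.compounds.items()
        }
        processed = 0
        for cell, (sens, res) in small_db.per_cell_index.items():
            bal_s, bal_r, report = cf.balance_classes(
                sens, res, lookup, cell_line_id=cell
            )
            assert cf.is_balanced(
                max(len(bal_s), len(bal_r)), min(len(bal_s), len(bal_r))
            )
            if not report.balanced:
                processed += 1
                assert len(report.selected_ids) == report.n_minority
        assert processed >= 1  # the fixture does contain unbalanced cells


def _separable_toy(n_per_class=12, n_bits=64):
    X = np.zeros((2 * n_per_class, n_bits))
    X[:n_per_class, 0:10] = 1
    X[n_per_class:, 10:20] = 1
    rng = np.random.default_rng(0)
    X[:, 30:] = rng.integers(0, 2, size=(2 * n_per_class, n_bits - 30))
    y = np.array([SENSITIVE] * n_per_class + [RESISTANT] * n_per_class)
    return X, y


class TestCellSVM:
    def test_separable_patterns_reach_perfect_training_accuracy(self):
        X, y = _separable_toy()
        model = cf.train_cell_svm(X, y, grid={"C": [1.0, 10.0], "gamma": [0.05]})
        assert (model.model.predict(X) == y).all()

    def test_single_class_raises(self):
        X = np.ones((5, 8))
        with pytest.raises(cf.TrainingError):
            cf.train_cell_svm(X, np.array([SENSITIVE] * 5))

    def test_shuffled_labels_give_chance_level_internal_cv(self):
        X, y = _separable_toy(n_per_class=20)
        rng = np.random.default_rng(7)
        accs = []
        for _ in range(20):
            perm = rng.permutation(len(y))
            model = cf.train_cell_svm(
                X, y[perm], grid={"C": [1.0], "gamma": [0.05]}, seed=1
            )
            accs.append(model.cv_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_duplicated_rows_keep_selected_hyperparameters(self):
        X, y = _separable_toy()
        grid = {"C": [0.5, 1.0, 8.0], "gamma": [0.01, 0.1]}
        m1 = cf.train_cell_svm(X, y, grid=grid, seed=3)
        m2 = cf.train_cell_svm(
            np.vstack([X, X]), np.concatenate([y, y]), grid=grid, seed=3
        )
        assert (m1.C, m1.gamma) == (m2.C, m2.gamma)

    def test_prediction_of_training_compound_and_empty_fingerprint(self):
        X, y = _separable_toy()
        model = cf.train_cell_svm(
            X, y, grid={"C": [1.0], "gamma": [0.05]}, cell_line_id="A"
        )
        fp = cf.Fingerprint(bits=X[0].astype(np.uint8), radius=8, n_bits=64)
        pred = cf.predict_cell_svm(model, fp)
        assert pred.label == SENSITIVE and pred.method == "svm"
        empty = cf.Fingerprint(bits=np.zeros(64, dtype=np.uint8), radius=8, n_bits=64)
        assert cf.predict_cell_svm(model, empty).label in (SENSITIVE, RESISTANT)

    def test_batch_path_equals_one_by_one(self):
        X, y = _separable_toy()
        model = cf.train_cell_svm(X, y, grid={"C": [1.0], "gamma": [0.05]})
        batch = model.model.predict(X)
        singles = [
            cf.predict_cell_svm(
                model, cf.Fingerprint(bits=row.astype(np.uint8), radius=8, n_bits=64)
            ).label
            for row in X
        ]
        assert list(batch) == singles

    def test_fingerprint_length_mismatch_raises(self):
        X, y = _separable_toy()
        model = cf.train_cell_svm(X, y, grid={"C": [1.0], "gamma": [0.05]})
        wrong = cf.Fingerprint(bits=np.zeros(128, dtype=np.uint8), radius=8, n_bits=128)
        with pytest.raises(cf.DimensionError):
            cf.predict_cell_svm(model, wrong)
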