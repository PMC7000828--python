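import numpy as np
import pytest

from ugimem.chemistry import adduct_mz
from ugimem.codec import PresenceMatrix
from ugimem.detect import (
    MultiPeakReader,
    SinglePeakReader,
    evaluate_read,
    optimal_threshold,
    prune_features,
    rank_features_auroc,
    roc_curve,
    split_spots,
    validate_library,
)
from ugimem.specio import default_grid, resample_to_grid, snr_normalize
from ugimem.specsim import SimParams, simulate_plate


def brute_force_counts(scores, labels, tau):
    called = scores > tau
    tp = int((called & labels).sum())
    fp = int((called & ~labels).sum())
    fn = int((~called & labels).sum())
    tn = int((~called & ~labels).sum())
    return tp, fp, tn, fn


class TestROC:
    def test_counts_match_exhaustive_recount(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50).round(1)  # force some ties
        labels = rng.random(50) < 0.4
        curve = roc_curve(scores, labels)
        for i, tau in enumerate(curve.thresholds):
            tp, fp, tn, fn = brute_force_counts(scores, labels, tau)
            assert (curve.tp[i], curve.fp[i], curve.tn[i], curve.fn[i]) == \
                (tp, fp, tn, fn)

    def test_separable_data_has_a_perfect_operating_point(self):
        curve = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        perfect = (curve.tpr == 1) & (curve.fpr == 0)
        assert perfect.any()
        tau, dist = optimal_threshold(curve)
        assert dist == 0.0
        assert 2 < tau < 3

    def test_all_equal_scores_only_degenerate_points(self):
        curve = roc_curve([5.0] * 6, [0, 1, 0, 1, 0, 1])
        points = set(zip(curve.fpr.tolist(), curve.tpr.tolist()))
        assert points == {(0.0, 0.0), (1.0, 1.0)}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_curve([1.0, 2.0], [1, 1])

    def test_optimal_threshold_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1.2, 1, 40)])
        labels = np.concatenate([np.zeros(60, bool), np.ones(40, bool)])
        curve = roc_curve(scores, labels)
        tau, dist = optimal_threshold(curve)
        # independent scan over every candidate threshold
        best = None
        for cand in curve.thresholds:
            tp, fp, tn, fn = brute_force_counts(scores, labels, cand)
            d = np.hypot(fp / (fp + tn), 1 - tp / (tp + fn))
            if best is None or d < best[1] - 1e-12 or (
                abs(d - best[1]) <= 1e-12 and cand > best[0]
            ):
                best = (cand, d)
        assert tau == best[0]
        assert dist == pytest.approx(best[1])

    def test_reversed_labels_reflect_the_curve(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        c1 = roc_curve(scores, labels)
        c2 = roc_curve(scores, ~labels)
        np.testing.assert_allclose(c2.tpr, c1.fpr)
        np.testing.assert_allclose(c2.fpr, c1.tpr)


class TestFeatureRanking:
    def test_label_identical_feature_ranks_first(self):
        rng = np.random.default_rng(3)
        y = rng.random(60) < 0.5
        X = rng.normal(size=(60, 20))
        X[:, 7] = y.astype(float)
        top = rank_features_auroc(X, y, 5)
        assert top[0] == 7

    def test_anti_correlated_feature_also_ranks_first(self):
        rng = np.random.default_rng(4)
        y = rng.random(60) < 0.5
        X = rng.normal(size=(60, 20))
        X[:, 3] = 1.0 - y.astype(float)
        top = rank_features_auroc(X, y, 5)
        assert top[0] == 3

    def test_random_feature_ranks_behind_informative_one(self):
        rng = np.random.default_rng(5)
        y = rng.random(500) < 0.5
        X = rng.normal(size=(500, 2))
        X[:, 0] = y + rng.normal(0, 0.3, 500)
        top = rank_features_auroc(X, y, 2)
        assert top.tolist() == [0, 1]

    def test_prune_feature_contract(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (30, 50))  # mean ~0, below floor
        X[:, [4, 9, 13]] += 10.0
        keep = prune_features(X, max_features=10, snr_floor=3.0)
        assert keep.tolist() == [4, 9, 13]
        keep2 = prune_features(X, max_features=2, snr_floor=3.0)
        assert len(keep2) == 2 and set(keep2) <= {4, 9, 13}
        assert prune_features(rng.normal(0, 1, (30, 50)),
                              max_features=10).size == 0


class TestEvaluateRead:
    def test_exact_and_complement(self):
        truth = np.random.default_rng(7).integers(0, 2, (10, 6), dtype=np.uint8)
        perfect = evaluate_read(truth, truth)
        assert perfect.accuracy == 1.0
        assert perfect.n_errors == 0
        assert np.nansum(perfect.per_compound_fpr) == 0
        flipped = evaluate_read(1 - truth, truth)
        assert flipped.accuracy == 0.0

    def test_counts_match_hand_placed_flips(self):
        truth = np.zeros((4, 5), dtype=np.uint8)
        truth[:, 0] = 1
        pred = truth.copy()
        pred[0, 0] = 0  # one false negative, compound 0
        pred[2, 3] = 1  # one false positive, compound 3
        report = evaluate_read(pred, truth)
        assert report.n_errors == 2
        assert report.accuracy == 1 - 2 / 20
        assert report.per_compound_fnr[0] == 0.25
        assert report.per_compound_fpr[3] == 0.25
        assert report.errors_per_mixture.tolist()[:2] == [2, 2]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            evaluate_read(np.zeros((2, 3)), np.zeros((3, 2)))


class TestSinglePeakReader:
    def test_infinite_threshold_reads_all_absent(self):
        grid = default_grid(499.0, 501.0, 0.01)
        X = np.full((4, grid.size), 50.0)
        reader = SinglePeakReader(mz_grid=grid, target_mz=np.array([500.0]),
                                  threshold=np.inf)
        reader.fit(X, np.zeros((4, 1)))
        assert reader.predict(X).sum() == 0

    def test_learned_threshold_separates_training_classes(self):
        grid = default_grid(499.0, 501.0, 0.01)
        X = np.zeros((20, grid.size))
        y = (np.arange(20) % 2).reshape(-1, 1)
        i = np.searchsorted(grid, 500.0)
        X[y[:, 0] == 1, i] = 40.0
        X[y[:, 0] == 0, i] = 2.0
        reader = SinglePeakReader(mz_grid=grid, target_mz=np.array([500.0]))
        reader.fit(X, y)
        assert 2.0 < reader.thresholds_[0] < 40.0
        np.testing.assert_array_equal(reader.predict(X), y)

    def test_single_class_compound_falls_back_flagged(self):
        grid = default_grid(499.0, 501.0, 0.01)
        X = np.random.default_rng(8).random((10, grid.size))
        y = np.ones((10, 2), dtype=np.uint8)
        y[:, 1] = np.arange(10) % 2
        reader = SinglePeakReader(mz_grid=grid,
                                  target_mz=np.array([500.0, 500.5]))
        reader.fit(X, y)
        assert reader.fallback_[0] and not reader.fallback_[1]
        assert np.isfinite(reader.thresholds_).all()


class TestMultiPeakReader:
    def test_perfectly_informative_feature_gives_perfect_heldout(self):
        rng = np.random.default_rng(9)
        y = (rng.random(60) < 0.5).astype(np.uint8).reshape(-1, 1)
        X = rng.normal(0, 1, (60, 30))
        X[:, 12] = 5.0 + 10.0 * y[:, 0]  # above floor, label-separable
        reader = MultiPeakReader(method="logistic").fit(X[:40], y[:40])
        np.testing.assert_array_equal(reader.predict(X[40:]), y[40:])

    def test_shuffled_labels_give_chance_heldout_accuracy(self):
        rng = np.random.default_rng(10)
        y = (rng.random(200) < 0.5).astype(np.uint8)
        X = rng.normal(0, 1, (200, 40))
        X[:, 5] = 5.0 + 10.0 * y
        y_shuffled = rng.permutation(y).reshape(-1, 1)
        reader = MultiPeakReader(method="logistic").fit(
            X[:140], y_shuffled[:140]
        )
        acc = (reader.predict(X[140:]) == y_shuffled[140:]).mean()
        assert 0.3 < acc < 0.7

    def test_prediction_is_deterministic(self):
        rng = np.random.default_rng(11)
        y = (rng.random(50) < 0.5).astype(np.uint8).reshape(-1, 1)
        X = rng.normal(4, 1, (50, 25))
        reader = MultiPeakReader(method="forest", n_trees=30,
                                 random_state=0).fit(X, y)
        np.testing.assert_array_equal(reader.predict(X), reader.predict(X))

    def test_suppressed_adduct_recovered_via_correlated_complex_peak(self):
        """A compound whose own peaks are silent stays readable through a
        correlated satellite; thresholding its own m/z cannot see it."""
        rng = np.random.default_rng(12)
        grid = default_grid(499.0, 504.0, 0.01)
        n = 80
        y = (rng.random(n) < 0.5).astype(np.uint8).reshape(-1, 1)
        X = rng.normal(0, 1, (n, grid.size))
        # own sodiated peak at 500.0: fully suppressed (nothing added);
        # reagent-complex satellite at 503.0 follows the truth
        j = np.searchsorted(grid, 503.0)
        X[:, j] += 40.0 * y[:, 0]
        single = SinglePeakReader(mz_grid=grid, target_mz=np.array([500.0]))
        single.fit(X[:40], y[:40])
        multi = MultiPeakReader(method="logistic", snr_floor=3.0)
        multi.fit(X[:40], y[:40])
        acc_single = (single.predict(X[40:]) == y[40:]).mean()
        acc_multi = (multi.predict(X[40:]) == y[40:]).mean()
        assert acc_multi > acc_single
        assert acc_multi > 0.95


class TestSplit:
    def test_split_is_seeded_and_disjoint(self):
        tr1, te1 = split_spots(100, 0.3, seed=4)
        tr2, te2 = split_spots(100, 0.3, seed=4)
        np.testing.assert_array_equal(tr1, tr2)
        assert len(tr1) == 30
        assert not set(tr1) & set(te1)
        assert len(tr1) + len(te1) == 100


@pytest.fixture(scope="module")
def validation_plate(library):
    """One-product-per-well plate over the first 100 products."""
    n = 100
    indices = list(range(1, n + 1))
    matrix = PresenceMatrix(np.eye(n, dtype=np.uint8))
    params = SimParams(mz_min=430, mz_max=800, seed=11)
    spectra, _ = simulate_plate(matrix, library, params,
                                compound_indices=indices)
    snr = snr_normalize(resample_to_grid(spectra, params.grid()))
    return snr, indices


class TestLibraryValidation:
    def test_noiseless_validation_is_perfect(self, library):
        n = 40
        indices = list(range(1, n + 1))
        matrix = PresenceMatrix(np.eye(n, dtype=np.uint8))
        params = SimParams.noiseless(mz_min=430, mz_max=800)
        spectra, _ = simulate_plate(matrix, library, params,
                                    compound_indices=indices)
        snr = snr_normalize(resample_to_grid(spectra, params.grid()),
                            skip_degenerate=True)
        report = validate_library(snr, library, list(range(n)),
                                  product_indices=indices)
        assert report.tpr == 1.0
        assert report.fpr == 0.0
        assert report.detected_fraction == 1.0

    def test_failure_rate_shows_up_in_detected_fraction(self, validation_plate,
                                                        library):
        snr, indices = validation_plate
        report = validate_library(snr, library, list(range(len(indices))),
                                  product_indices=indices)
        # simulator injects 10% reaction failures; binomial 4-sigma band
        assert abs(report.detected_fraction - 0.9) < 4 * np.sqrt(0.09 / 100)
        assert report.fpr < 0.1
        assert report.tpr > 0.75

    def test_mass_degenerate_partner_counts_as_tp_never_fp(self, library):
        """Wells of exact-mass twins score as hits for either twin."""
        # products 31 and 87 (1-based 32, 88) are formula twins in the
        # packaged library; verify, then validate a noiseless plate of both
        from ugimem.chemistry import mass_collisions

        groups = mass_collisions(library, 5.0)
        pair = groups[0]
        # the twins plus one mass-distinct partner (so both ROC classes exist)
        distinct = next(
            i for i in range(len(library))
            if all(i not in g for g in groups)
            and abs(library[i].M - library[pair[0]].M) > 1.0
        )
        indices = [pair[0] + 1, pair[1] + 1, distinct + 1]
        matrix = PresenceMatrix(np.eye(3, dtype=np.uint8))
        params = SimParams.noiseless(mz_min=430, mz_max=800)
        spectra, _ = simulate_plate(matrix, library, params,
                                    compound_indices=indices)
        snr = snr_normalize(resample_to_grid(spectra, params.grid()),
                            skip_degenerate=True)
        report = validate_library(snr, library, [0, 1, 2],
                                  product_indices=indices)
        # each well sees the other twin's peak at the same m/z, but the
        # degeneracy rule books it as TP, not FP
        assert report.fpr == 0.0
        assert report.tpr == 1.0
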