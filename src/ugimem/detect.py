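"""Compound presence calling and readout scoring.

Two readout families are provided, both as scikit-learn style estimators
operating on SNR-transformed spectral matrices (rows = spots, columns =
m/z grid points):

* :class:`SinglePeakReader` — for each compound, the sodiated-peak SNR is
  thresholded. The threshold is chosen by ROC analysis of labeled
  training spots, minimizing the distance to the (FPR, TPR) = (0, 1)
  corner, sqrt(FPR^2 + (1 - TPR)^2).
* :class:`MultiPeakReader` — one supervised model per compound (logistic
  regression on the 64 most AUROC-informative of the pruned features, or
  a 300-tree random forest on up to 20,000 pruned features), exploiting
  isotopes, secondary adducts, reagent complexes, and suppression of
  other compounds.

Library validation scores a one-product-per-well plate with a single
global ROC threshold; mass-degenerate products (monoisotopic masses
within tolerance) count toward the expected product rather than as false
positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .chemistry import CompoundLibrary, adduct_mz, mass_collisions
from .codec import PresenceMatrix
from .specio import SpectralMatrix, peak_intensity

# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    """Exact confusion counts at every candidate threshold.

    Thresholds are midpoints between consecutive sorted unique scores
    plus -inf/+inf sentinels; an item scores positive when score > tau.
    """

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def tpr(self) -> np.ndarray:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> np.ndarray:
        return self.fp / (self.fp + self.tn)

    @property
    def corner_distance(self) -> np.ndarray:
        return np.sqrt(self.fpr**2 + (1.0 - self.tpr) ** 2)


def roc_curve(scores, labels) -> ROCCurve:
    """Build the exact ROC curve of a score/label sample."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    # counts via cumulative sums over the sorted unique scores
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # for each threshold: positives called = scores > tau
    pos_above = n_pos - np.concatenate(
        [[0], np.cumsum(l_sorted)[np.searchsorted(s_sorted, uniq, side="right") - 1]]
    )
    all_above = scores.size - np.concatenate(
        [[0], np.searchsorted(s_sorted, uniq, side="right")]
    )
    tp = pos_above.astype(np.int64)
    fp = (all_above - pos_above).astype(np.int64)
    return ROCCurve(
        thresholds=thresholds,
        tp=tp,
        fp=fp,
        tn=n_neg - fp,
        fn=n_pos - tp,
    )


def optimal_threshold(curve: ROCCurve) -> tuple[float, float]:
    """Corner-distance-minimizing threshold; ties go to the larger tau.

    Returns (tau, corner distance at tau).
    """
    d = curve.corner_distance
    best = d.min()
    idx = np.flatnonzero(d == best)[-1]
    return float(curve.thresholds[idx]), float(best)


def rank_features_auroc(X: np.ndarray, y, k: int) -> np.ndarray:
    """Top-k columns of X by |AUROC - 0.5| (descending).

    Anti-correlated features (AUROC < 0.5, e.g. suppression of other
    compounds) are as usable as positively correlated ones, so ranking is
    by distance from chance. AUROC is computed by the rank-sum identity.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # average ranks (ties averaged), column-wise
    order = np.argsort(X, axis=0, kind="stable")
    ranks = np.empty_like(X, dtype=np.float64)
    rows = np.arange(1, X.shape[0] + 1, dtype=np.float64)[:, None]
    np.put_along_axis(ranks, order, np.broadcast_to(rows, X.shape), axis=0)
    # fix ties: average rank within equal values
    Xs = np.take_along_axis(X, order, axis=0)
    for col in range(X.shape[1]):
        vals = Xs[:, col]
        ties = np.flatnonzero(vals[1:] == vals[:-1])
        if ties.size:
            # group consecutive equal values and average their ranks
            uniq, inv = np.unique(vals, return_inverse=True)
            sums = np.bincount(inv, weights=rows[:, 0])
            cnts = np.bincount(inv)
            avg = sums / cnts
            ranks[order[:, col], col] = avg[inv]
    rank_sum_pos = ranks[y].sum(axis=0)
    auc = (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    score = np.abs(auc - 0.5)
    top = np.argsort(-score, kind="stable")[:k]
    return top


def prune_features(
    matrix: SpectralMatrix | np.ndarray,
    max_features: int = 20000,
    snr_floor: float = 3.0,
) -> np.ndarray:
    """Grid columns worth keeping: mean SNR above the noise floor.

    If more than ``max_features`` survive, the top ``max_features`` by
    mean SNR are kept. Returned indices are sorted ascending; the result
    may be empty for an all-noise matrix.
    """
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    data = matrix.data if isinstance(matrix, SpectralMatrix) else np.asarray(matrix)
    means = data.mean(axis=0)
    keep = np.flatnonzero(means >= snr_floor)
    if keep.size > max_features:
        keep = keep[np.argsort(-means[keep], kind="stable")[:max_features]]
        keep = np.sort(keep)
    return keep


# ---------------------------------------------------------------------------
# Readers (sklearn-style estimators)
# ---------------------------------------------------------------------------


class SinglePeakReader(BaseEstimator, ClassifierMixin):
    """Threshold the sodiated-peak SNR of each compound.

    Parameters
    ----------
    mz_grid : ndarray
        Common m/z grid of the spectral matrix rows given to fit/predict.
    target_mz : ndarray
        Per-compound sodiated adduct m/z values.
    tol_ppm : float
        Half-width of the peak lookup window.
    threshold : float or None
        Fixed global threshold; if None, per-compound thresholds are
        learned from the training labels by corner-distance ROC analysis.

    Attributes
    ----------
    thresholds_ : ndarray of shape (n_compounds,)
    corner_distances_ : ndarray
    fallback_ : ndarray of bool — compounds whose training labels were
        single-class (threshold fell back to the global median).
    """

    def __init__(self, mz_grid=None, target_mz=None, tol_ppm: float = 15.0,
                 threshold: float | None = None):
        self.mz_grid = mz_grid
        self.target_mz = target_mz
        self.tol_ppm = tol_ppm
        self.threshold = threshold

    def _scores(self, X: np.ndarray) -> np.ndarray:
        mat = SpectralMatrix(grid=self.mz_grid, data=X)
        return np.column_stack([
            peak_intensity(mat, mz, self.tol_ppm) for mz in self.target_mz
        ])

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("y must be (n_spots, n_compounds)")
        scores = self._scores(X)
        n_comp = y.shape[1]
        self.thresholds_ = np.empty(n_comp)
        self.corner_distances_ = np.empty(n_comp)
        self.fallback_ = np.zeros(n_comp, dtype=bool)
        if self.threshold is not None:
            self.thresholds_[:] = self.threshold
            self.corner_distances_[:] = np.nan
            return self
        for m in range(n_comp):
            col = y[:, m].astype(bool)
            if col.all() or not col.any():
                self.fallback_[m] = True
                self.thresholds_[m] = np.nan  # fill after the loop
                self.corner_distances_[m] = np.nan
                continue
            curve = roc_curve(scores[:, m], col)
            tau, dist = optimal_threshold(curve)
            self.thresholds_[m] = tau
            self.corner_distances_[m] = dist
        if self.fallback_.any():
            fill = (np.nanmedian(self.thresholds_)
                    if not self.fallback_.all() else np.median(scores))
            self.thresholds_[self.fallback_] = fill
        return self

    def predict(self, X) -> np.ndarray:
        scores = self._scores(np.asarray(X))
        return (scores > self.thresholds_[None, :]).astype(np.uint8)


class MultiPeakReader(BaseEstimator, ClassifierMixin):
    """Per-compound supervised presence classifiers on spectral features.

    method="logistic": shared noise-floor pruning, then the 64 (default)
    most AUROC-informative features per compound, then L2 logistic
    regression. method="forest": pruning to at most ``max_candidates``
    features, then a 300-tree random forest of unlimited depth (the
    forest does its own feature selection).

    Compounds whose training labels are single-class fall back to a
    constant predictor and are flagged in ``fallback_``.
    """

    def __init__(self, method: str = "logistic", n_features: int = 64,
                 max_candidates: int = 20000, snr_floor: float = 3.0,
                 n_trees: int = 300, random_state: int = 0):
        self.method = method
        self.n_features = n_features
        self.max_candidates = max_candidates
        self.snr_floor = snr_floor
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        if self.method not in ("logistic", "forest"):
            raise ValueError(f"unknown method {self.method!r}")
        X = np.asarray(X)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("y must be (n_spots, n_compounds)")
        self.candidate_columns_ = prune_features(
            X, max_features=self.max_candidates, snr_floor=self.snr_floor
        )
        Xc = X[:, self.candidate_columns_]
        n_comp = y.shape[1]
        self.models_ = []
        self.feature_columns_ = []
        self.fallback_ = np.zeros(n_comp, dtype=bool)
        self.constants_ = np.zeros(n_comp, dtype=np.uint8)
        for m in range(n_comp):
            col = y[:, m].astype(bool)
            if col.all() or not col.any():
                self.fallback_[m] = True
                self.constants_[m] = int(col.any())
                self.models_.append(None)
                self.feature_columns_.append(np.empty(0, dtype=int))
                continue
            if self.method == "logistic" and Xc.shape[1] > 0:
                # guard against selection overfit on small training plates:
                # never use more features than half the training spots
                k = min(self.n_features, max(1, Xc.shape[0] // 2))
                feats = rank_features_auroc(Xc, col, k)
                model = LogisticRegression(max_iter=2000, C=1.0)
            else:
                feats = np.arange(Xc.shape[1])
                model = RandomForestClassifier(
                    n_estimators=self.n_trees, max_depth=None,
                    random_state=self.random_state,
                )
            if feats.size == 0:
                self.fallback_[m] = True
                self.constants_[m] = int(col.mean() >= 0.5)
                self.models_.append(None)
                self.feature_columns_.append(feats)
                continue
            model.fit(Xc[:, feats], col.astype(int))
            self.models_.append(model)
            self.feature_columns_.append(feats)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.shape[1] < (self.candidate_columns_.max(initial=-1) + 1):
            raise ValueError("grid mismatch: fewer columns than at fit time")
        Xc = X[:, self.candidate_columns_]
        out = np.empty((X.shape[0], len(self.models_)), dtype=np.uint8)
        for m, model in enumerate(self.models_):
            if model is None:
                out[:, m] = self.constants_[m]
            else:
                out[:, m] = model.predict(Xc[:, self.feature_columns_[m]])
        return out


def split_spots(
    n_spots: int, train_fraction: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform train/test split of spot indices."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_spots)
    n_train = max(1, int(round(train_fraction * n_spots)))
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def train_classifiers(
    matrix: SpectralMatrix,
    truth: PresenceMatrix | np.ndarray,
    method: str = "logistic",
    train_fraction: float = 0.3,
    seed: int = 0,
    **reader_kwargs,
) -> tuple[MultiPeakReader, dict]:
    """Fit a MultiPeakReader on a seeded train split; report held-out metrics."""
    y = truth.data if isinstance(truth, PresenceMatrix) else np.asarray(truth)
    train, test = split_spots(matrix.n_spots, train_fraction, seed)
    reader = MultiPeakReader(method=method, random_state=seed, **reader_kwargs)
    reader.fit(matrix.data[train], y[train])
    report = evaluate_read(reader.predict(matrix.data[test]), y[test])
    return reader, {"train_spots": train, "test_spots": test,
                    "held_out": report}


def single_peak_read(
    matrix: SpectralMatrix,
    target_mz: np.ndarray,
    thresholds: np.ndarray | float,
    tol_ppm: float = 15.0,
) -> PresenceMatrix:
    """Threshold sodiated-peak SNRs with given per-compound thresholds."""
    thresholds = np.broadcast_to(np.asarray(thresholds, dtype=float),
                                 (len(target_mz),))
    scores = np.column_stack([
        peak_intensity(matrix, mz, tol_ppm) for mz in target_mz
    ])
    return PresenceMatrix(data=(scores > thresholds[None, :]).astype(np.uint8))


def multi_peak_read(reader: MultiPeakReader, matrix: SpectralMatrix) -> PresenceMatrix:
    return PresenceMatrix(data=reader.predict(matrix.data))


# ---------------------------------------------------------------------------
# Scoring and library validation
# ---------------------------------------------------------------------------


@dataclass
class ReadReport:
    """Cell-exact comparison of a predicted presence matrix to truth."""

    accuracy: float
    per_compound_fpr: np.ndarray
    per_compound_fnr: np.ndarray
    errors_per_mixture: np.ndarray  # histogram: index k = #mixtures with k errors
    n_errors: int
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_errors": self.n_errors,
            "n_cells": self.n_cells,
            "per_compound_fpr": self.per_compound_fpr.tolist(),
            "per_compound_fnr": self.per_compound_fnr.tolist(),
            "errors_per_mixture": self.errors_per_mixture.tolist(),
        }


def evaluate_read(predicted, truth) -> ReadReport:
    pred = predicted.data if isinstance(predicted, PresenceMatrix) else np.asarray(predicted)
    true = truth.data if isinstance(truth, PresenceMatrix) else np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    errors = pred != true
    with np.errstate(invalid="ignore"):
        fp = ((pred == 1) & (true == 0)).sum(axis=0)
        tn = ((pred == 0) & (true == 0)).sum(axis=0)
        fn = ((pred == 0) & (true == 1)).sum(axis=0)
        tp = ((pred == 1) & (true == 1)).sum(axis=0)
        fpr = np.where(fp + tn > 0, fp / np.maximum(fp + tn, 1), np.nan)
        fnr = np.where(fn + tp > 0, fn / np.maximum(fn + tp, 1), np.nan)
    per_row = errors.sum(axis=1)
    hist = np.bincount(per_row, minlength=true.shape[1] + 1)
    n_err = int(errors.sum())
    return ReadReport(
        accuracy=1.0 - n_err / errors.size,
        per_compound_fpr=fpr,
        per_compound_fnr=fnr,
        errors_per_mixture=hist,
        n_errors=n_err,
        n_cells=int(errors.size),
    )


@dataclass
class LibraryValidationReport:
    """Global ROC validation of a one-product-per-well library plate."""

    tau: float
    tpr: float
    fpr: float
    detected_fraction: float
    detected: np.ndarray  # per-well, expected product detected at tau
    snr: np.ndarray  # (n_wells, n_products) sodiated-peak SNR map
    corner_distance: float


def validate_library(
    matrix: SpectralMatrix,
    library: CompoundLibrary,
    expected: dict[int, int] | list[int],
    product_indices: list[int] | None = None,
    tol_ppm: float = 15.0,
    collision_tol_ppm: float = 5.0,
) -> LibraryValidationReport:
    """Score a library plate where well w should contain one product.

    ``expected`` maps well row -> expected product (0-based positions in
    ``product_indices``, which defaults to the whole library). Detection
    of a product whose monoisotopic mass overlaps the expected product's
    (within ``collision_tol_ppm``) counts as a true positive / false
    negative for the well, never as a false positive.
    """
    if product_indices is None:
        product_indices = list(range(1, len(library) + 1))
    products = [library[i - 1] for i in product_indices]
    if isinstance(expected, dict):
        expected_arr = np.array([expected[w] for w in range(matrix.n_spots)])
    else:
        expected_arr = np.asarray(expected)
    if expected_arr.size != matrix.n_spots:
        raise ValueError("need exactly one expected product per well")
    masses = [p.M for p in products]
    groups = mass_collisions(masses, tol_ppm=collision_tol_ppm)
    group_of = np.arange(len(products))
    for g in groups:
        for i in g:
            group_of[i] = g[0]
    snr = np.column_stack([
        peak_intensity(matrix, adduct_mz(p.M, "Na"), tol_ppm) for p in products
    ])
    # label (well, product) = 1 iff the product is mass-degenerate with
    # (or is) the well's expected product
    labels = group_of[None, :] == group_of[expected_arr][:, None]
    curve = roc_curve(snr.reshape(-1), labels.reshape(-1))
    tau, dist = optimal_threshold(curve)
    called = snr > tau
    tp = int((called & labels).sum())
    fn = int((~called & labels).sum())
    fp = int((called & ~labels).sum())
    tn = int((~called & ~labels).sum())
    detected = called[np.arange(matrix.n_spots), expected_arr]
    return LibraryValidationReport(
        tau=tau,
        tpr=tp / (tp + fn),
        fpr=fp / (fp + tn),
        detected_fraction=float(detected.mean()),
        detected=detected,
        snr=snr,
        corner_distance=dist,
    )
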