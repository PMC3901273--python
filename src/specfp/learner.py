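"""Per-bit kernel SVM learning of fingerprints from spectra.

One soft-margin SVM is trained per effective fingerprint bit on a
precomputed spectrum-kernel Gram matrix; the decision function for bit j
on a query spectrum chi is

    f_j(chi) = sum_i alpha_ij * y_ij * K(chi_i, chi) + b_j

with the predicted bit its sign (0 mapped to +1).  The soft-margin cost
C is selected per bit by inner molecule-grouped cross-validation over a
geometric grid (2^-5 ... 2^10 by default).

Cross-validation folds are molecule-grouped: all spectra of a molecule
share a fold, otherwise replicate spectra of one molecule on both sides
of a split would inflate accuracy.  The outer-CV per-bit accuracies are
the reliability scores w_j consumed by Poisson-binomial candidate
scoring downstream.

:class:`FingerprintPredictor` packages the whole procedure as a
scikit-learn estimator (fit on spectra + fingerprint labels, predict
fingerprint vectors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .constants import DEFAULT_C_GRID
from .fingerprints import EffectiveBitMask, FingerprintVector, apply_mask, effective_bit_mask
from .kernels import ProbabilityProductKernel, gram_matrix
from .spectra import Spectrum

__all__ = [
    "FoldAssignment",
    "BitModel",
    "make_grouped_folds",
    "grouped_fold_labels",
    "train_bit_svm",
    "select_C",
    "cross_validated_reliability",
    "FingerprintPredictor",
    "predict_fingerprints",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Molecule-grouped fold assignment of spectra."""

    fold_of_spectrum: dict
    k: int
    seed: int

    def labels(self, spectrum_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.fold_of_spectrum[sid] for sid in spectrum_ids])


def _deal_groups(groups: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign each sample a fold 0..k-1 such that no group spans folds.

    Groups are shuffled with the seed, then dealt largest-first to the
    currently lightest fold (ties toward the lowest fold index), which
    keeps per-fold sample counts within one group size of each other.
    """
    uniq = np.array(sorted(set(groups.tolist())), dtype=object)
    if uniq.size < k:
        raise ValueError(f"need at least k={k} groups, got {uniq.size}")
    rng = np.random.default_rng(seed)
    shuffled = uniq[rng.permutation(uniq.size)]
    sizes = {g: int(np.sum(groups == g)) for g in uniq}
    order = sorted(range(shuffled.size), key=lambda i: -sizes[shuffled[i]])
    loads = np.zeros(k, dtype=int)
    fold_of_group: dict = {}
    for i in order:
        g = shuffled[i]
        f = int(np.argmin(loads))  # argmin takes the lowest index on ties
        fold_of_group[g] = f
        loads[f] += sizes[g]
    return np.array([fold_of_group[g] for g in groups])


def make_grouped_folds(
    molecule_of_spectrum: Mapping[str, str], k: int, seed: int
) -> FoldAssignment:
    """Build a k-fold assignment keeping each molecule's spectra together."""
    if k < 2:
        raise ValueError("k must be at least 2")
    sids = list(molecule_of_spectrum.keys())
    groups = np.array([molecule_of_spectrum[s] for s in sids], dtype=object)
    folds = _deal_groups(groups, k, seed)
    return FoldAssignment(dict(zip(sids, (int(f) for f in folds))), k, seed)


def grouped_fold_labels(groups: Sequence, k: int, seed: int) -> np.ndarray:
    """Array form of :func:`make_grouped_folds` for positional data."""
    return _deal_groups(np.asarray(groups, dtype=object), k, seed)


@dataclass
class BitModel:
    """Trained (or constant) predictor for one fingerprint bit.

    For trained bits, ``alpha_y[i]`` holds alpha_i * y_i for support
    vector ``support[i]`` (indices into the training spectrum list), so
    the decision value on a query is ``K[query, support] @ alpha_y +
    bias``.  Bits whose training labels are single-class are stored as
    constant predictors instead.
    """

    bit_index: int
    constant: int | None = None
    alpha_y: np.ndarray | None = None
    support: np.ndarray | None = None
    bias: float = 0.0
    C: float | None = None

    def decision(self, K: np.ndarray) -> np.ndarray:
        """Decision values for queries; K is (n_query, n_train)."""
        if self.constant is not None:
            return np.full(K.shape[0], float(self.constant))
        return K[:, self.support] @ self.alpha_y + self.bias

    def predict(self, K: np.ndarray) -> np.ndarray:
        """Predicted +/-1 bits; a zero decision value maps to +1."""
        if self.constant is not None:
            return np.full(K.shape[0], self.constant, dtype=np.int8)
        return np.where(self.decision(K) >= 0, 1, -1).astype(np.int8)


def train_bit_svm(
    K: np.ndarray, labels: np.ndarray, C: float, bit_index: int = 0, tol: float = 1e-4
) -> BitModel:
    """Fit one soft-margin SVM on a precomputed Gram matrix.

    Single-class label vectors yield a constant model without touching
    the optimiser.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size == 1:
        return BitModel(bit_index=bit_index, constant=int(classes[0]))
    svc = SVC(C=C, kernel="precomputed", tol=tol, shrinking=True)
    svc.fit(K, y)
    return BitModel(
        bit_index=bit_index,
        alpha_y=svc.dual_coef_[0].copy(),
        support=svc.support_.copy(),
        bias=float(svc.intercept_[0]),
        C=float(C),
    )


def select_C(
    K: np.ndarray,
    labels: np.ndarray,
    groups: Sequence,
    grid: Sequence[float] = DEFAULT_C_GRID,
    inner_k: int = 5,
    seed: int = 0,
) -> float:
    """Pick the cost maximising inner grouped-CV accuracy (ties: smaller C).

    The inner folds are molecule-grouped like the outer ones; when fewer
    groups than ``inner_k`` exist the fold count shrinks to the group
    count.
    """
    grid = sorted(set(float(c) for c in grid))
    if not grid:
        raise ValueError("C grid must be non-empty")
    if len(grid) == 1:
        return grid[0]
    y = np.asarray(labels)
    if np.unique(y).size == 1:
        return grid[0]
    groups = np.asarray(groups, dtype=object)
    k = min(inner_k, np.unique(groups).size)
    if k < 2:
        return grid[0]
    folds = _deal_groups(groups, k, seed)
    best_c, best_acc = grid[0], -1.0
    for c in grid:
        correct = 0
        for f in range(k):
            test = folds == f
            train = ~test
            model = train_bit_svm(K[np.ix_(train, train)], y[train], c)
            pred = model.predict(K[np.ix_(test, train)])
            correct += int(np.sum(pred == y[test]))
        acc = correct / y.size
        if acc > best_acc + 1e-12:
            best_acc, best_c = acc, c
    return best_c


def cross_validated_reliability(
    K: np.ndarray,
    Y: np.ndarray,
    fold_labels: np.ndarray,
    groups: Sequence,
    grid: Sequence[float] = DEFAULT_C_GRID,
    inner_k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Outer-CV accuracies w_j of every fingerprint bit.

    For each outer fold, per-bit models (with inner-CV C selection) are
    trained on the complement and evaluated on the held-out spectra; w_j
    is the overall fraction of held-out spectra whose bit j was
    predicted correctly.  Bits that could never be evaluated fall back
    to the uninformative value 0.5.
    """
    Y = np.asarray(Y)
    n, m = Y.shape
    groups = np.asarray(groups, dtype=object)
    correct = np.zeros(m)
    counted = np.zeros(m)
    for f in sorted(set(int(x) for x in fold_labels)):
        test = fold_labels == f
        train = ~test
        if not np.any(test) or not np.any(train):
            continue
        K_tr = K[np.ix_(train, train)]
        K_te = K[np.ix_(test, train)]
        g_tr = groups[train]
        for j in range(m):
            y_tr = Y[train, j]
            c = select_C(K_tr, y_tr, g_tr, grid, inner_k, seed)
            model = train_bit_svm(K_tr, y_tr, c, bit_index=j)
            pred = model.predict(K_te)
            correct[j] += int(np.sum(pred == Y[test, j]))
            counted[j] += int(np.sum(test))
    w = np.where(counted > 0, correct / np.maximum(counted, 1), 0.5)
    return w


class FingerprintPredictor(ClassifierMixin, BaseEstimator):
    """Spectrum-to-fingerprint multilabel classifier.

    ``fit`` takes a list of training :class:`~specfp.spectra.Spectrum`
    objects and their +/-1 fingerprint matrix, masks uninformative bits,
    runs molecule-grouped outer CV to obtain per-bit reliability scores,
    then trains final per-bit SVMs on all data.  ``predict`` returns
    full-length +/-1 fingerprint matrices (masked bits report their
    constant training value).

    Parameters
    ----------
    sigma_mass, sigma_intensity, variants, normalize:
        Probability-product-kernel settings (see
        :class:`~specfp.kernels.ProbabilityProductKernel`).
    k_folds:
        Outer molecule-grouped CV folds for reliability estimation
        (shrinks to the molecule count when that is smaller).
    inner_folds:
        Inner grouped folds for per-bit C selection.
    c_grid:
        Candidate soft-margin costs.
    random_state:
        Seed for all fold shuffling.

    Attributes
    ----------
    mask_ : EffectiveBitMask
    reliability_ : ndarray of shape (m_effective,)
    bit_models_ : list of BitModel (one per effective bit)
    kernel_ : fitted ProbabilityProductKernel
    training_spectra_ : list of Spectrum
    key_names_ : tuple of bit names
    """

    def __init__(
        self,
        sigma_mass: float = 0.01,
        sigma_intensity: float = 0.05,
        variants: tuple[str, ...] = ("peaks", "mloss"),
        normalize: bool = True,
        k_folds: int = 10,
        inner_folds: int = 5,
        c_grid: tuple[float, ...] = DEFAULT_C_GRID,
        random_state: int = 0,
    ):
        self.sigma_mass = sigma_mass
        self.sigma_intensity = sigma_intensity
        self.variants = variants
        self.normalize = normalize
        self.k_folds = k_folds
        self.inner_folds = inner_folds
        self.c_grid = c_grid
        self.random_state = random_state

    # -- helpers -----------------------------------------------------
    @staticmethod
    def _label_matrix(Y, key_names=None):
        if isinstance(Y, np.ndarray):
            mat = np.asarray(Y, dtype=np.int8)
            names = tuple(key_names) if key_names else tuple(
                f"bit:{j}" for j in range(mat.shape[1])
            )
        else:
            mat = np.stack([fp.bits for fp in Y]).astype(np.int8)
            names = tuple(Y[0].key_names)
        if not np.all(np.isin(mat, (-1, 1))):
            raise ValueError("fingerprint labels must be +1/-1")
        return mat, names

    def fit(self, X: Sequence[Spectrum], Y, groups: Sequence | None = None,
            key_names: Sequence[str] | None = None):
        X = list(X)
        Y_full, self.key_names_ = self._label_matrix(Y, key_names)
        if len(X) != Y_full.shape[0]:
            raise ValueError("number of spectra and fingerprint rows differ")
        if groups is None:
            groups = [s.molecule_id for s in X]
            if any(g is None for g in groups):
                raise ValueError(
                    "training spectra need molecule_id (or pass groups=) for "
                    "molecule-grouped cross-validation"
                )
        groups = np.asarray(groups, dtype=object)
        n_molecules = np.unique(groups).size
        if n_molecules < 2:
            raise ValueError("need spectra of at least 2 distinct molecules")

        self.mask_ = effective_bit_mask(Y_full)
        Y_eff = apply_mask(self.mask_, Y_full)

        self.kernel_ = ProbabilityProductKernel(
            sigma_mass=self.sigma_mass,
            sigma_intensity=self.sigma_intensity,
            variants=tuple(self.variants),
            normalize=self.normalize,
        )
        K = self.kernel_.fit_transform(X)

        k = min(self.k_folds, n_molecules)
        fold_labels = _deal_groups(groups, k, self.random_state)
        self.fold_labels_ = fold_labels
        self.groups_ = groups
        self.reliability_ = cross_validated_reliability(
            K, Y_eff, fold_labels, groups, self.c_grid, self.inner_folds,
            self.random_state,
        )
        self.bit_models_ = []
        for j in range(Y_eff.shape[1]):
            c = select_C(K, Y_eff[:, j], groups, self.c_grid, self.inner_folds,
                         self.random_state)
            self.bit_models_.append(train_bit_svm(K, Y_eff[:, j], c, bit_index=j))
        self.training_spectra_ = X
        self.train_gram_ = K
        return self

    def decision_function(self, X: Sequence[Spectrum]) -> np.ndarray:
        """Per-effective-bit SVM decision values, shape (n, m_effective)."""
        K = self.kernel_.transform(list(X))
        return np.column_stack([bm.decision(K) for bm in self.bit_models_])

    def predict_effective(self, X: Sequence[Spectrum]) -> np.ndarray:
        """+/-1 predictions restricted to the effective bits."""
        X = list(X)
        if self.bit_models_ and all(bm.constant is not None for bm in self.bit_models_):
            consts = np.array([bm.constant for bm in self.bit_models_], dtype=np.int8)
            return np.tile(consts, (len(X), 1))  # no kernel evaluation needed
        K = self.kernel_.transform(X)
        return np.column_stack([bm.predict(K) for bm in self.bit_models_])

    def predict(self, X: Sequence[Spectrum]) -> np.ndarray:
        """Full-length +/-1 fingerprint matrix for query spectra."""
        eff = self.predict_effective(X)
        out = np.tile(self.mask_.constants, (eff.shape[0], 1)).astype(np.int8)
        out[:, self.mask_.keep] = eff
        return out

    def score(self, X, Y, sample_weight=None) -> float:
        """Mean per-bit accuracy over the effective bits."""
        Y_full, _ = self._label_matrix(Y, self.key_names_)
        pred = self.predict_effective(X)
        truth = apply_mask(self.mask_, Y_full)
        return float(np.mean(pred == truth))


def predict_fingerprints(model: FingerprintPredictor, query: Spectrum) -> FingerprintVector:
    """Predict the full fingerprint vector of a single query spectrum."""
    bits = model.predict([query])[0]
    return FingerprintVector(bits=bits, key_names=model.key_names_, source="predicted")
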