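"""Reproducible evaluation experiments on synthetic worlds.

These routines run the full pipeline on toy worlds with known ground
truth and summarise its behaviour: retrieval quality as a function of
fingerprint-prediction reliability, learning curves over training-set
size, and the effect of pooling spectra from several collision energies
into one model.  They are used both by the acceptance test-suite and by
the reproduction script.
"""

from __future__ import annotations

import math

import numpy as np

from .kernels import gram_matrix
from .learner import grouped_fold_labels, select_C, train_bit_svm
from .retrieval import rank_candidates
from .synthetic import corrupt_fingerprints, generate_toy_world, relative_rank

__all__ = ["retrieval_recovery", "learning_curve", "mixed_energy_benefit"]


def retrieval_recovery(
    n_candidates: int = 200,
    m_bits: int = 20,
    w_levels: tuple[float, ...] = (0.6, 0.8, 0.95, 1.0),
    n_replicates: int = 200,
    seed: int = 0,
) -> dict[float, dict[str, float]]:
    """Rank recovery of the true molecule under controlled bit reliability.

    A database of ``n_candidates`` molecules with distinct fingerprints
    is generated; in each replicate the true molecule's fingerprint is
    corrupted at uniform reliability w and the database is ranked by the
    Poisson-binomial score.  Returns per-w mean rank, mean relative rank
    and the fraction of replicates ranking the true molecule first.
    """
    world = generate_toy_world(
        n_molecules=n_candidates, m_bits=m_bits, seed=seed, n_energies=1,
        unique_fingerprints=True,
    )
    base = np.random.default_rng(seed)
    pick = base.integers(0, n_candidates, size=n_replicates)
    rep_seeds = base.integers(0, 2**31 - 1, size=(len(w_levels), n_replicates))
    out: dict[float, dict[str, float]] = {}
    for wi, w in enumerate(w_levels):
        ranks = []
        for rep in range(n_replicates):
            mol = world.molecules[int(pick[rep])]
            y_hat = corrupt_fingerprints(
                mol.fingerprint.bits, w, seed=int(rep_seeds[wi, rep])
            )
            result = rank_candidates(
                world.molecules, y_hat, np.full(m_bits, w), query_id=mol.molecule_id
            )
            ranks.append(result.rank_of(mol.molecule_id))
        ranks_arr = np.asarray(ranks, dtype=float)
        out[w] = {
            "mean_rank": float(ranks_arr.mean()),
            "mean_relative_rank": float(ranks_arr.mean() / n_candidates),
            "top1_rate": float(np.mean(ranks_arr == 1)),
        }
    return out


def learning_curve(
    n_molecules: int = 100,
    m_bits: int = 20,
    fractions: tuple[float, ...] = (0.2, 0.6, 1.0),
    k_folds: int = 10,
    seed: int = 0,
    c_grid: tuple[float, ...] = (0.25, 1.0, 4.0),
    inner_k: int = 3,
    n_energies: int = 2,
) -> dict[float, dict[str, float]]:
    """Molecule-grouped CV error and retrieval rank vs training-set size.

    For each outer fold and each training fraction, the training pool
    (all molecules outside the fold) is sub-sampled to the fraction —
    subsets are nested across fractions — per-bit SVMs are trained
    (cost selected by inner grouped CV) and the held-out spectra's bits
    predicted.  Per fraction, the aggregated CV accuracies serve as the
    reliability scores for ranking every held-out spectrum against the
    full candidate set.
    """
    world = generate_toy_world(
        n_molecules=n_molecules, m_bits=m_bits, seed=seed, n_energies=n_energies
    )
    spectra = world.spectra
    groups = np.array([s.molecule_id for s in spectra], dtype=object)
    Y = np.stack([world.fingerprint_of(str(g)).bits for g in groups])
    n, m = Y.shape
    K = gram_matrix(spectra).values
    fold_labels = grouped_fold_labels(groups, k_folds, seed)

    # nested training subsets: one permutation of each fold's training pool
    pool_order = {}
    for f in range(k_folds):
        pool = sorted(set(groups[fold_labels != f]))
        perm = np.random.default_rng(seed + 1000 + f).permutation(len(pool))
        pool_order[f] = [pool[i] for i in perm]

    out: dict[float, dict[str, float]] = {}
    for frac in fractions:
        preds = np.zeros_like(Y)
        for f in range(k_folds):
            test = fold_labels == f
            n_take = max(2, math.ceil(frac * len(pool_order[f])))
            chosen = set(pool_order[f][:n_take])
            train = np.array([g in chosen for g in groups])
            K_tr = K[np.ix_(train, train)]
            K_te = K[np.ix_(test, train)]
            g_tr = groups[train]
            for j in range(m):
                c = select_C(K_tr, Y[train, j], g_tr, c_grid, inner_k, seed)
                model = train_bit_svm(K_tr, Y[train, j], c, bit_index=j)
                preds[test, j] = model.predict(K_te)
        bit_error = float(np.mean(preds != Y))
        w = np.mean(preds == Y, axis=0)
        rel = [
            relative_rank(
                rank_candidates(world.molecules, preds[i], w, query_id=str(groups[i])),
                str(groups[i]),
            )
            for i in range(n)
        ]
        out[frac] = {
            "cv_bit_error": bit_error,
            "mean_relative_rank": float(np.mean(rel)),
        }
    return out


def mixed_energy_benefit(
    n_molecules: int = 40,
    m_bits: int = 20,
    n_seeds: int = 5,
    seed: int = 0,
    c_grid: tuple[float, ...] = (0.25, 1.0, 4.0),
    inner_k: int = 3,
) -> dict[str, object]:
    """Pooled-energy vs single-energy training on a fixed held-out split.

    Per seed: a world with 3 collision energies is generated; one fifth
    of the molecules are held out and their energy-0 spectra form the
    test set.  Two models are trained on the remaining molecules — one
    on energy-0 spectra only, one on all energies pooled — and compared
    by mean per-bit accuracy on the same test spectra.
    """
    singles, pooleds = [], []
    for s in range(n_seeds):
        world = generate_toy_world(
            n_molecules=n_molecules, m_bits=m_bits, seed=seed + s, n_energies=3
        )
        spectra = world.spectra
        groups = np.array([sp.molecule_id for sp in spectra], dtype=object)
        energy = np.array([sp.instrument_tag for sp in spectra])
        Y = np.stack([world.fingerprint_of(str(g)).bits for g in groups])
        K = gram_matrix(spectra).values

        mols = sorted({m.molecule_id for m in world.molecules})
        perm = np.random.default_rng(seed + s).permutation(len(mols))
        n_test = max(2, len(mols) // 5)
        test_mols = {mols[i] for i in perm[:n_test]}
        test = np.array([g in test_mols for g in groups]) & (energy == "TOY-ENERGY0")

        def accuracy(train_mask):
            correct = 0
            for j in range(Y.shape[1]):
                K_tr = K[np.ix_(train_mask, train_mask)]
                c = select_C(K_tr, Y[train_mask, j], groups[train_mask], c_grid, inner_k,
                             seed + s)
                model = train_bit_svm(K_tr, Y[train_mask, j], c, bit_index=j)
                pred = model.predict(K[np.ix_(test, train_mask)])
                correct += int(np.sum(pred == Y[test, j]))
            return correct / (int(np.sum(test)) * Y.shape[1])

        train_mols_mask = np.array([g not in test_mols for g in groups])
        singles.append(accuracy(train_mols_mask & (energy == "TOY-ENERGY0")))
        pooleds.append(accuracy(train_mols_mask))
    return {
        "single_energy_accuracy": singles,
        "pooled_energy_accuracy": pooleds,
        "mean_single": float(np.mean(singles)),
        "mean_pooled": float(np.mean(pooleds)),
    }
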