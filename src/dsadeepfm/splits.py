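"""Cross-validation split plans for the four evaluation regimes.

All regimes keep an unordered drug pair and its order-swapped duplicate in
the same partition by splitting over canonical triplet keys.  Five folds
realize the 3:1:1 train/validation/test ratio: per fold one fifth is the
test set, the next fifth the validation set, the remaining three fifths the
training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TripletDataset

REGIMES = ("random_cv", "leave_cell_line_out", "leave_tissue_out", "leave_drug_out")


@dataclass
class SplitPlan:
    regime: str
    fold: int
    seed: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def check_disjoint(self):
        a, b, c = set(self.train_idx), set(self.val_idx), set(self.test_idx)
        assert not (a & b) and not (a & c) and not (b & c)


def _fold_partition(keys: np.ndarray, fold_count: int, rng) -> list:
    """Shuffle unique keys and cut them into `fold_count` near-equal folds."""
    uniq = np.unique(keys)
    perm = rng.permutation(len(uniq))
    return [uniq[perm[f::fold_count]] for f in range(fold_count)]


def _plan_from_key_folds(keys, key_folds, fold, fold_count, regime, seed):
    test_keys = set(key_folds[fold])
    val_keys = set(key_folds[(fold + 1) % fold_count])
    idx = np.arange(len(keys))
    in_test = np.array([k in test_keys for k in keys])
    in_val = np.array([k in val_keys for k in keys]) & ~in_test
    train = idx[~in_test & ~in_val]
    return SplitPlan(regime, fold, seed, train, idx[in_val], idx[in_test])


def make_split(dataset: TripletDataset, regime: str, fold_count: int = 5,
               seed: int = 0) -> list:
    """Build one SplitPlan per fold for the requested regime.

    random_cv splits over unordered-triplet keys; the leave-out regimes
    split over cell lines, tissues, or drugs respectively, so that the
    held-out entities never appear in the training partition.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {REGIMES}")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)

    if regime == "random_cv":
        keys = dataset.pair_keys
        folds = _fold_partition(keys, fold_count, rng)
        return [
            _plan_from_key_folds(keys, folds, f, fold_count, regime, seed)
            for f in range(fold_count)
        ]

    if regime == "leave_cell_line_out":
        keys = dataset.cat[:, 2]
        uniq = np.unique(keys)
        if len(uniq) < 3:
            raise ValueError("leave-cell-line-out needs at least 3 cell lines")
        fold_count = min(fold_count, len(uniq))
        folds = _fold_partition(keys, fold_count, rng)
        return [
            _plan_from_key_folds(keys, folds, f, fold_count, regime, seed)
            for f in range(fold_count)
        ]

    if regime == "leave_tissue_out":
        if not dataset.tissues:
            raise ValueError("dataset has no tissue annotations")
        m = dataset.n_drugs
        tissue_of = np.array(
            [str(dataset.tissues.get(dataset.cell_ids[c - m], "")) for c in dataset.cat[:, 2]]
        )
        uniq = np.unique(tissue_of)
        if len(uniq) < 3:
            raise ValueError("leave-tissue-out needs at least 3 tissues")
        fold_count = min(fold_count, len(uniq))
        folds = _fold_partition(tissue_of, fold_count, rng)
        return [
            _plan_from_key_folds(tissue_of, folds, f, fold_count, regime, seed)
            for f in range(fold_count)
        ]

    # leave_drug_out: partition drugs; a triplet joins the test (val) set if
    # it touches a test (val) drug, and trains only on all-train-drug pairs,
    # so every test pair contains at least one drug absent from training.
    drug_ids = np.arange(dataset.n_drugs)
    if dataset.n_drugs < 3:
        raise ValueError("leave-drug-out needs at least 3 drugs")
    fold_count = min(fold_count, dataset.n_drugs)
    perm = rng.permutation(drug_ids)
    drug_folds = [perm[f::fold_count] for f in range(fold_count)]
    plans = []
    idx = np.arange(len(dataset))
    d1, d2 = dataset.cat[:, 0], dataset.cat[:, 1]
    for f in range(fold_count):
        test_drugs = set(drug_folds[f].tolist())
        val_drugs = set(drug_folds[(f + 1) % fold_count].tolist())
        in_test = np.array([a in test_drugs or b in test_drugs for a, b in zip(d1, d2)])
        in_val = (
            np.array([a in val_drugs or b in val_drugs for a, b in zip(d1, d2)])
            & ~in_test
        )
        plans.append(
            SplitPlan(regime, f, seed, idx[~in_test & ~in_val], idx[in_val], idx[in_test])
        )
    return plans
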