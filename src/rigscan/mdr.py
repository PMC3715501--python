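"""Multifactor dimensionality reduction (MDR) baseline.

MDR labels each joint-genotype cell "high risk" when its case:control
ratio reaches a threshold (default: the training data's overall
case:control ratio) and scores a SNP combination by the balanced accuracy
of the resulting one-dimensional classifier.  k-fold cross-validation,
stratified by phenotype, yields two model-selection criteria: mean testing
balanced accuracy (BA) and cross-validation consistency (CVC, the number
of folds in which a combination had the best training BA).

Conventions: a cell with cases but no controls is high risk; an empty cell
is low risk; a ratio exactly at the threshold is high risk.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .dataset import GenotypeDataset
from .entropy import ContingencyTable, combination_codes
from .exceptions import CombinationLimitError, SingleClassError

__all__ = ["MDRResult", "classify_cells", "balanced_accuracy", "mdr_cv"]


@dataclass(frozen=True)
class MDRResult:
    """Cross-validated MDR summary for one SNP combination.

    ``train_ba``/``test_ba`` are means over folds (and repeats); ``cvc``
    is the per-repeat mean selection count, an integer when n_repeats=1.
    """

    snp_indices: tuple[int, ...]
    risk_labels: np.ndarray  # (3^k,) bool, True = high risk (full data)
    train_ba: float
    test_ba: float
    cvc: float


def classify_cells(table: ContingencyTable, threshold: float) -> np.ndarray:
    """High/low risk call per cell by case:control ratio against threshold."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    case = table.counts[:, 0].astype(np.float64)
    ctrl = table.counts[:, 1].astype(np.float64)
    high = np.zeros(case.shape, dtype=bool)
    occupied = (case + ctrl) > 0
    zero_ctrl = occupied & (ctrl == 0)
    high[zero_ctrl] = True
    rest = occupied & (ctrl > 0)
    high[rest] = case[rest] >= threshold * ctrl[rest]
    return high


def balanced_accuracy(risk_labels: np.ndarray, table: ContingencyTable) -> float:
    """(sensitivity + specificity) / 2, high-risk cells predicting "case"."""
    risk_labels = np.asarray(risk_labels, dtype=bool)
    case = table.counts[:, 0].astype(np.float64)
    ctrl = table.counts[:, 1].astype(np.float64)
    n_case, n_ctrl = case.sum(), ctrl.sum()
    if n_case == 0 or n_ctrl == 0:
        raise SingleClassError("evaluation table must contain both classes")
    sens = case[risk_labels].sum() / n_case
    spec = ctrl[~risk_labels].sum() / n_ctrl
    return float((sens + spec) / 2.0)


def _stratified_folds(
    phenotype: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold label per sample; each class spread as evenly as possible."""
    folds = np.empty(phenotype.size, dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(phenotype == cls)
        if idx.size < n_folds:
            raise SingleClassError(
                f"class {cls} has {idx.size} samples, fewer than "
                f"{n_folds} folds; stratification impossible"
            )
        labels = rng.permutation(np.arange(idx.size) % n_folds)
        folds[idx] = labels
    return folds


def _cell_counts(flat: np.ndarray, sample_idx: np.ndarray, size: int) -> np.ndarray:
    """Counts (C, ncells, 2) from precomputed flat bin codes for a subset."""
    counts = np.bincount(flat[:, sample_idx].ravel(), minlength=size + 1)[:size]
    return counts.reshape(flat.shape[0], -1, 2)


def _fold_ba(counts: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Balanced accuracy per combination given high-risk masks.

    ``counts``: (C, ncells, 2); ``high``: (C, ncells) bool.
    """
    case = counts[:, :, 0]
    ctrl = counts[:, :, 1]
    n_case = case.sum(axis=1)
    n_ctrl = ctrl.sum(axis=1)
    if (n_case == 0).any() or (n_ctrl == 0).any():
        raise SingleClassError("a fold lost one phenotype class entirely")
    sens = (case * high).sum(axis=1) / n_case
    spec = (ctrl * ~high).sum(axis=1) / n_ctrl
    return (sens + spec) / 2.0


def mdr_cv(
    dataset: GenotypeDataset,
    k: int,
    n_folds: int = 10,
    seed: int | None = None,
    n_repeats: int = 1,
    max_combinations: int = 2_000_000,
) -> list[MDRResult]:
    """Exhaustive order-k MDR with stratified k-fold cross-validation.

    Returns one result per combination, ranked by CVC (descending), ties
    broken by mean testing BA then lexicographic SNP indices — the overall
    winner is the first element.  Deterministic under a fixed seed.
    """
    p = dataset.n_snps
    if not 1 <= k <= p:
        raise ValueError(f"order k={k} out of range 1..{p}")
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    dataset.require_both_classes()
    n_combo = math.comb(p, k)
    if n_combo > max_combinations:
        raise CombinationLimitError(
            f"C({p},{k}) = {n_combo} combinations exceeds the limit "
            f"{max_combinations}"
        )
    combos = np.array(list(itertools.combinations(range(p), k)), dtype=np.intp)
    ncells = 3**k
    codes, valid = combination_codes(dataset.genotypes, combos)
    y = dataset.phenotype.astype(np.int64)
    size = n_combo * ncells * 2
    offsets = (np.arange(n_combo, dtype=np.int64) * (ncells * 2))[:, None]
    flat = offsets + codes.astype(np.int64) * 2 + (1 - y)[None, :]
    flat[~valid] = size  # dump bin for per-combination missing exclusion
    all_idx = np.arange(dataset.n_samples)
    total_counts = _cell_counts(flat, all_idx, size)

    rng = np.random.default_rng(seed)
    sum_train_ba = np.zeros(n_combo)
    sum_test_ba = np.zeros(n_combo)
    cvc_counts = np.zeros(n_combo)
    for _ in range(n_repeats):
        folds = _stratified_folds(dataset.phenotype, n_folds, rng)
        for f in range(n_folds):
            test_idx = np.flatnonzero(folds == f)
            test_counts = _cell_counts(flat, test_idx, size)
            train_counts = total_counts - test_counts
            case_tr = train_counts[:, :, 0]
            ctrl_tr = train_counts[:, :, 1]
            n_case_tr = case_tr.sum(axis=1, keepdims=True)
            n_ctrl_tr = ctrl_tr.sum(axis=1, keepdims=True)
            # integer-exact >= comparison against the train case:control ratio
            occupied = (case_tr + ctrl_tr) > 0
            high = occupied & (case_tr * n_ctrl_tr >= n_case_tr * ctrl_tr)
            train_ba = _fold_ba(train_counts, high)
            test_ba = _fold_ba(test_counts, high)
            sum_train_ba += train_ba
            sum_test_ba += test_ba
            best = int(np.argmax(train_ba))  # first max = lexicographic tie-break
            cvc_counts[best] += 1.0

    denom = n_folds * n_repeats
    mean_train = sum_train_ba / denom
    mean_test = sum_test_ba / denom
    cvc = cvc_counts / n_repeats

    # full-data risk labels at the overall case:control threshold
    n_case_all = total_counts[:, :, 0].sum(axis=1, keepdims=True)
    n_ctrl_all = total_counts[:, :, 1].sum(axis=1, keepdims=True)
    occ = total_counts.sum(axis=2) > 0
    high_all = occ & (
        total_counts[:, :, 0] * n_ctrl_all >= n_case_all * total_counts[:, :, 1]
    )

    results = [
        MDRResult(
            snp_indices=tuple(int(x) for x in combos[i]),
            risk_labels=high_all[i].copy(),
            train_ba=float(mean_train[i]),
            test_ba=float(mean_test[i]),
            cvc=float(cvc[i]),
        )
        for i in range(n_combo)
    ]
    results.sort(key=lambda r: (-r.cvc, -r.test_ba, r.snp_indices))
    return results
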