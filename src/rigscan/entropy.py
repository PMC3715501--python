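"""Contingency tables and entropy statistics for SNP-combination scans.

The association measure is the relative information gain (RIG, also known
as normalized mutual information)

    R0 = IG / H(Y) = (H(Y) - H(Y|X)) / H(Y),

where Y is disease status and X the joint genotype of a k-SNP combination.
All entropies are in bits.  R0 lies in [0, 1]: 0 when the case proportion
is identical in every genotype cell, 1 when every occupied cell is pure.

The exhaustive order-k scan evaluates R0 for every k-combination of SNPs.
Internally the scan is vectorized over both combinations and phenotype
vectors, so a permutation ensemble (many shuffled phenotypes, fixed
genotypes) reuses the same cell structure; see :func:`r0_matrix`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .dataset import MISSING, GenotypeDataset
from .exceptions import (
    CombinationLimitError,
    DegenerateDistributionError,
    EmptyDataError,
    InvalidGenotypeError,
    SingleClassError,
)

__all__ = [
    "ContingencyTable",
    "RIGResult",
    "GStatistic",
    "encode_joint_genotype",
    "decode_joint_genotype",
    "build_contingency_table",
    "shannon_entropy",
    "conditional_entropy",
    "relative_information_gain",
    "g_statistic",
    "scan_combinations",
    "r0_matrix",
]

#: Default ceiling on the number of combinations an exhaustive scan may visit.
DEFAULT_MAX_COMBINATIONS = 2_000_000

_LN2 = math.log(2.0)


def encode_joint_genotype(genotype_codes: Sequence[int]) -> int:
    """Map a k-tuple of genotype codes to its contingency-table row index.

    Mixed-radix (base 3) encoding with the first SNP most significant and
    genotype order AA < Aa < aa (0 < 1 < 2); bijective onto 0..3^k - 1.
    """
    index = 0
    for code in genotype_codes:
        if code not in (0, 1, 2):
            raise InvalidGenotypeError(f"invalid genotype code {code!r}")
        index = index * 3 + int(code)
    return index


def decode_joint_genotype(index: int, k: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_joint_genotype` for a k-SNP combination."""
    if not 0 <= index < 3**k:
        raise InvalidGenotypeError(f"row index {index} out of range for k={k}")
    codes = []
    for m in range(k):
        codes.append((index // 3 ** (k - 1 - m)) % 3)
    return tuple(codes)


@dataclass(frozen=True)
class ContingencyTable:
    """3^k x 2 table of joint genotype vs disease status for one combination.

    Rows follow the mixed-radix order of :func:`encode_joint_genotype`;
    column 0 counts cases, column 1 controls.  Samples with any missing
    genotype among ``snp_indices`` are excluded from this table only.
    """

    snp_indices: tuple[int, ...]
    counts: np.ndarray  # (3^k, 2) int64

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        k = len(self.snp_indices)
        if counts.shape != (3**k, 2):
            raise ValueError(
                f"counts shape {counts.shape} != ({3 ** k}, 2) for k={k}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def order(self) -> int:
        return len(self.snp_indices)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_nonempty_rows(self) -> int:
        return int(np.count_nonzero(self.counts.sum(axis=1)))


@dataclass(frozen=True)
class RIGResult:
    """Entropy decomposition for one SNP combination (all values in bits)."""

    snp_indices: tuple[int, ...]
    order: int
    h_y: float
    h_y_given_x: float
    ig: float
    r0: float


@dataclass(frozen=True)
class GStatistic:
    """Log-likelihood-ratio (G) test of genotype-status independence.

    ``df`` is the standard independence-test value (3^k - 1)(2 - 1);
    ``n_nonempty_rows`` flags sparse tables for which the chi-square
    approximation is unreliable.
    """

    g2: float
    df: int
    n_nonempty_rows: int


def build_contingency_table(
    dataset: GenotypeDataset, snp_indices: Sequence[int]
) -> ContingencyTable:
    """Tally joint genotype vs disease status for one SNP combination."""
    snp_indices = tuple(int(i) for i in snp_indices)
    k = len(snp_indices)
    if k == 0:
        raise ValueError("snp_indices must be non-empty")
    if len(set(snp_indices)) != k:
        raise ValueError(f"snp_indices must be distinct, got {snp_indices}")
    for i in snp_indices:
        if not 0 <= i < dataset.n_snps:
            raise IndexError(f"SNP index {i} out of range (p={dataset.n_snps})")
    sub = dataset.genotypes[:, snp_indices]
    valid = (sub != MISSING).all(axis=1)
    if not valid.any():
        raise EmptyDataError(
            f"no samples with complete genotypes for combination {snp_indices}"
        )
    sub = sub[valid].astype(np.int64)
    # mixed-radix row code, first SNP most significant
    codes = np.zeros(sub.shape[0], dtype=np.int64)
    for m in range(k):
        codes = codes * 3 + sub[:, m]
    y = dataset.phenotype[valid]
    flat = codes * 2 + (1 - y)  # column 0 = case, 1 = control
    counts = np.bincount(flat, minlength=3**k * 2).reshape(3**k, 2)
    return ContingencyTable(snp_indices=snp_indices, counts=counts)


def shannon_entropy(counts: Iterable[float]) -> float:
    """Shannon entropy in bits of the distribution given by ``counts``.

    Uses the 0 * log 0 = 0 convention for empty cells.
    """
    c = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts,
                   dtype=np.float64)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise DegenerateDistributionError("all-zero count vector has no entropy")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(table: ContingencyTable) -> float:
    """H(Y | X) in bits: row-weighted average of within-row entropies.

    Empty rows contribute zero, so sparse tables are well-defined.
    """
    counts = table.counts.astype(np.float64)
    n = counts.sum()
    if n <= 0:
        raise EmptyDataError("contingency table is empty")
    row_tot = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / row_tot[:, None]
        terms = np.where(counts > 0, -p * np.log2(p), 0.0)
    return float((row_tot / n * terms.sum(axis=1)).sum())


def relative_information_gain(table: ContingencyTable) -> RIGResult:
    """Compute H(Y), H(Y|X), IG and R0 = IG / H(Y) for one table."""
    col_tot = table.counts.sum(axis=0)
    if col_tot[0] == 0 or col_tot[1] == 0:
        raise SingleClassError(
            "both disease classes must be present (H(Y) > 0); column totals "
            f"are {tuple(int(c) for c in col_tot)}"
        )
    h_y = shannon_entropy(col_tot)
    h_y_x = conditional_entropy(table)
    ig = max(h_y - h_y_x, 0.0)
    r0 = min(ig / h_y, 1.0)
    return RIGResult(
        snp_indices=table.snp_indices,
        order=table.order,
        h_y=h_y,
        h_y_given_x=h_y_x,
        ig=ig,
        r0=r0,
    )


def g_statistic(table: ContingencyTable) -> GStatistic:
    """G statistic 2 * sum O ln(O/E) with independence-test df.

    Satisfies the identity G2 = 2 * n * ln(2) * IG_bits, i.e. the G test is
    the information gain on a different scale.
    """
    counts = table.counts.astype(np.float64)
    n = counts.sum()
    if n <= 0:
        raise EmptyDataError("contingency table is empty")
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    expected = np.outer(row_tot, col_tot) / n
    mask = counts > 0
    g2 = 2.0 * float((counts[mask] * np.log(counts[mask] / expected[mask])).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return GStatistic(g2=max(g2, 0.0), df=df, n_nonempty_rows=table.n_nonempty_rows)


# ---------------------------------------------------------------------------
# Vectorized scan machinery
# ---------------------------------------------------------------------------

def _binary_entropy(p: np.ndarray) -> np.ndarray:
    """Elementwise H2(p) in bits with the 0 log 0 convention; p may hold NaN."""
    p = np.asarray(p, dtype=np.float64)
    out = np.zeros_like(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        for q in (p, 1.0 - p):
            term = np.where((q > 0) & (q < 1), -q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
            out += np.nan_to_num(term, nan=0.0)
    return out


def combination_codes(
    genotypes: np.ndarray, combos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Joint-genotype row codes and validity mask for a batch of combinations.

    Returns ``codes`` (C, n) int32 (undefined where invalid) and ``valid``
    (C, n) bool marking samples with complete genotypes for each combination.
    """
    combos = np.asarray(combos, dtype=np.intp)
    k = combos.shape[1]
    g = genotypes[:, combos.reshape(-1)].reshape(genotypes.shape[0], combos.shape[0], k)
    g = np.moveaxis(g, 0, 1)  # (C, n, k)
    valid = (g != MISSING).all(axis=2)
    codes = np.zeros(g.shape[:2], dtype=np.int32)
    for m in range(k):
        codes = codes * 3 + np.where(valid, g[:, :, m], 0).astype(np.int32)
    return codes, valid


def r0_matrix(
    genotypes: np.ndarray,
    phenotypes: np.ndarray,
    combos: np.ndarray,
    block: int = 256,
    return_components: bool = False,
):
    """R0 for every (phenotype vector, SNP combination) pair.

    Parameters
    ----------
    genotypes
        ``(n, p)`` genotype matrix (``MISSING`` allowed).
    phenotypes
        ``(m, n)`` matrix whose rows are 0/1 phenotype vectors — a single
        observed vector or a whole permutation ensemble.
    combos
        ``(C, k)`` array of SNP-index combinations.
    block
        Number of combinations processed per sparse matmul.

    Returns
    -------
    ``(m, C)`` array of R0 values, plus ``(H_Y, H_Y|X)`` arrays of the same
    shape when ``return_components`` is set.
    """
    phenotypes = np.asarray(phenotypes, dtype=np.float64)
    if phenotypes.ndim == 1:
        phenotypes = phenotypes[None, :]
    m, n = phenotypes.shape
    combos = np.asarray(combos, dtype=np.intp)
    n_combo, k = combos.shape
    ncells = 3**k

    r0 = np.empty((m, n_combo), dtype=np.float64)
    h_y_out = np.empty((m, n_combo), dtype=np.float64) if return_components else None
    h_cond_out = np.empty((m, n_combo), dtype=np.float64) if return_components else None

    for start in range(0, n_combo, block):
        cb = combos[start : start + block]
        b = cb.shape[0]
        codes, valid = combination_codes(genotypes, cb)
        # sparse indicator: sample -> (combo, cell) column; invalid samples
        # simply contribute no entry, implementing complete-case exclusion
        c_idx, s_idx = np.nonzero(valid)
        cols = c_idx * ncells + codes[c_idx, s_idx]
        ind = sparse.csr_matrix(
            (np.ones(len(s_idx)), (s_idx, cols)), shape=(n, b * ncells)
        )
        case_counts = (phenotypes @ ind).reshape(m, b, ncells)
        row_tot = np.asarray(ind.sum(axis=0)).reshape(b, ncells)

        n_used = row_tot.sum(axis=1)  # (b,)
        if (n_used == 0).any():
            bad = cb[np.argmax(n_used == 0)]
            raise EmptyDataError(
                f"no samples with complete genotypes for combination "
                f"{tuple(int(x) for x in bad)}"
            )
        n_case = case_counts.sum(axis=2)  # (m, b)
        h_y = _binary_entropy(n_case / n_used[None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            p_case = np.where(row_tot[None, :, :] > 0,
                              case_counts / row_tot[None, :, :], 0.0)
        h_rows = _binary_entropy(p_case)  # (m, b, ncells)
        weights = row_tot / n_used[:, None]  # (b, ncells)
        h_cond = (h_rows * weights[None, :, :]).sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            block_r0 = np.where(h_y > 0, (h_y - h_cond) / np.where(h_y > 0, h_y, 1.0), 0.0)
        np.clip(block_r0, 0.0, 1.0, out=block_r0)
        r0[:, start : start + b] = block_r0
        if return_components:
            h_y_out[:, start : start + b] = h_y
            h_cond_out[:, start : start + b] = h_cond

    if return_components:
        return r0, h_y_out, h_cond_out
    return r0


def all_combinations(p: int, k: int) -> np.ndarray:
    """All k-combinations of range(p) in lexicographic order, shape (C, k)."""
    combos = np.array(list(itertools.combinations(range(p), k)), dtype=np.intp)
    return combos.reshape(-1, k)


def scan_combinations(
    dataset: GenotypeDataset,
    k: int,
    top_n: int | None = None,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
) -> list[RIGResult]:
    """Exhaustive order-k RIG scan, sorted by R0 descending.

    Ties are broken lexicographically on SNP indices, so the ranking is
    deterministic for a fixed dataset.
    """
    p = dataset.n_snps
    if not 1 <= k <= p:
        raise ValueError(f"order k={k} out of range 1..{p}")
    dataset.require_both_classes()
    n_combo = math.comb(p, k)
    if n_combo > max_combinations:
        raise CombinationLimitError(
            f"C({p},{k}) = {n_combo} combinations exceeds the limit "
            f"{max_combinations}; raise max_combinations to force the scan"
        )
    combos = all_combinations(p, k)
    r0, h_y, h_cond = r0_matrix(
        dataset.genotypes, dataset.phenotype, combos, return_components=True
    )
    r0, h_y, h_cond = r0[0], h_y[0], h_cond[0]
    results = [
        RIGResult(
            snp_indices=tuple(int(x) for x in combos[i]),
            order=k,
            h_y=float(h_y[i]),
            h_y_given_x=float(h_cond[i]),
            ig=float(max(h_y[i] - h_cond[i], 0.0)),
            r0=float(r0[i]),
        )
        for i in range(len(combos))
    ]
    # stable sort on -r0 keeps the lexicographic combination order for ties
    results.sort(key=lambda r: -r.r0)
    if top_n is not None:
        results = results[: max(int(top_n), 0)]
    return results
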