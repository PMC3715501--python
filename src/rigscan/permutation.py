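"""Permutation-max null distribution and standardized RIG (U_r).

Phenotype labels are repeatedly shuffled while genotypes stay fixed, and
the maximum R0 over all order-k combinations is recorded for each shuffle.
The mean and standard deviation of those maxima standardize an observed R0
into U_r = (R0 - mu) / sigma, and the ensemble of maxima also yields
family-wise-error-controlling adjusted p-values and alpha-level cutoffs.

One ensemble per interaction order serves every combination of that order;
the maximum is taken across combinations *within* each permuted dataset,
never per combination.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dataset import GenotypeDataset
from .entropy import RIGResult, all_combinations, r0_matrix
from .exceptions import DegenerateNullError, OrderMismatchError

__all__ = [
    "PermutationNull",
    "StandardizedResult",
    "permute_phenotype",
    "build_null",
    "standardize",
    "adjusted_pvalue",
    "cutoff",
    "format_pvalue",
]


@dataclass
class PermutationNull:
    """Per-order ensemble of maximum R0 values over permuted datasets."""

    order: int
    n_perm: int
    M: np.ndarray  # (n_perm,) per-permutation maximum R0
    mu: float
    sigma: float
    seed: int | None = None

    @classmethod
    def from_maxima(
        cls, order: int, M: np.ndarray, seed: int | None = None
    ) -> "PermutationNull":
        M = np.asarray(M, dtype=np.float64)
        if M.size < 2:
            raise ValueError("need at least 2 permutations")
        mu = float(M.mean())
        sigma = float(M.std(ddof=1))
        if sigma <= 0.0:
            raise DegenerateNullError(
                "permutation maxima have zero spread (all M_i = "
                f"{M[0]:.6g}); the genotype data carry no variation to "
                "standardize against"
            )
        return cls(order=order, n_perm=M.size, M=M, mu=mu, sigma=sigma, seed=seed)

    def quantile(self, q: float) -> float:
        """Empirical quantile of M (higher order statistic, conservative)."""
        idx = min(max(math.ceil(q * self.n_perm), 1), self.n_perm)
        return float(np.sort(self.M)[idx - 1])

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the null summary (and maxima) for re-standardization."""
        payload = {
            "order": self.order,
            "n_perm": self.n_perm,
            "mu": self.mu,
            "sigma": self.sigma,
            "seed": self.seed,
            "quantiles": {
                str(q): self.quantile(q) for q in (0.5, 0.9, 0.95, 0.99)
            },
            "M": [float(x) for x in self.M],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PermutationNull":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            order=d["order"],
            n_perm=d["n_perm"],
            M=np.asarray(d["M"], dtype=np.float64),
            mu=d["mu"],
            sigma=d["sigma"],
            seed=d.get("seed"),
        )


@dataclass(frozen=True)
class StandardizedResult:
    """A combination's R0 with its standardized score and adjusted p-value."""

    snp_indices: tuple[int, ...]
    order: int
    r0: float
    u_r: float
    p_adj: float


def permute_phenotype(
    dataset: GenotypeDataset, rng: np.random.Generator
) -> GenotypeDataset:
    """Uniform random shuffle of the phenotype; genotypes untouched."""
    return dataset.with_phenotype(rng.permutation(dataset.phenotype))


def _permutation_matrix(
    phenotype: np.ndarray, n_perm: int, seed: int | None
) -> np.ndarray:
    """(n_perm, n) matrix of independently shuffled phenotype vectors.

    Each row uses its own RNG stream spawned from the master seed, so the
    ensemble is reproducible and could be generated in any order.
    """
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    out = np.empty((n_perm, phenotype.size), dtype=np.float64)
    for i, ss in enumerate(streams):
        out[i] = np.random.default_rng(ss).permutation(phenotype)
    return out


def build_null(
    dataset: GenotypeDataset,
    k: int,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationNull:
    """Empirical null of the order-k maximum R0 from ``n_perm`` shuffles."""
    if n_perm < 2:
        raise ValueError(f"n_perm must be >= 2, got {n_perm}")
    dataset.require_both_classes()
    combos = all_combinations(dataset.n_snps, k)
    if combos.shape[0] == 0:
        raise ValueError(f"no order-{k} combinations for p={dataset.n_snps}")
    P = _permutation_matrix(dataset.phenotype, n_perm, seed)
    r0 = r0_matrix(dataset.genotypes, P, combos)
    M = r0.max(axis=1)
    return PermutationNull.from_maxima(order=k, M=M, seed=seed)


def adjusted_pvalue(r0: float, null: PermutationNull) -> float:
    """FWER-adjusted p-value: fraction of permutation maxima >= R0.

    A numeric 0 means "smaller than the permutation resolution"; render it
    with :func:`format_pvalue`.
    """
    return float(np.count_nonzero(null.M >= r0)) / null.n_perm


def format_pvalue(p: float, n_perm: int) -> str:
    """Human-readable adjusted p-value with the < 1/n_perm floor."""
    if p <= 0.0:
        return f"< {1.0 / n_perm:g}"
    return f"{p:g}"


def standardize(
    results: list[RIGResult], null: PermutationNull
) -> list[StandardizedResult]:
    """Standardize R0 values against the matching-order null.

    Order-preserving; since U_r is an increasing affine map of R0, ranking
    by U_r is identical to ranking by R0.
    """
    if null.sigma <= 0:
        raise DegenerateNullError("null sigma must be positive")
    out = []
    for r in results:
        if r.order != null.order:
            raise OrderMismatchError(
                f"result order {r.order} does not match null order {null.order}"
            )
        out.append(
            StandardizedResult(
                snp_indices=r.snp_indices,
                order=r.order,
                r0=r.r0,
                u_r=(r.r0 - null.mu) / null.sigma,
                p_adj=adjusted_pvalue(r.r0, null),
            )
        )
    return out


def cutoff(null: PermutationNull, alpha: float = 0.05) -> tuple[float, float]:
    """Alpha-level significance cutoff from the null of maxima.

    Returns ``(M_cut, U_cut)`` where ``M_cut`` is the upper-alpha empirical
    order statistic of M (ceiling convention) and ``U_cut`` its standardized
    value.  A combination is significant iff R0 > M_cut (equivalently
    U_r > U_cut).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if null.n_perm * alpha < 1.0:
        raise ValueError(
            f"n_perm={null.n_perm} too small to resolve alpha={alpha}"
        )
    m_cut = null.quantile(1.0 - alpha)
    return m_cut, (m_cut - null.mu) / null.sigma
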