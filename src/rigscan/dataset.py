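"""Case-control genotype container.

Genotypes are coded as minor-allele counts (0 = AA, 1 = Aa, 2 = aa) with
``MISSING`` (-1) as the explicit missing sentinel.  The phenotype is binary
(1 = case, 0 = control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidGenotypeError, SingleClassError

#: Sentinel for a missing genotype call.
MISSING: int = -1

VALID_CODES = frozenset({0, 1, 2, MISSING})


@dataclass
class GenotypeDataset:
    """Samples x SNPs genotype matrix plus binary disease status.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` integer matrix of codes in {0, 1, 2} with
        ``MISSING`` marking a failed call.
    phenotype
        Length-``n_samples`` vector in {0, 1}; 1 = case.
    snp_ids
        Unique SNP labels, one per column.  Generated if omitted.
    sample_ids
        Unique sample labels, one per row.  Generated if omitted.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise InvalidGenotypeError("genotypes must be a 2-D matrix")
        n, p = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise InvalidGenotypeError(
                f"phenotype length {self.phenotype.shape} does not match "
                f"{n} samples"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise InvalidGenotypeError(
                f"invalid genotype code {int(self.genotypes[i, j])} at "
                f"sample {i}, SNP {j}"
            )
        if not np.isin(self.phenotype, (0, 1)).all():
            raise InvalidGenotypeError("phenotype must be coded 0/1")
        if not self.snp_ids:
            self.snp_ids = [f"SNP{j + 1}" for j in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        if len(self.snp_ids) != p:
            raise InvalidGenotypeError("snp_ids length does not match columns")
        if len(self.sample_ids) != n:
            raise InvalidGenotypeError("sample_ids length does not match rows")
        if len(set(self.snp_ids)) != p:
            raise InvalidGenotypeError("snp_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.count_nonzero(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.count_nonzero(self.phenotype == 0))

    def require_both_classes(self) -> None:
        """Raise unless cases and controls are both present."""
        if self.n_cases == 0 or self.n_controls == 0:
            raise SingleClassError(
                "analysis requires both cases and controls; got "
                f"{self.n_cases} cases / {self.n_controls} controls"
            )

    def with_phenotype(self, phenotype: np.ndarray) -> "GenotypeDataset":
        """Return a copy sharing genotypes but with a new phenotype vector."""
        return GenotypeDataset(
            genotypes=self.genotypes,
            phenotype=np.asarray(phenotype, dtype=np.int8),
            snp_ids=list(self.snp_ids),
            sample_ids=list(self.sample_ids),
        )
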