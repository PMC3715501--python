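"""Two-locus penetrance simulation and the hit-ratio power experiment.

Eight epistatic disease models are specified as 3x3 odds-ratio grids over
the joint genotypes of two causal loci, together with a shared minor
allele frequency (MAF) and a target population prevalence.  Odds ratios
are interpreted as multipliers of a common baseline odds b:

    penetrance_ij = OR_ij * b / (1 + OR_ij * b),

with b solved so that the Hardy-Weinberg-weighted mean penetrance equals
the prevalence.  A zero odds ratio is a structural zero (penetrance 0).

Case-control data are drawn retrospectively: case genotype pairs with
probability proportional to hwe_i * hwe_j * penetrance_ij, controls with
hwe_i * hwe_j * (1 - penetrance_ij).  Noise SNPs are independent of the
phenotype, drawn under HWE with per-SNP MAF ~ Uniform(0.05, 0.5).

The power experiment embeds one causal pair among p SNPs and measures the
hit ratio: the fraction of replicates in which that pair ranks first among
all two-locus combinations.  Ranking by R0 and by the standardized U_r are
identical (standardization is monotone), so the R0 ranking is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .dataset import GenotypeDataset
from .entropy import all_combinations, r0_matrix
from .exceptions import InfeasibleModelError
from . import mdr as _mdr

__all__ = [
    "PenetranceModel",
    "SimulationDesign",
    "MODEL_SPECS",
    "GROUP_TABLE",
    "hwe_frequencies",
    "derive_penetrance",
    "penetrance_model",
    "sample_causal_pair",
    "generate_dataset",
    "power_experiment",
]

# Odds-ratio grids indexed [locus A genotype, locus B genotype] with
# 0=AA/BB (common homozygote), 1=Aa/Bb, 2=aa/bb.  Each entry is
# (maf, prevalence, OR grid).  Models 1-3 vary effect size on a fixed
# checkerboard structure; 4-6 and 7-8 come from published epistasis
# benchmarks with little marginal effect.
MODEL_SPECS: dict[int, tuple[float, float, tuple[tuple[float, ...], ...]]] = {
    1: (0.1, 0.050, ((1.21, 0.2, 0.2), (0.2, 5.0, 5.0), (0.2, 5.0, 5.0))),
    2: (0.1, 0.050, ((1.23, 0.33, 0.33), (0.33, 3.0, 3.0), (0.33, 3.0, 3.0))),
    3: (0.1, 0.050, ((1.22, 0.4, 0.4), (0.4, 2.5, 2.5), (0.4, 2.5, 2.5))),
    4: (0.1, 0.046, ((0.55, 1.54, 1.75), (1.75, 0.18, 0.18), (1.33, 0.74, 0.0))),
    5: (0.1, 0.026, ((1.16, 0.38, 0.76), (0.38, 3.70, 1.97), (0.76, 1.97, 2.82))),
    6: (0.1, 0.017, ((1.15, 0.28, 1.15), (0.40, 4.23, 0.06), (0.17, 4.89, 5.56))),
    7: (0.2, 0.052, ((0.84, 1.30, 1.45), (1.35, 0.39, 0.13), (0.80, 1.45, 1.04))),
    8: (0.4, 0.048, ((0.52, 1.30, 1.21), (1.07, 0.92, 1.08), (1.89, 0.59, 0.33))),
}

# Table of simulation design groups: group id -> (n_snp, n_sample).
# Groups count down columns of the (n_sample x n_snp) grid: 1-3 are 10 SNPs
# at 400/1000/2000 samples, 4-6 are 50 SNPs, and so on to 13-15 at 1000.
GROUP_TABLE: dict[int, tuple[int, int]] = {
    g: (n_snp, n_sample)
    for g, (n_snp, n_sample) in enumerate(
        (
            (p, n)
            for p in (10, 50, 100, 500, 1000)
            for n in (400, 1000, 2000)
        ),
        start=1,
    )
}


def hwe_frequencies(maf: float) -> np.ndarray:
    """Genotype frequencies ((1-q)^2, 2q(1-q), q^2) at minor allele freq q."""
    if not 0.0 < maf < 1.0:
        raise ValueError(f"maf must be in (0, 1), got {maf}")
    q = maf
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


@dataclass(frozen=True)
class PenetranceModel:
    """A resolved two-locus disease model.

    ``penetrance[i, j]`` is P(disease | locus A genotype i, locus B
    genotype j); ``baseline_odds`` is the solved common odds scale.
    """

    model_id: int | None
    or_table: np.ndarray  # (3, 3)
    maf: float
    prevalence: float
    penetrance: np.ndarray  # (3, 3)
    baseline_odds: float

    @property
    def hwe(self) -> np.ndarray:
        return hwe_frequencies(self.maf)

    @property
    def joint_genotype_probs(self) -> np.ndarray:
        """HWE product distribution over the 9 two-locus genotypes."""
        w = self.hwe
        return np.outer(w, w)


def derive_penetrance(
    or_table: Sequence[Sequence[float]],
    maf: float,
    prevalence: float,
    model_id: int | None = None,
    bracket: tuple[float, float] = (1e-8, 1e3),
) -> PenetranceModel:
    """Solve baseline odds so HWE-weighted mean penetrance = prevalence.

    The weighted mean is strictly increasing in the baseline odds b, so a
    bisection-type root find (Brent) on the bracket is exact; the residual
    of the prevalence constraint is checked to < 1e-10.
    """
    ors = np.asarray(or_table, dtype=np.float64)
    if ors.shape != (3, 3):
        raise ValueError("or_table must be 3x3")
    if (ors < 0).any():
        raise ValueError("odds ratios must be non-negative")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    w = hwe_frequencies(maf)
    weights = np.outer(w, w)

    def mean_penetrance(b: float) -> np.ndarray:
        with np.errstate(over="ignore"):
            return float((weights * ors * b / (1.0 + ors * b)).sum())

    lo, hi = bracket
    f_lo = mean_penetrance(lo) - prevalence
    f_hi = mean_penetrance(hi) - prevalence
    if f_lo * f_hi > 0:
        raise InfeasibleModelError(
            f"no baseline odds in {bracket} gives prevalence {prevalence} "
            f"(f({lo})={f_lo:.3g}, f({hi})={f_hi:.3g})"
        )
    b = float(brentq(lambda x: mean_penetrance(x) - prevalence, lo, hi,
                     xtol=1e-15, rtol=8.9e-16))
    penetrance = ors * b / (1.0 + ors * b)
    residual = abs(float((weights * penetrance).sum()) - prevalence)
    if residual >= 1e-10:
        raise InfeasibleModelError(
            f"prevalence residual {residual:.3g} after root solve"
        )
    return PenetranceModel(
        model_id=model_id,
        or_table=ors,
        maf=maf,
        prevalence=prevalence,
        penetrance=penetrance,
        baseline_odds=b,
    )


def penetrance_model(model_id: int) -> PenetranceModel:
    """Resolve one of the eight built-in models by id."""
    if model_id not in MODEL_SPECS:
        raise KeyError(f"unknown model id {model_id}; valid ids 1-8")
    maf, prevalence, ors = MODEL_SPECS[model_id]
    return derive_penetrance(ors, maf, prevalence, model_id=model_id)


def sample_causal_pair(
    model: PenetranceModel,
    status: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` two-locus genotype pairs retrospectively for one status.

    Cell probabilities are proportional to hwe_i*hwe_j*penetrance_ij for
    cases and hwe_i*hwe_j*(1 - penetrance_ij) for controls.  Returns an
    (n, 2) array of genotype codes.
    """
    if status not in ("case", "control"):
        raise ValueError(f"status must be 'case' or 'control', got {status!r}")
    w = model.joint_genotype_probs
    lik = model.penetrance if status == "case" else 1.0 - model.penetrance
    probs = (w * lik).reshape(-1)
    total = probs.sum()
    if total <= 0:
        raise InfeasibleModelError(f"no probability mass for {status}s")
    cells = rng.choice(9, size=n, p=probs / total)
    return np.column_stack([cells // 3, cells % 3]).astype(np.int8)


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the simulation protocol.

    ``model_id=None`` produces global-null data (no causal pair).  The
    (group, n_snp, n_sample) mapping follows :data:`GROUP_TABLE`; sample
    counts are always balanced 1:1 case:control.
    """

    group_id: int
    model_id: int | None = 1
    n_replicates: int = 100
    causal_positions: tuple[int, int] = (0, 1)
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.group_id not in GROUP_TABLE:
            raise ValueError(f"unknown group id {self.group_id}; valid ids 1-15")
        if self.model_id is not None and self.model_id not in MODEL_SPECS:
            raise ValueError(f"unknown model id {self.model_id}")
        a, b = self.causal_positions
        if a == b or not (0 <= a < self.n_snp and 0 <= b < self.n_snp):
            raise ValueError(f"invalid causal positions {self.causal_positions}")

    @property
    def n_snp(self) -> int:
        return GROUP_TABLE[self.group_id][0]

    @property
    def n_sample(self) -> int:
        return GROUP_TABLE[self.group_id][1]

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = {
            "group_id": self.group_id,
            "model_id": self.model_id,
            "n_snp": self.n_snp,
            "n_sample": self.n_sample,
            "n_replicates": self.n_replicates,
            "causal_positions": list(self.causal_positions),
            "noise_maf_range": list(self.noise_maf_range),
            "master_seed": self.master_seed,
        }
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimulationDesign":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = yaml.safe_load(text)
        return cls(
            group_id=d["group_id"],
            model_id=d.get("model_id"),
            n_replicates=d.get("n_replicates", 100),
            causal_positions=tuple(d.get("causal_positions", (0, 1))),
            noise_maf_range=tuple(d.get("noise_maf_range", (0.05, 0.5))),
            master_seed=d.get("master_seed", 0),
        )


def _replicate_rng(master_seed: int, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(replicate_index)])
    )


def generate_dataset(
    design: SimulationDesign, replicate_index: int = 0
) -> GenotypeDataset:
    """One balanced case-control replicate; deterministic in (seed, index)."""
    rng = _replicate_rng(design.master_seed, replicate_index)
    n, p = design.n_sample, design.n_snp
    if n % 2:
        raise ValueError(f"n_sample must be even for balanced sampling, got {n}")
    n_cases = n // 2
    phenotype = np.concatenate([np.ones(n_cases, dtype=np.int8),
                                np.zeros(n - n_cases, dtype=np.int8)])
    genotypes = np.empty((n, p), dtype=np.int8)
    lo, hi = design.noise_maf_range
    noise_mafs = rng.uniform(lo, hi, size=p)
    for j in range(p):
        genotypes[:, j] = rng.binomial(2, noise_mafs[j], size=n).astype(np.int8)
    if design.model_id is not None:
        model = penetrance_model(design.model_id)
        a, b = design.causal_positions
        case_pairs = sample_causal_pair(model, "case", n_cases, rng)
        ctrl_pairs = sample_causal_pair(model, "control", n - n_cases, rng)
        pairs = np.vstack([case_pairs, ctrl_pairs])
        genotypes[:, a] = pairs[:, 0]
        genotypes[:, b] = pairs[:, 1]
    return GenotypeDataset(genotypes=genotypes, phenotype=phenotype)


def _top_pair_by_r0(dataset: GenotypeDataset) -> tuple[int, int]:
    combos = all_combinations(dataset.n_snps, 2)
    r0 = r0_matrix(dataset.genotypes, dataset.phenotype, combos)[0]
    # argmax on -r0 keeps the first (lexicographically smallest) tie
    best = int(np.argmax(r0))
    return tuple(int(x) for x in combos[best])


def power_experiment(
    models: Iterable[int],
    groups: Iterable[int],
    n_replicates: int = 100,
    methods: Sequence[str] = ("U_r", "MDR-BA", "MDR-CVC"),
    master_seed: int = 0,
    n_folds: int = 10,
) -> pd.DataFrame:
    """Hit-ratio power table over (model, group, method).

    A replicate scores a hit for a method when the embedded causal pair
    (compared as an unordered index set) is that method's top-ranked
    two-locus combination.  The U_r hit ratio equals the R0 hit ratio by
    rank invariance.
    """
    valid = {"U_r", "MDR-BA", "MDR-CVC"}
    methods = tuple(methods)
    unknown = set(methods) - valid
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; valid: {sorted(valid)}")
    need_mdr = bool({"MDR-BA", "MDR-CVC"} & set(methods))
    rows = []
    for model_id in models:
        for group_id in groups:
            design = SimulationDesign(
                group_id=group_id, model_id=model_id,
                n_replicates=n_replicates, master_seed=master_seed,
            )
            causal = frozenset(design.causal_positions)
            hits = {m: 0 for m in methods}
            for rep in range(n_replicates):
                ds = generate_dataset(design, rep)
                if "U_r" in hits:
                    hits["U_r"] += frozenset(_top_pair_by_r0(ds)) == causal
                if need_mdr:
                    mdr_results = _mdr.mdr_cv(
                        ds, k=2, n_folds=n_folds,
                        seed=int(np.random.SeedSequence(
                            [design.master_seed, rep, 7]).generate_state(1)[0] % 2**31),
                    )
                    if "MDR-BA" in hits:
                        by_ba = min(
                            mdr_results,
                            key=lambda r: (-r.test_ba, r.snp_indices),
                        )
                        hits["MDR-BA"] += frozenset(by_ba.snp_indices) == causal
                    if "MDR-CVC" in hits:
                        hits["MDR-CVC"] += frozenset(mdr_results[0].snp_indices) == causal
            for m in methods:
                rows.append(
                    {
                        "model": model_id,
                        "group": group_id,
                        "method": m,
                        "hit_ratio": hits[m] / n_replicates,
                        "n_replicates": n_replicates,
                        "master_seed": master_seed,
                    }
                )
    return pd.DataFrame(rows)
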