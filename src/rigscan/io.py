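"""Reading and writing genotype tables, results, and run reports.

Native dialects: a delimited table (TSV/CSV) with one header row, an
optional leading ``sample_id`` column, a ``phenotype`` column in {0, 1}
and one column per SNP holding codes {0, 1, 2} or NA; and the PLINK
``.raw`` additive-dosage export (FID IID PAT MAT SEX PHENOTYPE then one
dosage column per SNP, phenotype coded 1=control/2=case, missing -9/0).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset
from .exceptions import ParseError

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "RunReport",
]

logger = logging.getLogger("rigscan")

_RAW_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_delimited(path: Path, sep: str) -> GenotypeDataset:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if not header:
        raise ParseError(f"{path}: empty file")
    if "phenotype" not in header:
        raise ParseError(f"{path}: missing required 'phenotype' column")
    df = pd.read_csv(path, sep=sep, na_values=["NA", "na", ""], dtype=str)
    cols = list(header)
    sample_ids = None
    if cols and cols[0] == "sample_id":
        sample_ids = df["sample_id"].astype(str).tolist()
        cols = cols[1:]
    snp_cols = [c for c in cols if c != "phenotype"]
    if len(set(snp_cols)) != len(snp_cols):
        dup = sorted({c for c in snp_cols if snp_cols.count(c) > 1})
        raise ParseError(f"{path}: duplicate SNP ids {dup}")
    pheno_raw = df["phenotype"]
    if pheno_raw.isna().any():
        row = int(pheno_raw.index[pheno_raw.isna()][0]) + 2  # 1-based + header
        raise ParseError(f"{path}: missing phenotype at line {row}")
    try:
        phenotype = pheno_raw.astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric phenotype value ({exc})") from exc
    if not np.isin(phenotype, (0.0, 1.0)).all():
        row = int(np.flatnonzero(~np.isin(phenotype, (0.0, 1.0)))[0]) + 2
        raise ParseError(f"{path}: phenotype must be 0/1; offending line {row}")
    n = len(df)
    genotypes = np.full((n, len(snp_cols)), MISSING, dtype=np.int8)
    for j, col in enumerate(snp_cols):
        raw = df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.notna() & ~vals.isin([0, 1, 2])
        unparsed = raw.notna() & vals.isna()
        if bad.any() or unparsed.any():
            idx = int((bad | unparsed).idxmax())
            raise ParseError(
                f"{path}: invalid genotype code {raw.iloc[idx]!r} in column "
                f"'{col}', line {idx + 2}"
            )
        obs = vals.notna().to_numpy()
        genotypes[obs, j] = vals.to_numpy()[obs].astype(np.int8)
    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=phenotype.astype(np.int8),
        snp_ids=snp_cols,
        sample_ids=sample_ids or [],
    )


def _read_plink_raw(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"], dtype=str)
    missing_meta = [c for c in _RAW_META_COLS if c not in df.columns]
    if missing_meta:
        raise ParseError(f"{path}: .raw file lacks columns {missing_meta}")
    snp_cols = [c for c in df.columns if c not in _RAW_META_COLS]
    if not snp_cols:
        raise ParseError(f"{path}: no genotype columns after the .raw header")
    # PLINK appends the counted allele as _A; strip it for SNP ids
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    if len(set(snp_ids)) != len(snp_ids):
        dup = sorted({s for s in snp_ids if snp_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate SNP ids {dup}")
    pheno = pd.to_numeric(df["PHENOTYPE"], errors="coerce")
    usable = pheno.isin([1.0, 2.0]).to_numpy()
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info(
            "%s: excluded %d sample(s) with missing phenotype (-9/0/NA)",
            path, n_dropped,
        )
    if not usable.any():
        raise ParseError(f"{path}: no samples with usable PHENOTYPE (1/2)")
    df = df.loc[usable].reset_index(drop=True)
    phenotype = (pd.to_numeric(df["PHENOTYPE"]).to_numpy() - 1).astype(np.int8)
    n = len(df)
    genotypes = np.full((n, len(snp_cols)), MISSING, dtype=np.int8)
    for j, col in enumerate(snp_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ~vals.isin([0, 1, 2])
        if bad.any():
            idx = int(bad.idxmax())
            raise ParseError(
                f"{path}: invalid dosage {df[col].iloc[idx]!r} in column "
                f"'{col}', data row {idx + 1}"
            )
        obs = vals.notna().to_numpy()
        genotypes[obs, j] = vals.to_numpy()[obs].astype(np.int8)
    sample_ids = (df["FID"].astype(str) + "_" + df["IID"].astype(str)).tolist()
    return GenotypeDataset(
        genotypes=genotypes,
        phenotype=phenotype,
        snp_ids=snp_ids,
        sample_ids=sample_ids,
    )


def read_genotype_table(path: str | Path, dialect: str = "tsv") -> GenotypeDataset:
    """Load a case-control genotype table.

    ``dialect`` is one of ``tsv``, ``csv`` or ``plink_raw``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    if dialect == "tsv":
        return _read_delimited(path, "\t")
    if dialect == "csv":
        return _read_delimited(path, ",")
    if dialect == "plink_raw":
        return _read_plink_raw(path)
    raise ValueError(f"unknown dialect {dialect!r}; use tsv, csv or plink_raw")


def write_genotype_table(
    dataset: GenotypeDataset, path: str | Path, dialect: str = "tsv"
) -> None:
    """Write the native delimited format (sample_id, phenotype, SNPs)."""
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"cannot write dialect {dialect!r}; use tsv or csv")
    sep = "\t" if dialect == "tsv" else ","
    g = dataset.genotypes.astype(object)
    df = pd.DataFrame(np.where(g == MISSING, pd.NA, g), columns=dataset.snp_ids)
    df.insert(0, "phenotype", dataset.phenotype)
    df.insert(0, "sample_id", dataset.sample_ids)
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


@dataclass
class RunReport:
    """Machine-readable record of one analysis run.

    Every number shown in a figure is recoverable from the report (or its
    sidecar tables); reports round-trip through JSON.
    """

    tool: str = "rigscan"
    version: str = "0.1.0"
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    command: str = ""
    seed: int | None = None
    input_digest: dict[str, Any] = field(default_factory=dict)
    scans: list[dict[str, Any]] = field(default_factory=list)
    nulls: list[dict[str, Any]] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    @staticmethod
    def digest(dataset: GenotypeDataset) -> dict[str, Any]:
        return {
            "n_samples": dataset.n_samples,
            "n_snps": dataset.n_snps,
            "n_cases": dataset.n_cases,
            "n_controls": dataset.n_controls,
            "n_missing_genotypes": int((dataset.genotypes == MISSING).sum()),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))
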