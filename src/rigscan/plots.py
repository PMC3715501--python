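"""Scree and multidimensional-scaling visualizations.

The scree plot ranks combinations by their (standardized) relative
information gain; a dotted horizontal line marks the permutation-null
alpha cutoff, and the top combination is labeled in parentheses.

The MDS plot embeds SNPs in the plane by classical (Torgerson) scaling of
the pairwise two-locus RIG matrix, so the distance between two SNPs
reflects the strength of their interaction, with marker sizes scaled to
each SNP's single-locus (main-effect) RIG.  Each figure writes a sidecar
table carrying the plotted numbers.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "classical_mds",
    "pairwise_r0_matrix",
    "scree_plot",
    "mds_plot",
]


def classical_mds(distances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling: 2-D coordinates from a symmetric distance matrix.

    Double-centers the squared distances, eigendecomposes, and keeps the
    two leading non-negative eigenpairs.  Falls back to a 1-D layout (with
    a warning) when only one non-negative eigenvalue exists.

    Returns (coordinates (p, 2), eigenvalues sorted descending).
    """
    d = np.asarray(distances, dtype=np.float64)
    p = d.shape[0]
    if d.shape != (p, p):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    j = np.eye(p) - np.ones((p, p)) / p
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-12 * abs(eigvals[0]) if eigvals.size else 0.0)
    nonneg = eigvals > tol
    coords = np.zeros((p, 2))
    n_axes = min(2, int(nonneg[:2].sum()))
    if n_axes < 2:
        warnings.warn(
            "fewer than 2 non-negative eigenvalues; 1-D MDS layout used",
            stacklevel=2,
        )
    for axis in range(n_axes):
        coords[:, axis] = eigvecs[:, axis] * np.sqrt(eigvals[axis])
    return coords, eigvals


def pairwise_r0_matrix(results: Sequence, p: int) -> np.ndarray:
    """Symmetric p x p matrix of two-locus values from an order-2 scan.

    ``results`` may hold RIGResult (uses r0) or StandardizedResult objects
    (uses u_r shifted by a constant so the minimum is zero).
    """
    mat = np.zeros((p, p))
    use_u = all(hasattr(r, "u_r") for r in results)
    vals = np.array([r.u_r if use_u else r.r0 for r in results], dtype=np.float64)
    if use_u and vals.size:
        vals = vals - vals.min()  # shift so the weakest pair has distance 0
    for r, v in zip(results, vals):
        i, j = r.snp_indices
        mat[i, j] = mat[j, i] = v
    return mat


def scree_plot(
    results: Sequence,
    cutoff: float | None = None,
    top_n: int = 100,
    out_path: str | Path = "scree.png",
    value: str = "u_r",
    snp_ids: Sequence[str] | None = None,
) -> Path:
    """Ranked-value scree plot with the alpha cutoff as a dotted line.

    ``value`` selects ``u_r`` (standardized, default) or ``r0``.  The top
    combination is annotated in parentheses.  A sidecar TSV with the same
    numbers is written next to the figure.
    """
    if not results:
        raise ValueError("results must be non-empty")
    if value not in ("u_r", "r0"):
        raise ValueError("value must be 'u_r' or 'r0'")
    vals = np.array([getattr(r, value) for r in results], dtype=np.float64)
    order = np.argsort(-vals, kind="stable")
    vals = vals[order][: max(int(top_n), 1)]
    combos = [results[i].snp_indices for i in order[: len(vals)]]
    ranks = np.arange(1, len(vals) + 1)

    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ranks, vals, "o", ms=4, color="tab:blue")
    if cutoff is not None:
        ax.axhline(cutoff, ls=":", color="black", lw=1)
    label = _combo_label(combos[0], snp_ids)
    ax.annotate(
        label, (1, vals[0]), textcoords="offset points", xytext=(6, 2), fontsize=8
    )
    ax.set_xlabel("rank")
    ax.set_ylabel("standardized RIG $U_r$" if value == "u_r" else "RIG $R_0$")
    k = len(combos[0])
    ax.set_title(f"order-{k} interactions (top {len(vals)})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    sidecar = out_path.with_suffix(".tsv")
    pd.DataFrame(
        {
            "rank": ranks,
            "snp_indices": [",".join(map(str, c)) for c in combos],
            "snp_ids": [_combo_label(c, snp_ids) for c in combos],
            value: vals,
        }
    ).to_csv(sidecar, sep="\t", index=False)
    return out_path


def _combo_label(combo: Sequence[int], snp_ids: Sequence[str] | None) -> str:
    names = [snp_ids[i] if snp_ids else str(i + 1) for i in combo]
    return "(" + ", ".join(names) + ")"


def mds_plot(
    pairwise: np.ndarray,
    main_effect: np.ndarray,
    out_path: str | Path = "mds.png",
    snp_ids: Sequence[str] | None = None,
    min_marker: float = 20.0,
    max_marker: float = 300.0,
) -> Path:
    """Classical-MDS map of SNPs from the pairwise two-locus RIG matrix.

    Marker areas are affine in the single-locus RIG values with a floor at
    ``min_marker`` so weak main effects stay visible.  Coordinates go to a
    sidecar TSV.
    """
    pairwise = np.asarray(pairwise, dtype=np.float64)
    main_effect = np.asarray(main_effect, dtype=np.float64)
    p = pairwise.shape[0]
    if main_effect.shape != (p,):
        raise ValueError("main_effect length must match the matrix size")
    coords, eigvals = classical_mds(pairwise)
    span = main_effect.max() - main_effect.min()
    if span > 0:
        sizes = min_marker + (max_marker - min_marker) * (
            (main_effect - main_effect.min()) / span
        )
    else:
        sizes = np.full(p, min_marker)

    out_path = Path(out_path)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.scatter(coords[:, 0], coords[:, 1], s=sizes, alpha=0.7, color="tab:red",
               edgecolors="black", linewidths=0.5)
    labels = snp_ids if snp_ids else [str(i + 1) for i in range(p)]
    for i, lab in enumerate(labels):
        ax.annotate(lab, coords[i], textcoords="offset points", xytext=(5, 3),
                    fontsize=8)
    ax.set_xlabel("MDS axis 1")
    ax.set_ylabel("MDS axis 2")
    ax.set_title("two-locus interaction map")
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)

    sidecar = out_path.with_suffix(".tsv")
    pd.DataFrame(
        {
            "snp": labels,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "main_effect_r0": main_effect,
            "marker_size": sizes,
        }
    ).to_csv(sidecar, sep="\t", index=False)
    return out_path
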