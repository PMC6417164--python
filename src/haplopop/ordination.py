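"""Ordination: classical (Torgerson) multidimensional scaling of corrected
pairwise-difference matrices, and PCA of haplotype frequency tables."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .hapfreq import HaplotypeFrequencyTable


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray  # (points, k)
    eigenvalues: np.ndarray  # all eigenvalues, descending (may include negatives)
    explained: np.ndarray    # variance fractions of the k reported axes
    method: str              # "MDS" | "PCA"
    loadings: Optional[pd.DataFrame] = None  # PCA only: variables x components

    def frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            eig = " ".join(f"{v:.6g}" for v in self.eigenvalues)
            fh.write(f"# method={self.method} eigenvalues={eig}\n")
            self.frame().to_csv(fh, sep="\t", index_label="label")


def classical_mds(
    distances: Union[pd.DataFrame, np.ndarray], k: int = 2, labels: Optional[list[str]] = None
) -> OrdinationResult:
    """Torgerson scaling of a symmetric distance matrix.

    Negative entries (legal for corrected pairwise differences) are clamped at
    zero before squaring; the doubly centered Gram matrix B = -1/2 J D2 J is
    eigendecomposed and coordinates come from the top-k non-negative
    eigenpairs (negative eigenvalues are reported but contribute no axis).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(D - D.T).max(initial=0.0) > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond 1e-9")
    n = D.shape[0]
    D2 = np.clip(D, 0.0, None) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = np.clip(w, 0.0, None)
    k_eff = min(k, n - 1) if n > 1 else 1
    coords = V[:, :k_eff] * np.sqrt(pos[:k_eff])
    total = pos.sum()
    explained = pos[:k_eff] / total if total > 0 else np.zeros(k_eff)
    return OrdinationResult(
        labels=labels, coordinates=coords, eigenvalues=w, explained=explained, method="MDS"
    )


def pca_frequencies(
    table: HaplotypeFrequencyTable, k: int = 2, scale: bool = False
) -> OrdinationResult:
    """PCA of a haplotype frequency table.

    Haplotypes are the observations, unit frequency columns the variables.
    Columns are centered (optionally standardized); scores come from the SVD.
    Sign convention: the largest-magnitude loading of each component is
    positive, making results deterministic.
    """
    X = table.freq.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 haplotypes and 2 units")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0):
        raise ValueError("constant frequency matrix: no variance to decompose")
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("cannot standardize a zero-variance column")
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: flip each component so its top |loading| is positive
    for c in range(Vt.shape[0]):
        top = np.argmax(np.abs(Vt[c]))
        if Vt[c, top] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    eig = (s ** 2) / (n - 1)
    k_eff = min(k, len(s), n - 1)
    scores = U[:, :k_eff] * s[:k_eff]
    total = eig.sum()
    loadings = pd.DataFrame(
        Vt[:k_eff].T, index=table.units, columns=[f"PC{i + 1}" for i in range(k_eff)]
    )
    return OrdinationResult(
        labels=table.haplotypes,
        coordinates=scores,
        eigenvalues=eig,
        explained=eig[:k_eff] / total,
        method="PCA",
        loadings=loadings,
    )
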