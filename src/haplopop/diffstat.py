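"""Corrected pairwise-difference differentiation between populations.

For two units X and Y the statistic is

    P'(X,Y) = P(X,Y) - (P(X) + P(Y)) / 2

where P(X,Y) is the mean Hamming distance over all cross pairs of haplotype
copies and P(X), P(Y) are the mean distances over unordered within-unit pairs.
Significance is assessed by permuting unit labels of the pooled copies.

All statistics are computed from per-locus allele counts: for a unit with n
copies and per-locus allele counts {c_a}, the number of differing unordered
pairs at a locus is (n^2 - sum_a c_a^2) / 2, and between units X and Y it is
n_x n_y - sum_a c_a^X c_a^Y.  This makes 10^5 label permutations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .panel import MISSING, PhasedCohort

Copies = Union[Sequence[str], np.ndarray]


@dataclass
class DiffStatResult:
    x_label: str
    y_label: str
    p_between: float
    p_within_x: float
    p_within_y: float
    p_corrected: float
    p_value: Optional[float] = None
    n_permutations: Optional[int] = None
    seed: Optional[int] = None


@dataclass
class DistanceMatrixResult:
    labels: list[str]
    p_corrected: pd.DataFrame  # symmetric, zero diagonal
    p_values: pd.DataFrame


def _encode(copies: Copies) -> np.ndarray:
    """Copies (strings or code matrix) -> (n, L) small non-negative int codes.

    Rows containing missing entries are excluded: the published data are
    complete, and excluding a copy removes exactly the pairs any of whose
    members has a missing entry.
    """
    if isinstance(copies, np.ndarray):
        X = copies
    else:
        seqs = list(copies)
        if not seqs:
            return np.empty((0, 0), dtype=np.uint8)
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("haplotype strings must have equal length")
        X = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("expected a 2-D copies matrix")
    complete = ~(X == MISSING).any(axis=1) if X.size else np.ones(0, bool)
    return X[complete]


def _one_hot(X: np.ndarray) -> np.ndarray:
    """(n, L) codes -> (n, L*A) float32 one-hot over the per-matrix alphabet."""
    _, inv = np.unique(X, return_inverse=True)
    codes = inv.reshape(X.shape)
    A = codes.max() + 1 if codes.size else 1
    n, L = codes.shape
    oh = np.zeros((n, L * A), dtype=np.float32)
    oh[np.arange(n)[:, None], np.arange(L) * A + codes] = 1.0
    return oh


def _stats_from_counts(cx: np.ndarray, nx, cy: np.ndarray, ny):
    """Per-locus-allele count blocks -> (P_between, P(X), P(Y)); vectorized.

    cx, cy: (..., L*A) allele counts; nx, ny: scalars or (...,) copy totals.
    """
    nx = np.asarray(nx, dtype=np.float64)
    ny = np.asarray(ny, dtype=np.float64)
    sum_cx2 = np.square(cx).sum(axis=-1)
    sum_cy2 = np.square(cy).sum(axis=-1)
    cross = (cx * cy).sum(axis=-1)
    # number of loci: each locus contributes exactly nx to the count total
    n_sites = np.where(nx > 0, cx.sum(axis=-1) / np.maximum(nx, 1), 0.0)
    within_x = (n_sites * np.square(nx) - sum_cx2) / 2.0
    within_y = (n_sites * np.square(ny) - sum_cy2) / 2.0
    between = n_sites * nx * ny - cross
    p_between = between / (nx * ny)
    p_wx = np.where(nx > 1, within_x / (nx * (nx - 1) / 2.0), np.nan)
    p_wy = np.where(ny > 1, within_y / (ny * (ny - 1) / 2.0), np.nan)
    return p_between, p_wx, p_wy


def mean_pairwise_within(copies: Copies) -> float:
    """Mean Hamming distance over unordered distinct pairs of copies."""
    X = _encode(copies)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete copies")
    oh = _one_hot(X)
    c = oh.sum(axis=0, dtype=np.float64)
    L = X.shape[1]
    total = (L * n * n - np.square(c).sum()) / 2.0
    return float(total / (n * (n - 1) / 2.0))


def corrected_pairwise_difference(
    x_copies: Copies, y_copies: Copies, x_label: str = "X", y_label: str = "Y"
) -> DiffStatResult:
    """P'(X,Y) = P(X,Y) - (P(X)+P(Y))/2; may legitimately be negative."""
    X, Y = _encode(x_copies), _encode(y_copies)
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValueError("each unit needs at least 2 complete copies")
    if X.shape[1] != Y.shape[1]:
        raise ValueError("units span different numbers of positions")
    pooled = np.vstack([X, Y])
    oh = _one_hot(pooled)
    nx, ny = X.shape[0], Y.shape[0]
    cx = oh[:nx].sum(axis=0, dtype=np.float64)
    cy = oh[nx:].sum(axis=0, dtype=np.float64)
    p_b, p_wx, p_wy = _stats_from_counts(cx, nx, cy, ny)
    return DiffStatResult(
        x_label=x_label, y_label=y_label,
        p_between=float(p_b), p_within_x=float(p_wx), p_within_y=float(p_wy),
        p_corrected=float(p_b - (p_wx + p_wy) / 2.0),
    )


def permutation_pvalue(
    x_copies: Copies,
    y_copies: Copies,
    n_perm: int = 100_000,
    seed: Optional[int] = None,
    x_label: str = "X",
    y_label: str = "Y",
    chunk: int = 512,
) -> DiffStatResult:
    """Label-permutation p-value for P'(X,Y).

    Pools the copies, repeatedly reassigns unit labels preserving the two
    sample sizes, and reports p = (#{permuted P' >= observed} + 1)/(n_perm+1)
    (add-one estimator; inclusive ties make the test conservative).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = corrected_pairwise_difference(x_copies, y_copies, x_label, y_label)
    X, Y = _encode(x_copies), _encode(y_copies)
    pooled = np.vstack([X, Y])
    oh = _one_hot(pooled)
    n, slots = oh.shape
    nx, ny = X.shape[0], Y.shape[0]
    ct = oh.sum(axis=0, dtype=np.float64)

    rng = np.random.default_rng(seed)
    b = 0
    done = 0
    while done < n_perm:
        r = min(chunk, n_perm - done)
        # r random nx-subsets of the pooled rows == label permutations
        keys = rng.random((r, n))
        idx = np.argpartition(keys, nx - 1, axis=1)[:, :nx]
        cx = oh[idx].sum(axis=1, dtype=np.float64)  # (r, slots)
        cy = ct[None, :] - cx
        p_b, p_wx, p_wy = _stats_from_counts(cx, float(nx), cy, float(ny))
        stat = p_b - (p_wx + p_wy) / 2.0
        b += int(np.count_nonzero(stat >= obs.p_corrected - 1e-12))
        done += r

    obs.p_value = (b + 1) / (n_perm + 1)
    obs.n_permutations = n_perm
    obs.seed = seed
    return obs


def _pair_seed(master: Optional[int], i: int, j: int) -> Optional[int]:
    if master is None:
        return None
    ss = np.random.SeedSequence([int(master), i, j])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def pairwise_distance_matrix(
    cohort: PhasedCohort,
    level: str = "population",
    n_perm: int = 100_000,
    seed: Optional[int] = None,
) -> DistanceMatrixResult:
    """P' and permutation p-values for every unordered unit pair.

    Per-pair seeds are derived from the master seed and the canonical
    (sorted-label) pair ordering, so the matrix is invariant to input order.
    """
    labels = cohort.unit_labels(level)
    units = sorted(set(labels.tolist()))
    if len(units) < 2:
        raise ValueError("need at least 2 units")
    copies = {u: cohort.matrix[labels == u] for u in units}
    for u, X in copies.items():
        if _encode(X).shape[0] < 2:
            raise ValueError(f"unit {u!r} has fewer than 2 complete haplotype copies")
    k = len(units)
    pp = np.zeros((k, k))
    pv = np.full((k, k), np.nan)
    np.fill_diagonal(pv, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            res = permutation_pvalue(
                copies[units[i]], copies[units[j]], n_perm=n_perm,
                seed=_pair_seed(seed, i, j), x_label=units[i], y_label=units[j],
            )
            pp[i, j] = pp[j, i] = res.p_corrected
            pv[i, j] = pv[j, i] = res.p_value
    return DistanceMatrixResult(
        labels=units,
        p_corrected=pd.DataFrame(pp, index=units, columns=units),
        p_values=pd.DataFrame(pv, index=units, columns=units),
    )


def write_distance_matrix(result: DistanceMatrixResult, path: str | Path) -> None:
    result.p_corrected.to_csv(path, sep="\t", index_label="unit")


def write_phylip_matrix(result: DistanceMatrixResult, path: str | Path) -> None:
    """PHYLIP-style square distance matrix export."""
    with open(path, "w") as fh:
        fh.write(f"{len(result.labels)}\n")
        for lab in result.labels:
            row = " ".join(f"{v:.6f}" for v in result.p_corrected.loc[lab])
            fh.write(f"{lab:<10s} {row}\n")
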