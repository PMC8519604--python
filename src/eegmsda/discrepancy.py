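"""Pairwise classifier discrepancy on target samples and similarity weights.

With N per-source classifiers, the discrepancy between classifiers n and m is
the mean L1 distance between their probability outputs on the same target
batch, d_nm in [0, 2].  Averaging d over the N(N-1)/2 unordered pairs gives
the unweighted statistic; the weighted loss rescales each pair term by
(1 - omega_mn), where omega_mn = d_nm / sum_{j != n} d_nj normalizes row n's
discrepancies.  Pairs of *similar* classifiers (small d) thus keep a large
(1 - omega) weight, concentrating the consensus pressure where agreement is
already plausible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "DiscrepancyTable",
    "pairwise_discrepancy",
    "unweighted_global",
    "similarity_weights",
    "global_loss",
]


@dataclass
class DiscrepancyTable:
    """d: symmetric N x N pairwise discrepancies; omega[n, m] = omega_mn."""

    d: np.ndarray
    omega: np.ndarray | None = None


def pairwise_discrepancy(probs_n, probs_m):
    """Mean absolute output difference between two classifiers, in [0, 2]."""
    a, b = as_tensor(probs_n), as_tensor(probs_m)
    plain = not (isinstance(probs_n, Tensor) or isinstance(probs_m, Tensor))
    if a.shape != b.shape:
        raise ValueError("probability matrices must share a shape")
    out = (a - b).abs().sum(axis=1).mean()
    return out.item() if plain else out


def discrepancy_table(probs: list) -> DiscrepancyTable:
    """All pairwise discrepancies plus similarity weights."""
    N = len(probs)
    d = np.zeros((N, N))
    for n in range(N):
        for m in range(n + 1, N):
            d[n, m] = d[m, n] = pairwise_discrepancy(
                probs[n].data if isinstance(probs[n], Tensor) else probs[n],
                probs[m].data if isinstance(probs[m], Tensor) else probs[m],
            )
    return DiscrepancyTable(d, similarity_weights(d))


def unweighted_global(probs: list):
    """Mean discrepancy over the N(N-1)/2 unordered classifier pairs."""
    N = len(probs)
    if N < 2:
        raise ValueError("need at least two classifiers")
    plain = not any(isinstance(p, Tensor) for p in probs)
    terms = [
        pairwise_discrepancy(as_tensor(probs[n]), as_tensor(probs[m]))
        for n in range(N)
        for m in range(n + 1, N)
    ]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    out = total * (2.0 / (N * (N - 1)))
    return out.item() if plain else out


def similarity_weights(d: np.ndarray) -> np.ndarray:
    """Row-normalized weights omega[n, m] = d_nm / sum_{j != n} d_nj.

    Rows whose off-diagonal discrepancies are all zero get the uniform
    1/(N-1) convention (their pair terms vanish anyway).
    """
    d = np.asarray(d, dtype=np.float64)
    if (d < 0).any():
        raise ValueError("discrepancies must be nonnegative")
    N = d.shape[0]
    off = d.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1, keepdims=True)
    omega = np.where(row > 0, off / np.where(row > 0, row, 1.0), 1.0 / max(N - 1, 1))
    np.fill_diagonal(omega, 0.0)
    return omega


def global_loss(probs: list, symmetrize: bool = False):
    """Similarity-weighted classifier-discrepancy loss.

    L = 2/(N(N-1)) * sum_{n<m} (1 - omega_mn) d_nm.  For N = 2 the row
    normalization forces omega = 1 and the loss would vanish identically, so
    the unweighted pair discrepancy is used instead (with a warning).  The
    weights are treated as constants when the inputs carry gradients.
    """
    N = len(probs)
    if N < 2:
        raise ValueError("need at least two classifiers")
    plain = not any(isinstance(p, Tensor) for p in probs)
    if N == 2:
        warnings.warn("N=2: similarity weights degenerate; using unweighted discrepancy")
        return unweighted_global(probs)
    table = discrepancy_table(probs)
    omega = table.omega
    if symmetrize:
        omega = 0.5 * (omega + omega.T)
    total = None
    for n in range(N):
        for m in range(n + 1, N):
            term = pairwise_discrepancy(as_tensor(probs[n]), as_tensor(probs[m]))
            term = term * float(1.0 - omega[n, m])
            total = term if total is None else total + term
    out = total * (2.0 / (N * (N - 1)))
    return out.item() if plain else out
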