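"""Gaussian-kernel MMD and its label-conditional (local) variant.

The maximum mean discrepancy (MMD) between sample sets X and Y compares mean
kernel embeddings:

    MMD^2 = 1/n^2 sum k(x_i, x_j) + 1/m^2 sum k(y_i, y_j) - 2/nm sum k(x_i, y_j)

with the Gaussian kernel k(x, y) = exp(-||x - y||^2 / (2 sigma^2)), averaged
over a bandwidth set when several sigmas are given.

The local variant aligns each class separately between every source domain
and the target.  Source samples of class c receive weight 1/(class count);
unlabeled target samples receive soft weights from a classifier's probability
column, normalized to sum to one per class.  The per-class weighted kernel
sums are averaged over classes and source domains.  Two scalings are
available: the default ``"weighted"`` mode uses the normalized weights alone
(scale-stable under batch size), while ``"literal"`` additionally applies the
1/|X|^2 pair-count prefactors of the plain MMD estimator.

All computational routines accept numpy arrays or autodiff Tensors, so the
same code path is used for analysis and inside the training objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "KernelSpec",
    "ClassWeightSet",
    "median_heuristic_sigmas",
    "kernel_matrix",
    "mmd_squared",
    "source_class_weights",
    "target_class_weights",
    "llmmd",
    "LocalMMDResult",
]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel family with one or more bandwidths."""

    family: str = "gaussian"
    sigmas: tuple = (1.0,)

    def __post_init__(self):
        if self.family != "gaussian":
            raise ValueError("only the gaussian kernel family is supported")
        if len(self.sigmas) == 0 or any(s <= 0 for s in self.sigmas):
            raise ValueError("need at least one positive bandwidth")


def median_heuristic_sigmas(X: np.ndarray, Y: np.ndarray | None = None, spread: int = 2) -> KernelSpec:
    """Bandwidth set {median distance * 2^k, k in -spread..spread}.

    The median of pairwise Euclidean distances is the standard MMD bandwidth
    heuristic; a geometric ladder around it makes the statistic sensitive at
    several scales at once.
    """
    Z = X if Y is None else np.concatenate([np.asarray(X), np.asarray(Y)])
    d2 = _sqdist(Tensor(Z), Tensor(Z)).data
    med = float(np.sqrt(np.median(d2[d2 > 0]))) if (d2 > 0).any() else 1.0
    med = max(med, 1e-6)
    return KernelSpec(sigmas=tuple(med * 2.0**k for k in range(-spread, spread + 1)))


def _sqdist(X: Tensor, Y: Tensor) -> Tensor:
    """Pairwise squared Euclidean distances, autodiff-friendly."""
    xx = (X * X).sum(axis=1, keepdims=True)
    yy = (Y * Y).sum(axis=1, keepdims=True)
    d2 = xx + yy.T - 2.0 * (X @ Y.T)
    return d2.clip_min(0.0)


def kernel_matrix(X, Y, spec: KernelSpec = KernelSpec()):
    """n x m Gaussian kernel matrix, averaged over the bandwidth set."""
    Xt, Yt = as_tensor(X), as_tensor(Y)
    plain = not (isinstance(X, Tensor) or isinstance(Y, Tensor))
    if Xt.shape[1] != Yt.shape[1]:
        raise ValueError("feature dimensions differ")
    d2 = _sqdist(Xt, Yt)
    acc = None
    for s in spec.sigmas:
        term = (d2 * (-1.0 / (2.0 * s**2))).exp()
        acc = term if acc is None else acc + term
    out = acc * (1.0 / len(spec.sigmas))
    return out.data if plain else out


def mmd_squared(X, Y, spec: KernelSpec = KernelSpec()):
    """Squared MMD between two sample sets (biased V-statistic estimator)."""
    Xt, Yt = as_tensor(X), as_tensor(Y)
    plain = not (isinstance(X, Tensor) or isinstance(Y, Tensor))
    if Xt.shape[0] == 0 or Yt.shape[0] == 0:
        raise ValueError("empty sample set")
    out = (
        kernel_matrix(Xt, Xt, spec).mean()
        + kernel_matrix(Yt, Yt, spec).mean()
        - 2.0 * kernel_matrix(Xt, Yt, spec).mean()
    )
    return out.item() if plain else out


@dataclass
class ClassWeightSet:
    """Per-class, per-sample weights; each non-empty class column sums to 1."""

    weights: np.ndarray  # n x C, column c holds the class-c weights
    empty: np.ndarray    # length-C flags: class has no mass in this batch

    @property
    def n_classes(self) -> int:
        return self.weights.shape[1]

    def class_weights(self, c: int) -> np.ndarray:
        """Compact weight vector over the members of class c (hard labels)."""
        col = self.weights[:, c]
        return col[col > 0]


def source_class_weights(labels_onehot: np.ndarray) -> ClassWeightSet:
    """Hard label weights: sample i of class c gets 1 / (count of class c)."""
    y = np.asarray(labels_onehot, dtype=np.float64)
    if y.ndim != 2:
        raise ValueError("labels must be a one-hot n x C matrix")
    if not np.allclose(y.sum(axis=1), 1.0) or ((y != 0) & (y != 1)).any():
        raise ValueError("each row must be one-hot")
    counts = y.sum(axis=0)
    empty = counts == 0
    w = y / np.where(empty, 1.0, counts)
    return ClassWeightSet(w, empty)


def target_class_weights(probs: np.ndarray) -> ClassWeightSet:
    """Soft pseudo-label weights: phi_i^c = p_i^c / sum_j p_j^c."""
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("probs must be n x C")
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    mass = p.sum(axis=0)
    empty = mass == 0
    w = p / np.where(empty, 1.0, mass)
    w[:, empty] = 0.0
    return ClassWeightSet(w, empty)


@dataclass
class LocalMMDResult:
    total: object           # float or Tensor
    per_domain: list        # one float/Tensor per source domain
    skipped: list           # (domain index, class) pairs absent on both sides


def llmmd(
    source_feats: list,
    source_labels: list,
    target_feats,
    target_probs,
    spec: KernelSpec = KernelSpec(),
    mode: str = "weighted",
) -> LocalMMDResult:
    """Local label-conditional MMD between each source domain and the target.

    Parameters
    ----------
    source_feats, source_labels
        Per-domain feature matrices and one-hot labels.
    target_feats
        Target features; a single matrix shared by all domains or a list of
        per-domain matrices (one per domain-specific feature space).
    target_probs
        Per-domain classifier probability matrices for the target (list), or
        a single matrix used for every pair.  Weights derived from them are
        treated as constants (detached) so pseudo-labels cannot
        self-reinforce through the weight terms.
    mode
        ``"weighted"`` (default) or ``"literal"`` (adds 1/|X|^2 prefactors).
    """
    if mode not in ("weighted", "literal"):
        raise ValueError("mode must be 'weighted' or 'literal'")
    n_dom = len(source_feats)
    if n_dom == 0:
        raise ValueError("need at least one source domain")
    if not isinstance(target_feats, (list, tuple)):
        target_feats = [target_feats] * n_dom
    if not isinstance(target_probs, (list, tuple)):
        target_probs = [target_probs] * n_dom

    plain = not any(
        isinstance(t, Tensor) for t in list(source_feats) + list(target_feats)
    )
    per_domain, skipped = [], []
    for n in range(n_dom):
        Xs = as_tensor(source_feats[n])
        Xt = as_tensor(target_feats[n])
        ws = source_class_weights(source_labels[n])
        p = target_probs[n]
        wt = target_class_weights(p.data if isinstance(p, Tensor) else p)
        C = ws.n_classes
        Kss = kernel_matrix(Xs, Xs, spec)
        Kst = kernel_matrix(Xs, Xt, spec)
        Ktt = kernel_matrix(Xt, Xt, spec)
        ns, nt = Xs.shape[0], Xt.shape[0]
        dom_total = None
        for c in range(C):
            if ws.empty[c] and wt.empty[c]:
                skipped.append((n, c))
                continue
            a = Tensor(ws.weights[:, c : c + 1])  # ns x 1, constants
            b = Tensor(wt.weights[:, c : c + 1])  # nt x 1, detached
            t_ss = (a.T @ Kss @ a).reshape(())
            t_st = (a.T @ Kst @ b).reshape(())
            t_tt = (b.T @ Ktt @ b).reshape(())
            if mode == "literal":
                term = t_ss * (1.0 / ns**2) - t_st * (2.0 / (ns * nt)) + t_tt * (1.0 / nt**2)
            else:
                term = t_ss - 2.0 * t_st + t_tt
            dom_total = term if dom_total is None else dom_total + term
        if dom_total is None:
            warnings.warn(f"domain {n}: no class present on either side")
            dom_total = Tensor(0.0)
        per_domain.append(dom_total * (1.0 / C))
    total = per_domain[0]
    for t in per_domain[1:]:
        total = total + t
    total = total * (1.0 / n_dom)
    if plain:
        return LocalMMDResult(total.item(), [t.item() for t in per_domain], skipped)
    return LocalMMDResult(total, per_domain, skipped)
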