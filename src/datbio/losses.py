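"""Distances and margin losses for Siamese and triplet metric learning.

``pair_distance`` is the Euclidean (L2) distance between two embeddings.
The contrastive loss pulls same-class pairs together and pushes
different-class pairs beyond a margin *m*; the triplet loss requires each
anchor to sit closer (in squared distance) to its positive than to its
negative by at least a margin *alpha*.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["pair_distance", "contrastive_loss", "triplet_distances",
           "triplet_loss"]


def pair_distance(fA: np.ndarray, fB: np.ndarray) -> float:
    """Euclidean distance ``sqrt(sum_i (f(A)_i - f(B)_i)^2)``."""
    fA = np.asarray(fA, dtype=float)
    fB = np.asarray(fB, dtype=float)
    if fA.shape != fB.shape:
        raise ValueError(f"dimension mismatch: {fA.shape} vs {fB.shape}")
    return float(np.linalg.norm(fA - fB))


def contrastive_loss(D: float, Y: int, m: float, as_printed: bool = False) -> float:
    """Contrastive loss for one pair at distance *D* with label *Y*.

    With the default convention (Y=1 means same class)::

        L = 1/2 * Y * D^2  +  1/2 * (1 - Y) * max(0, m - D)^2

    i.e. same-class pairs are pulled to distance 0 and different-class
    pairs pushed beyond the margin *m*.  ``as_printed=True`` swaps the two
    terms (the hinge acts on same-class pairs instead), a published
    variant of the formula kept for comparison.
    """
    if Y not in (0, 1):
        raise ValueError(f"Y must be 0 or 1, got {Y}")
    if D < 0:
        raise ValueError("distance must be non-negative")
    if m <= 0:
        raise ValueError("margin m must be positive")
    attract = 0.5 * D**2
    repel = 0.5 * max(0.0, m - D) ** 2
    if as_printed:
        return (1 - Y) * attract + Y * repel
    return Y * attract + (1 - Y) * repel


def triplet_distances(e_a: np.ndarray, e_p: np.ndarray,
                      e_n: np.ndarray) -> tuple[float, float]:
    """Anchor-positive and anchor-negative Euclidean distances."""
    return pair_distance(e_a, e_p), pair_distance(e_a, e_n)


def triplet_loss(e_a: np.ndarray, e_p: np.ndarray, e_n: np.ndarray,
                 alpha: float, reduction: str = "sum") -> float:
    """Hinged triplet loss over a batch of embedded triplets.

        L = sum_i [ ||a_i - p_i||^2 - ||a_i - n_i||^2 + alpha ]_+

    where ``[z]_+ = max(z, 0)``.  Inputs are (N, dim) arrays (or single
    vectors); an empty batch returns 0 with a warning.
    """
    if alpha <= 0:
        raise ValueError("margin alpha must be positive")
    e_a, e_p, e_n = (np.atleast_2d(np.asarray(e, dtype=float))
                     for e in (e_a, e_p, e_n))
    if not (e_a.shape == e_p.shape == e_n.shape):
        raise ValueError("anchor/positive/negative shapes must match")
    if e_a.shape[0] == 0:
        warnings.warn("empty triplet batch; loss is 0", stacklevel=2)
        return 0.0
    d_ap2 = np.sum((e_a - e_p) ** 2, axis=1)
    d_an2 = np.sum((e_a - e_n) ** 2, axis=1)
    hinge = np.maximum(d_ap2 - d_an2 + alpha, 0.0)
    if reduction == "sum":
        return float(hinge.sum())
    if reduction == "mean":
        return float(hinge.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def triplet_loss_grads(e_a, e_p, e_n, alpha: float):
    """Gradients of the mean triplet loss w.r.t. the three embedding sets."""
    n = e_a.shape[0]
    d_ap2 = np.sum((e_a - e_p) ** 2, axis=1)
    d_an2 = np.sum((e_a - e_n) ** 2, axis=1)
    active = (d_ap2 - d_an2 + alpha > 0).astype(float)[:, None] / n
    ga = 2.0 * active * ((e_n - e_p))
    gp = -2.0 * active * (e_a - e_p)
    gn = 2.0 * active * (e_a - e_n)
    return ga, gp, gn


def contrastive_loss_grads(e1, e2, y, m: float):
    """Gradients of the mean contrastive loss w.r.t. both embedding sets.

    *y* is a (N,) binary array, 1 = same class.
    """
    n = e1.shape[0]
    diff = e1 - e2
    d = np.linalg.norm(diff, axis=1)
    safe_d = np.maximum(d, 1e-12)
    same = y[:, None].astype(float)
    hinge_active = ((m - d) > 0).astype(float)
    # d/de1 of 1/2 d^2 is diff; of 1/2 max(0, m-d)^2 is -(m-d) * diff / d
    g_same = diff
    g_diff = -((m - d) * hinge_active / safe_d)[:, None] * diff
    g1 = (same * g_same + (1 - same) * g_diff) / n
    return g1, -g1
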