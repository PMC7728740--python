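"""Genomic relationship matrices and the RKHS Gaussian kernel.

The additive matrix is the VanRaden construction on allele-frequency-centered
dosages; the dominance matrix uses the heterozygosity-deviation (Su-style)
coding; the Gaussian kernel exponentiates pairwise squared Euclidean distances
normalized to [0, 1] by their maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "additive_relationship",
    "dominance_relationship",
    "gaussian_kernel",
]

PSD_JITTER = 1e-8


@dataclass
class RelationshipMatrix:
    """Symmetric n x n sample-similarity matrix of a given kind."""

    sample_ids: list[str]
    values: np.ndarray
    kind: str  # additive | dominance | gaussian
    bandwidth_h: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def jittered(self, eps: float = PSD_JITTER) -> np.ndarray:
        """Copy with eps added to the diagonal (PSD repair for factorizations)."""
        V = self.values.copy()
        V[np.diag_indices_from(V)] += eps
        return V


def additive_relationship(G: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden additive GRM: A = WW' / (2 sum p_i q_i), W = dosage - 2p_i."""
    X = G.dosage
    pfreq = G.allele_freq
    q = 1.0 - pfreq
    denom = 2.0 * np.sum(pfreq * q)
    if denom <= 0:
        raise ValueError("all markers monomorphic: additive GRM denominator is zero")
    W = X - 2.0 * pfreq
    A = (W @ W.T) / denom
    return RelationshipMatrix(list(G.sample_ids), A, kind="additive")


def dominance_relationship(G: GenotypeMatrix) -> RelationshipMatrix:
    """Dominance GRM from heterozygosity deviations.

    W_d column i = 1{dosage == 1} - 2 p_i q_i;
    D = W_d W_d' / sum_i 2 p_i q_i (1 - 2 p_i q_i).
    """
    X = G.dosage
    pfreq = G.allele_freq
    q = 1.0 - pfreq
    two_pq = 2.0 * pfreq * q
    denom = np.sum(two_pq * (1.0 - two_pq))
    if denom <= 0:
        raise ValueError("dominance GRM denominator is zero (no heterozygosity)")
    het = np.where(np.abs(X - 1.0) < 1e-9, 1.0, 0.0)
    Wd = het - two_pq
    D = (Wd @ Wd.T) / denom
    return RelationshipMatrix(list(G.sample_ids), D, kind="dominance")


def gaussian_kernel(G: GenotypeMatrix, h: float = 0.5) -> RelationshipMatrix:
    """RKHS Gaussian kernel K = exp(-h * d2_norm) with d2 max-normalized to [0,1]."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    if G.n_samples < 2:
        raise ValueError("gaussian kernel requires at least 2 samples")
    d2 = squareform(pdist(G.dosage, metric="sqeuclidean"))
    m = d2.max()
    if m > 0:
        d2 = d2 / m
    K = np.exp(-h * d2)
    np.fill_diagonal(K, 1.0)
    return RelationshipMatrix(list(G.sample_ids), K, kind="gaussian", bandwidth_h=h)


def gaussian_cross_kernel(
    G_new: GenotypeMatrix, G_train: GenotypeMatrix, h: float = 0.5
) -> np.ndarray:
    """Kernel block between new and training samples, normalized by the
    training set's maximum pairwise squared distance (the training kernel's scale)."""
    d2_train = pdist(G_train.dosage, metric="sqeuclidean")
    m = d2_train.max() if d2_train.size else 0.0
    diff2 = (
        np.sum(G_new.dosage**2, axis=1)[:, None]
        + np.sum(G_train.dosage**2, axis=1)[None, :]
        - 2.0 * G_new.dosage @ G_train.dosage.T
    )
    diff2 = np.maximum(diff2, 0.0)
    if m > 0:
        diff2 = diff2 / m
    return np.exp(-h * diff2)
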