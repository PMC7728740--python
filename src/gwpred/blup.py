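"""GBLUP and RKHS kernel prediction via Henderson's mixed-model equations.

Genetic values are BLUPs at plugged-in variance ratios: g_k = sigma_k^2 K_k
V^-1 (y - 1*mu) with V = sum_k sigma_k^2 K_k + sigma_e^2 I and mu the GLS
intercept. Held-out samples are predicted by kernel interpolation
g_new = K_cross K_train^-1 g_train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PhenotypeTable
from .kinship import RelationshipMatrix
from .reml import VarianceComponents, fit_reml

__all__ = ["GeneticValues", "fit_kernel_blup", "predict_blup"]


@dataclass
class GeneticValues:
    """Fitted mixed-model genetic values and their per-kernel components."""

    sample_ids: list[str]
    mu: float
    values: np.ndarray
    components: dict[str, np.ndarray]
    vc_used: VarianceComponents
    kernels: list[RelationshipMatrix] = field(repr=False, default_factory=list)


def fit_kernel_blup(
    y: PhenotypeTable | np.ndarray,
    kernels: RelationshipMatrix | list[RelationshipMatrix],
    vc: VarianceComponents | None = None,
) -> GeneticValues:
    """Solve the mixed-model equations for one or two genetic kernels.

    If ``vc`` is not supplied it is estimated by :func:`fit_reml` on the same
    kernels. Kernel diagonals get a 1e-8 jitter before inversion.
    """
    if isinstance(kernels, RelationshipMatrix):
        kernels = [kernels]
    yv = y.value if isinstance(y, PhenotypeTable) else np.asarray(y, dtype=float)
    n = yv.size
    for K in kernels:
        if K.n != n:
            raise ValueError("kernel not aligned to phenotype samples")
    if vc is None:
        vc = fit_reml(yv, kernels)
    if len(vc.values) != len(kernels) + 1:
        raise ValueError("variance components do not match the kernel list")

    sige = max(vc.sigma2_e, 1e-12)
    V = sige * np.eye(n)
    for k, K in enumerate(kernels):
        V += vc.values[k] * K.jittered()
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular mixed-model coefficient matrix: {exc}")
    ones = np.ones(n)
    mu = float(ones @ Vinv @ yv) / float(ones @ Vinv @ ones)
    r = Vinv @ (yv - mu)
    components = {}
    for k, K in enumerate(kernels):
        name = K.kind if K.kind not in components else f"{K.kind}{k}"
        components[name] = vc.values[k] * (K.jittered() @ r)
    total = np.sum(list(components.values()), axis=0)
    sample_ids = kernels[0].sample_ids
    return GeneticValues(list(sample_ids), mu, total, components, vc, list(kernels))


def predict_blup(
    fit: GeneticValues, K_cross: np.ndarray | list[np.ndarray]
) -> np.ndarray:
    """Predict new samples from kernel blocks against the training samples.

    ``K_cross`` holds, per kernel (same order as in the fit), the n_new x
    n_train matrix of kernel values between new and training samples. Returns
    mu + sum_k K_cross_k K_train_k^-1 g_k.
    """
    if isinstance(K_cross, np.ndarray):
        K_cross = [K_cross]
    if len(K_cross) != len(fit.kernels):
        raise ValueError("one cross-kernel block per training kernel required")
    n_train = len(fit.sample_ids)
    pred = None
    for Kc, K, g in zip(K_cross, fit.kernels, fit.components.values()):
        Kc = np.asarray(Kc, dtype=float)
        if Kc.ndim != 2 or Kc.shape[1] != n_train:
            raise ValueError(
                f"cross-kernel block must have {n_train} columns, got {Kc.shape}"
            )
        g_new = Kc @ np.linalg.solve(K.jittered(), g)
        pred = g_new if pred is None else pred + g_new
    return fit.mu + pred
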