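"""Back-solving per-SNP effects from predicted genetic values (DL-GWAS).

Given fitted/predicted genetic values a-hat from any model and the marker
design Z, per-SNP effects are the weighted minimum-norm solution
u = D Z' (Z D Z')^-1 a-hat, with the diagonal weight matrix D re-estimated
iteratively from the squared effects times 2 p_i (1 - p_i) and renormalized to
trace p. Three iterations sharpen large effects against the background, which
is what makes the trajectory usable for QTL discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix

__all__ = ["EffectTrajectory", "backsolve_effects", "call_qtl"]


@dataclass
class EffectTrajectory:
    """Per-iteration back-solved effects u_t and the D diagonals that produced them."""

    marker_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    u_by_iteration: list[np.ndarray]
    D_diag_by_iteration: list[np.ndarray]  # D_t used to compute u_t (D_0 = I first)
    a_hat: np.ndarray
    p_i: np.ndarray

    def effects(self, iteration: int = 3) -> np.ndarray:
        if not 1 <= iteration <= len(self.u_by_iteration):
            raise ValueError(f"iteration must be in 1..{len(self.u_by_iteration)}")
        return self.u_by_iteration[iteration - 1]


def backsolve_effects(
    G: GenotypeMatrix,
    a_hat: np.ndarray,
    n_iterations: int = 3,
    ridge_jitter: float | None = None,
    center: bool = True,
) -> EffectTrajectory:
    """Iteratively back-solve SNP effects from genetic values.

    Starting from D_0 = I, each iteration computes
    u_t = D_t Z' (Z D_t Z' + jitter I)^-1 a-hat, then re-weights
    D*_{t+1} = diag(u_i^2 * 2 p_i (1 - p_i)) and renormalizes to trace p.
    ``ridge_jitter`` defaults to 1e-8 * mean(diag(Z D Z')); pass 0 for the
    exact interpolating solution. ``center=False`` uses the raw 0/1/2 design.
    """
    X = G.dosage
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    a = np.asarray(a_hat, dtype=float)
    if a.size != n:
        raise ValueError("a_hat length must equal sample count")
    a = a - a.mean()
    pfreq = G.allele_freq
    Z = X - 2.0 * pfreq if center else X.copy()
    two_pq = 2.0 * pfreq * (1.0 - pfreq)

    D = np.ones(p)
    u_list: list[np.ndarray] = []
    D_list: list[np.ndarray] = []
    for _ in range(n_iterations):
        ZD = Z * D
        M = ZD @ Z.T
        jitter = ridge_jitter
        if jitter is None:
            jitter = 1e-8 * float(np.mean(np.diag(M)))
        if jitter:
            M = M + jitter * np.eye(n)
        try:
            if jitter:
                x = np.linalg.solve(M, a)
            else:
                # column centering makes Z D Z' exactly singular (1 in its null
                # space); the minimum-norm solve is the right generalized inverse
                x = np.linalg.lstsq(M, a, rcond=None)[0]
            u = ZD.T @ x
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"Z D Z' numerically singular even with jitter={jitter}: {exc}"
            )
        u_list.append(u)
        D_list.append(D.copy())
        D_star = u**2 * two_pq
        tr = D_star.sum()
        if tr == 0.0:  # all effects zero: weights undefined, stop early
            break
        D = (p / tr) * D_star
    return EffectTrajectory(
        marker_ids=list(G.marker_ids),
        chrom=G.chrom.copy(),
        pos=G.pos.copy(),
        u_by_iteration=u_list,
        D_diag_by_iteration=D_list,
        a_hat=a,
        p_i=pfreq.copy(),
    )


def call_qtl(
    traj: EffectTrajectory, threshold: float, iteration: int = 3
) -> list[tuple[str, str, int, float]]:
    """Markers with |u| > threshold at the chosen iteration, largest first.

    Returns (marker_id, chrom, pos, effect) tuples. The threshold is
    trait-specific and deliberately a required user input.
    """
    u = traj.effects(iteration)
    hits = np.flatnonzero(np.abs(u) > threshold)
    order = hits[np.argsort(-np.abs(u[hits]))]
    return [
        (traj.marker_ids[j], str(traj.chrom[j]), int(traj.pos[j]), float(u[j]))
        for j in order
    ]
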