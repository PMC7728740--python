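"""REML variance components and heritability ratios.

Fits y = 1*mu + sum_k g_k + e with g_k ~ N(0, K_k sigma_k^2) by restricted
maximum likelihood: expectation-maximization steps (monotone, boundary-safe)
refined by average-information (AI) Newton steps once the iterate is in the
interior. Standard errors come from the inverse AI matrix; ratio standard
errors use the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PhenotypeTable
from .kinship import RelationshipMatrix

__all__ = ["VarianceComponents", "RemlError", "fit_reml", "heritability_ratios"]


class RemlError(RuntimeError):
    """REML failure; carries the last iterate when available."""

    def __init__(self, message: str, last: "VarianceComponents | None" = None):
        super().__init__(message)
        self.last = last


@dataclass
class VarianceComponents:
    """Estimated variance components. The residual is always the last entry."""

    names: list[str]
    values: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n_used: int
    n_iter: int
    converged: bool = True
    loglik_trace: np.ndarray | None = None

    @property
    def sigma2_a(self) -> float:
        return float(self.values[0])

    @property
    def sigma2_d(self) -> float | None:
        return float(self.values[1]) if len(self.values) > 2 else None

    @property
    def sigma2_e(self) -> float:
        return float(self.values[-1])


def _reml_pieces(y: np.ndarray, Ks: list[np.ndarray], theta: np.ndarray):
    """P matrix, Py, and restricted log-likelihood at theta."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for k, K in enumerate(Ks):
        V += theta[k] * K
    Vinv = np.linalg.inv(V)
    X = np.ones((n, 1))
    XtViX = X.T @ Vinv @ X
    P = Vinv - (Vinv @ X) @ np.linalg.solve(XtViX, X.T @ Vinv)
    Py = P @ y
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        raise RemlError("V not positive definite")
    ll = -0.5 * (logdetV + np.log(XtViX[0, 0]) + float(y @ Py))
    return P, Py, ll


def fit_reml(
    y: PhenotypeTable | np.ndarray,
    kernels: RelationshipMatrix | list[RelationshipMatrix],
    max_iter: int = 100,
    tol: float = 1e-6,
    method: str = "ai",
    n_em_warmup: int = 5,
) -> VarianceComponents:
    """Estimate variance components for one or two genetic kernels + residual.

    ``method='ai'`` runs EM warm-up iterations then AI steps with an EM
    fallback whenever an AI step leaves the parameter space or decreases the
    restricted likelihood. ``method='em'`` runs pure EM (monotone likelihood).
    Components are constrained to >= 1e-6 * var(y).
    """
    if isinstance(kernels, RelationshipMatrix):
        kernels = [kernels]
    yv = y.value if isinstance(y, PhenotypeTable) else np.asarray(y, dtype=float)
    if np.isnan(yv).any():
        raise ValueError("phenotype contains missing values")
    n = yv.size
    if n < 30:
        raise ValueError("REML requires n >= 30")
    for K in kernels:
        if K.n != n:
            raise ValueError("kernel not aligned to phenotype samples")
    Ks = [K.jittered() for K in kernels]
    names = [K.kind for K in kernels] + ["residual"]
    m = len(Ks) + 1
    vary = yv.var()
    bound = 1e-6 * vary
    theta = np.full(m, vary / m)

    def scores_and_ai(P, Py):
        designs = Ks + [np.eye(n)]
        KPy = [K @ Py for K in designs]
        score = np.array(
            [-0.5 * (np.sum(P * K) - Py @ K @ Py) for K in designs]
        )  # tr(PK) via elementwise product (P, K symmetric)
        AI = np.empty((m, m))
        PKPy = [P @ v for v in KPy]
        for i in range(m):
            for j in range(i, m):
                AI[i, j] = AI[j, i] = 0.5 * KPy[i] @ PKPy[j]
        return score, AI

    def em_step(theta, P, Py):
        new = theta.copy()
        designs = Ks + [np.eye(n)]
        for i, K in enumerate(designs):
            upd = theta[i] + (theta[i] ** 2 / n) * (Py @ K @ Py - np.sum(P * K))
            new[i] = max(upd, bound)
        return new

    P, Py, ll = _reml_pieces(yv, Ks, theta)
    score0, AI0 = scores_and_ai(P, Py)
    if np.linalg.cond(AI0) > 1e12:
        raise RemlError(
            "singular kernel set: variance components are not identifiable "
            "(e.g. a kernel proportional to the identity aliases the residual)"
        )

    trace = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        if method == "em" or it <= n_em_warmup:
            theta_new = np.maximum(em_step(theta, P, Py), bound)
            P_new, Py_new, ll_new = _reml_pieces(yv, Ks, theta_new)
        else:
            score, AI = scores_and_ai(P, Py)
            theta_ai = None
            try:
                step = np.linalg.solve(AI, score)
                theta_ai = theta + step
                if np.any(theta_ai < bound):
                    # clamp offending components to the boundary and take the
                    # AI step in the remaining coordinates only
                    fixed = theta_ai < bound
                    theta_ai = theta.copy()
                    theta_ai[fixed] = bound
                    free = ~fixed
                    if free.any():
                        sub = np.linalg.solve(AI[np.ix_(free, free)], score[free])
                        theta_ai[free] = np.maximum(theta[free] + sub, bound)
            except np.linalg.LinAlgError:
                theta_ai = None
            # AI step with halving; EM (monotone) as the last resort
            candidates = []
            if theta_ai is not None:
                full = theta_ai - theta
                candidates += [
                    np.maximum(theta + full / 2**k, bound) for k in range(5)
                ]
            candidates.append(np.maximum(em_step(theta, P, Py), bound))
            for cand in candidates:
                P_new, Py_new, ll_new = _reml_pieces(yv, Ks, cand)
                theta_new = cand
                if ll_new >= ll - 1e-8:
                    break
        delta = ll_new - ll
        theta_change = np.max(np.abs(theta_new - theta))
        theta, P, Py, ll = theta_new, P_new, Py_new, ll_new
        trace.append(ll)
        # parameter-change criterion matters at the zero boundary, where the
        # likelihood flattens long before the EM fallback steps become tiny
        if (abs(delta) < tol or theta_change < 1e-8 * vary) and it > n_em_warmup:
            converged = True
            break

    _, AI = scores_and_ai(P, Py)
    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((m, m), np.nan)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    vc = VarianceComponents(
        names=names,
        values=theta,
        se=se,
        cov=cov,
        loglik=ll,
        n_used=n,
        n_iter=len(trace) - 1,
        converged=converged,
        loglik_trace=np.array(trace),
    )
    if not converged and method != "em":
        raise RemlError(f"REML did not converge in {max_iter} iterations", last=vc)
    return vc


def heritability_ratios(vc: VarianceComponents, mode: str = "narrow") -> dict:
    """Heritability ratios with delta-method standard errors.

    narrow: h2 = s_a / (s_a + s_e)  (one genetic kernel).
    broad_with_ratios: H2 = (s_a + s_d) / T, ha2 = s_a / T, hd2 = s_d / T with
    T = s_a + s_d + s_e (two genetic kernels); ha2 + hd2 == H2 by construction.
    """
    v = vc.values
    C = vc.cov

    def delta_se(grad: np.ndarray) -> float:
        return float(np.sqrt(max(grad @ C @ grad, 0.0)))

    if mode == "narrow":
        if len(v) != 2:
            raise ValueError("narrow mode expects exactly one genetic kernel")
        sa, se_ = v
        T = sa + se_
        if T <= 0:
            raise ValueError("zero total variance")
        h2 = sa / T
        grad = np.array([se_ / T**2, -sa / T**2])
        return {"h2": h2, "h2_se": delta_se(grad)}
    if mode == "broad_with_ratios":
        if len(v) != 3:
            raise ValueError("broad mode expects two genetic kernels")
        sa, sd, se_ = v
        T = sa + sd + se_
        if T <= 0:
            raise ValueError("zero total variance")
        H2 = (sa + sd) / T
        ha2 = sa / T
        hd2 = sd / T
        g_H2 = np.array([se_ / T**2, se_ / T**2, -(sa + sd) / T**2])
        g_ha = np.array([(sd + se_) / T**2, -sa / T**2, -sa / T**2])
        g_hd = np.array([-sd / T**2, (sa + se_) / T**2, -sd / T**2])
        return {
            "H2": H2,
            "H2_se": delta_se(g_H2),
            "ha2": ha2,
            "ha2_se": delta_se(g_ha),
            "hd2": hd2,
            "hd2_se": delta_se(g_hd),
        }
    raise ValueError(f"unknown mode {mode!r}")
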