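"""Single-site Gibbs samplers for the Bayesian alphabet (BRR, BL, Bayes A/B/Cpi).

All five models share the linear model y_i = mu + sum_j W_ij a_j (+ H_ij d_j)
+ e_i on the allele-frequency-centered 0/1/2 additive design (and the centered
{0,1,0} heterozygosity design for dominance) and differ only in the prior on
the additive marker effects:

* BRR      a_j ~ N(0, s2a) with a common scaled-inv-chi2 variance;
* BL       a_j ~ double-exponential via the normal/exponential mixture
           a_j | tau_j^2 ~ N(0, tau_j^2 s2e), tau_j^2 ~ Exp(lambda^2/2);
* Bayes A  a_j ~ N(0, s2a_j), marker-specific scaled-inv-chi2 variances;
* Bayes B  spike-and-slab with fixed null proportion pi and marker-specific
           slab variances;
* Bayes C-pi  spike-and-slab with a common slab variance and pi sampled under
           a uniform Beta prior.

The sweep kernel is numba-compiled; a fixed seed makes chains reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .io import GenotypeMatrix, PhenotypeTable

__all__ = ["GibbsConfig", "PosteriorSummary", "run_gibbs", "posterior_predict"]

_MODEL_CODES = {"BRR": 0, "BL": 1, "BayesA": 2, "BayesB": 3, "BayesCpi": 4}


@dataclass
class GibbsConfig:
    """Chain settings and prior hyperparameters for one Gibbs run.

    ``S_a``/``S_e`` default (None) to scales whose prior mode is half the
    phenotypic variance split across markers / assigned to the residual. The
    study-scale chain (1e6 iterations, 1e5 burn-in, thin 50) is available as
    ``GibbsConfig.study_scale()``; the default is a desk-scale chain.
    """

    model: str = "BRR"
    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    df_a: float = 5.0
    S_a: float | None = None
    df_e: float = 5.0
    S_e: float | None = None
    pi0: float = 0.95
    lambda_shape: float = 1.1
    lambda_rate: float = 0.1
    use_dominance: bool = False
    fix_marker_var: float | None = None
    fix_resid_var: float | None = None
    save_effect_samples: bool = False

    def __post_init__(self) -> None:
        if self.model not in _MODEL_CODES:
            raise ValueError(f"unknown model {self.model!r}; one of {sorted(_MODEL_CODES)}")
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must be in [0, 1]")
        if self.df_a <= 0 or self.df_e <= 0:
            raise ValueError("prior degrees of freedom must be > 0")

    @classmethod
    def study_scale(cls, model: str = "BRR", **kw) -> "GibbsConfig":
        return cls(model=model, n_iter=1_000_000, burn_in=100_000, thin=50, **kw)

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSummary:
    """Posterior means over kept Gibbs samples."""

    mu: float
    add_effects: np.ndarray
    dom_effects: np.ndarray | None
    marker_var: float
    resid_var: float
    pi: float | None
    inclusion_prob: np.ndarray | None
    fitted_genetic_values: np.ndarray
    n_samples_kept: int
    marker_ids: list[str]
    train_allele_freq: np.ndarray
    model: str
    effect_samples: np.ndarray | None = field(default=None, repr=False)


@njit(cache=True)
def _inv_gaussian(mu: float, lam: float) -> float:
    nu = np.random.normal()
    yy = nu * nu
    x = mu + (mu * mu * yy) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * yy + mu * mu * yy * yy
    )
    if x <= 0.0:
        return mu * mu / max(mu * 1e-12, 1e-300)
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _gibbs_core(
    W,
    Hd,
    y,
    model_code,
    n_iter,
    burn_in,
    thin,
    seed,
    df_a,
    S_a,
    df_e,
    S_e,
    pi0,
    lambda_shape,
    lambda_rate,
    use_dom,
    fix_marker_var,
    fix_resid_var,
    save_samples,
):
    np.random.seed(seed)
    n, p = W.shape
    pd_ = Hd.shape[1]
    wtw = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        wtw[j] = s
    htj = np.empty(pd_)
    for j in range(pd_):
        s = 0.0
        for i in range(n):
            s += Hd[i, j] * Hd[i, j]
        htj[j] = s

    mu = y.mean()
    a = np.zeros(p)
    d = np.zeros(pd_)
    vary = y.var()
    sigma2_e = 0.5 * vary if fix_resid_var <= 0.0 else fix_resid_var
    sigma2_a = df_a * S_a / (df_a + 2.0) if fix_marker_var <= 0.0 else fix_marker_var
    sigma2_aj = np.full(p, sigma2_a)
    sigma2_d = sigma2_a
    tau2 = np.ones(p)
    lam2 = lambda_shape / lambda_rate
    pi = pi0
    delta = np.ones(p)
    if model_code == 3 or model_code == 4:
        delta[:] = 0.0
        a[:] = 0.0

    e = y - mu  # residual (a and d start at zero)

    n_kept = (n_iter - burn_in) // thin
    sum_mu = 0.0
    sum_a = np.zeros(p)
    sum_d = np.zeros(pd_)
    sum_s2a = 0.0
    sum_s2e = 0.0
    sum_pi = 0.0
    sum_delta = np.zeros(p)
    samples = np.zeros((n_kept if save_samples else 1, p))
    kept = 0

    for it in range(1, n_iter + 1):
        # intercept (flat prior)
        em = 0.0
        for i in range(n):
            em += e[i]
        em /= n
        mu_new = mu + em + np.random.normal() * np.sqrt(sigma2_e / n)
        shift = mu_new - mu
        for i in range(n):
            e[i] -= shift
        mu = mu_new

        # additive effects, single site
        for j in range(p):
            if wtw[j] == 0.0:
                continue
            rhs = 0.0
            for i in range(n):
                rhs += W[i, j] * e[i]
            rhs += wtw[j] * a[j]
            if model_code == 0:  # BRR
                prec = wtw[j] + sigma2_e / sigma2_a
                mean = rhs / prec
                a_new = mean + np.random.normal() * np.sqrt(sigma2_e / prec)
            elif model_code == 1:  # BL
                prec = wtw[j] + 1.0 / tau2[j]
                mean = rhs / prec
                a_new = mean + np.random.normal() * np.sqrt(sigma2_e / prec)
            elif model_code == 2:  # BayesA
                prec = wtw[j] + sigma2_e / sigma2_aj[j]
                mean = rhs / prec
                a_new = mean + np.random.normal() * np.sqrt(sigma2_e / prec)
            else:  # BayesB / BayesCpi: spike and slab
                s2j = sigma2_aj[j] if model_code == 3 else sigma2_a
                v0 = wtw[j] * sigma2_e
                v1 = wtw[j] * wtw[j] * s2j + wtw[j] * sigma2_e
                if pi >= 1.0:
                    incl = False
                elif pi <= 0.0:
                    incl = True
                else:
                    log_odds = (
                        np.log((1.0 - pi) / pi)
                        + 0.5 * (np.log(v0 / v1))
                        + 0.5 * rhs * rhs * (1.0 / v0 - 1.0 / v1)
                    )
                    incl = np.random.random() < 1.0 / (1.0 + np.exp(-log_odds))
                if incl:
                    prec = wtw[j] + sigma2_e / s2j
                    mean = rhs / prec
                    a_new = mean + np.random.normal() * np.sqrt(sigma2_e / prec)
                    delta[j] = 1.0
                else:
                    a_new = 0.0
                    delta[j] = 0.0
            diff = a_new - a[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= W[i, j] * diff
            a[j] = a_new

        # dominance effects: ridge-style common variance
        if use_dom:
            for j in range(pd_):
                if htj[j] == 0.0:
                    continue
                rhs = 0.0
                for i in range(n):
                    rhs += Hd[i, j] * e[i]
                rhs += htj[j] * d[j]
                prec = htj[j] + sigma2_e / sigma2_d
                mean = rhs / prec
                d_new = mean + np.random.normal() * np.sqrt(sigma2_e / prec)
                diff = d_new - d[j]
                for i in range(n):
                    e[i] -= Hd[i, j] * diff
                d[j] = d_new
            ssd = 0.0
            for j in range(pd_):
                ssd += d[j] * d[j]
            sigma2_d = (ssd + df_a * S_a) / np.random.chisquare(df_a + pd_)

        # variances and mixing parameters
        if model_code == 0:
            if fix_marker_var <= 0.0:
                ssa = 0.0
                for j in range(p):
                    ssa += a[j] * a[j]
                sigma2_a = (ssa + df_a * S_a) / np.random.chisquare(df_a + p)
        elif model_code == 1:
            for j in range(p):
                aj2 = a[j] * a[j]
                if aj2 < 1e-300:
                    aj2 = 1e-300
                inv_tau2 = _inv_gaussian(np.sqrt(lam2 * sigma2_e / aj2), lam2)
                tau2[j] = 1.0 / max(inv_tau2, 1e-300)
            sum_tau2 = 0.0
            for j in range(p):
                sum_tau2 += tau2[j]
            lam2 = np.random.gamma(
                lambda_shape + p, 1.0 / (lambda_rate + 0.5 * sum_tau2)
            )
        elif model_code == 2:
            for j in range(p):
                sigma2_aj[j] = (a[j] * a[j] + df_a * S_a) / np.random.chisquare(
                    df_a + 1.0
                )
        elif model_code == 3:
            for j in range(p):
                if delta[j] > 0.5:
                    sigma2_aj[j] = (
                        a[j] * a[j] + df_a * S_a
                    ) / np.random.chisquare(df_a + 1.0)
                else:
                    sigma2_aj[j] = df_a * S_a / np.random.chisquare(df_a)
        else:  # BayesCpi
            m_incl = 0.0
            ssa = 0.0
            for j in range(p):
                if delta[j] > 0.5:
                    m_incl += 1.0
                    ssa += a[j] * a[j]
            sigma2_a = (ssa + df_a * S_a) / np.random.chisquare(df_a + m_incl)
            pi = np.random.beta(p - m_incl + 1.0, m_incl + 1.0)

        if fix_resid_var <= 0.0:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            if model_code == 1:
                extra = 0.0
                for j in range(p):
                    extra += a[j] * a[j] / tau2[j]
                sigma2_e = (sse + extra + df_e * S_e) / np.random.chisquare(
                    df_e + n + p
                )
            else:
                sigma2_e = (sse + df_e * S_e) / np.random.chisquare(df_e + n)

        if not (np.isfinite(sigma2_e) and np.isfinite(mu)):
            return (
                sum_mu, sum_a, sum_d, sum_s2a, sum_s2e, sum_pi, sum_delta,
                samples, kept, it,
            )

        # accumulate kept samples
        if it > burn_in and (it - burn_in) % thin == 0:
            sum_mu += mu
            for j in range(p):
                sum_a[j] += a[j]
                sum_delta[j] += delta[j]
            for j in range(pd_):
                sum_d[j] += d[j]
            if model_code == 2 or model_code == 3:
                s2m = 0.0
                for j in range(p):
                    s2m += sigma2_aj[j]
                sum_s2a += s2m / p
            else:
                sum_s2a += sigma2_a
            sum_s2e += sigma2_e
            sum_pi += pi
            if save_samples:
                for j in range(p):
                    samples[kept, j] = a[j]
            kept += 1

    return sum_mu, sum_a, sum_d, sum_s2a, sum_s2e, sum_pi, sum_delta, samples, kept, 0


def run_gibbs(
    y: PhenotypeTable | np.ndarray, G: GenotypeMatrix, cfg: GibbsConfig
) -> PosteriorSummary:
    """Run the configured Gibbs sampler and return posterior means."""
    yv = y.value if isinstance(y, PhenotypeTable) else np.asarray(y, dtype=float)
    if not np.all(np.isfinite(yv)):
        raise ValueError("phenotype contains non-finite values")
    if G.n_markers == 0:
        raise ValueError("no markers in genotype matrix")
    if yv.size != G.n_samples:
        raise ValueError("phenotype/genotype sample mismatch")

    X = G.dosage
    pfreq = G.allele_freq
    W = np.ascontiguousarray(X - 2.0 * pfreq)
    if cfg.use_dominance:
        het = np.where(np.abs(X - 1.0) < 1e-9, 1.0, 0.0)
        Hd = np.ascontiguousarray(het - 2.0 * pfreq * (1.0 - pfreq))
    else:
        Hd = np.zeros((yv.size, 0))

    vary = float(yv.var())
    sum2pq = float(np.sum(2.0 * pfreq * (1.0 - pfreq)))
    S_a = cfg.S_a
    if S_a is None:
        per_marker = 0.5 * vary / max(sum2pq, 1e-12)
        S_a = per_marker * (cfg.df_a + 2.0) / cfg.df_a  # prior mode = per_marker
    S_e = cfg.S_e
    if S_e is None:
        S_e = 0.5 * vary * (cfg.df_e + 2.0) / cfg.df_e

    out = _gibbs_core(
        W,
        Hd,
        yv.astype(float),
        _MODEL_CODES[cfg.model],
        cfg.n_iter,
        cfg.burn_in,
        cfg.thin,
        cfg.seed,
        float(cfg.df_a),
        float(S_a),
        float(cfg.df_e),
        float(S_e),
        float(cfg.pi0),
        float(cfg.lambda_shape),
        float(cfg.lambda_rate),
        cfg.use_dominance,
        -1.0 if cfg.fix_marker_var is None else float(cfg.fix_marker_var),
        -1.0 if cfg.fix_resid_var is None else float(cfg.fix_resid_var),
        cfg.save_effect_samples,
    )
    (sum_mu, sum_a, sum_d, sum_s2a, sum_s2e, sum_pi, sum_delta, samples, kept, bad_it) = out
    if bad_it:
        raise FloatingPointError(f"divergent chain: non-finite state at iteration {bad_it}")
    if kept != cfg.n_kept:  # pragma: no cover - arithmetic guard
        raise RuntimeError("kept-sample bookkeeping mismatch")

    a_mean = sum_a / kept
    d_mean = sum_d / kept if cfg.use_dominance else None
    fitted = W @ a_mean
    if cfg.use_dominance:
        fitted = fitted + Hd @ d_mean
    mixture = cfg.model in ("BayesB", "BayesCpi")
    return PosteriorSummary(
        mu=sum_mu / kept,
        add_effects=a_mean,
        dom_effects=d_mean,
        marker_var=sum_s2a / kept,
        resid_var=sum_s2e / kept,
        pi=(sum_pi / kept) if cfg.model == "BayesCpi" else None,
        inclusion_prob=(sum_delta / kept) if mixture else None,
        fitted_genetic_values=fitted,
        n_samples_kept=kept,
        marker_ids=list(G.marker_ids),
        train_allele_freq=pfreq.copy(),
        model=cfg.model,
        effect_samples=samples if cfg.save_effect_samples else None,
    )


def posterior_predict(ps: PosteriorSummary, G_new: GenotypeMatrix) -> np.ndarray:
    """Predict new samples: mu + (X_new - 2 p_train) a (+ dominance part)."""
    if list(G_new.marker_ids) != list(ps.marker_ids):
        missing = sorted(set(ps.marker_ids) - set(G_new.marker_ids))
        raise ValueError(f"marker mismatch with training set; missing {missing[:5]}...")
    pfreq = ps.train_allele_freq
    W_new = G_new.dosage - 2.0 * pfreq
    pred = ps.mu + W_new @ ps.add_effects
    if ps.dom_effects is not None:
        het = np.where(np.abs(G_new.dosage - 1.0) < 1e-9, 1.0, 0.0)
        pred = pred + (het - 2.0 * pfreq * (1.0 - pfreq)) @ ps.dom_effects
    return pred
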