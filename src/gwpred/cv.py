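"""Repeated 90/10 cross-validation, predictive ability, and Tukey-Kramer letters.

``run_cv`` draws one seeded random train/validation split per cycle and shares
it across *all* models (paired design), trains each model on the training
split only — internal scaling and allele frequencies included — and records
the Pearson correlation between observed and predicted phenotypes in the
validation split (the predictive ability, PA). Models are then compared per
trait by one-way ANOVA on per-cycle PA with all pairwise Tukey-Kramer
contrasts summarized as a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .bayes import GibbsConfig, posterior_predict, run_gibbs
from .blup import fit_kernel_blup, predict_blup
from .brnn import BrnnConfig, brnn_preset, predict_net, train_brnn
from .io import GenotypeMatrix, PhenotypeTable
from .kinship import RelationshipMatrix, additive_relationship, gaussian_cross_kernel, gaussian_kernel
from .lstm import lstm_preset, predict_lstm, train_lstm
from .reml import RemlError, fit_reml

__all__ = [
    "CvResultTable",
    "make_model",
    "run_cv",
    "predictive_ability",
    "tukey_kramer_pairwise",
    "tukey_kramer_cld",
]


def predictive_ability(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation; NaN sentinel when either vector is constant."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size != predicted.size or observed.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if observed.std() == 0.0 or predicted.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1])


# ---------------------------------------------------------------------------
# model wrappers: uniform fit-on-train / predict-on-validation contract
# ---------------------------------------------------------------------------


def _safe_reml(y, kernels):
    try:
        return fit_reml(y, kernels)
    except RemlError as exc:
        if exc.last is not None:  # use the last iterate rather than abort a cycle
            return exc.last
        raise


class GblupModel:
    """Additive GBLUP; validation samples predicted with the training centering."""

    def __init__(self, name: str = "GBLUP"):
        self.name = name

    def fit_predict(self, G_train, y_train, G_valid) -> np.ndarray:
        A = additive_relationship(G_train)
        vc = _safe_reml(y_train, A)
        fit = fit_kernel_blup(y_train, A, vc=vc)
        pfreq = G_train.allele_freq
        denom = 2.0 * np.sum(pfreq * (1.0 - pfreq))
        W_tr = G_train.dosage - 2.0 * pfreq
        W_va = G_valid.dosage - 2.0 * pfreq
        A_cross = (W_va @ W_tr.T) / denom
        return predict_blup(fit, A_cross)


class RkhsModel:
    """Gaussian-kernel regression with REML-estimated variance ratios."""

    def __init__(self, h: float = 0.5, name: str = "RKHS"):
        self.name = name
        self.h = h

    def fit_predict(self, G_train, y_train, G_valid) -> np.ndarray:
        K = gaussian_kernel(G_train, h=self.h)
        vc = _safe_reml(y_train, K)
        fit = fit_kernel_blup(y_train, K, vc=vc)
        K_cross = gaussian_cross_kernel(G_valid, G_train, h=self.h)
        return predict_blup(fit, K_cross)


class BayesModel:
    """Any Bayesian-alphabet sampler at desk-scale chain settings."""

    def __init__(self, cfg: GibbsConfig, name: str | None = None):
        self.cfg = cfg
        self.name = name or cfg.model

    def fit_predict(self, G_train, y_train, G_valid) -> np.ndarray:
        ps = run_gibbs(y_train, G_train, self.cfg)
        return posterior_predict(ps, G_valid)


class BrnnModel:
    def __init__(self, preset: str, **cfg_kw):
        self.name = preset
        self.cfg_kw = cfg_kw
        self.architecture = brnn_preset(preset)

    def fit_predict(self, G_train, y_train, G_valid) -> np.ndarray:
        cfg = BrnnConfig(architecture=self.architecture, **self.cfg_kw)
        yv = y_train.value if isinstance(y_train, PhenotypeTable) else y_train
        net = train_brnn(G_train.dosage, yv, cfg)
        return predict_net(net, G_valid.dosage)


class LstmModel:
    def __init__(self, preset: str, **cfg_kw):
        self.name = preset
        self.preset = preset
        self.cfg_kw = cfg_kw

    def fit_predict(self, G_train, y_train, G_valid) -> np.ndarray:
        cfg = lstm_preset(self.preset, **self.cfg_kw)
        yv = y_train.value if isinstance(y_train, PhenotypeTable) else y_train
        net = train_lstm(G_train.dosage, yv, cfg)
        return predict_lstm(net, G_valid.dosage)


_CV_BAYES_DEFAULTS = dict(n_iter=3000, burn_in=1000, thin=2)


def make_model(name: str, **kw):
    """Model wrapper by name: GBLUP, RKHS, BRR/BL/BayesA/BayesB/BayesCpi,
    brnn1..brnn10, lstm1..lstm6. Keyword arguments override desk-scale defaults."""
    if name == "GBLUP":
        return GblupModel()
    if name == "RKHS":
        return RkhsModel(**kw)
    if name in ("BRR", "BL", "BayesA", "BayesB", "BayesCpi"):
        settings = {**_CV_BAYES_DEFAULTS, **kw}
        return BayesModel(GibbsConfig(model=name, **settings))
    if name.startswith("brnn"):
        kw.setdefault("max_epochs", 100)
        return BrnnModel(name, **kw)
    if name.startswith("lstm"):
        kw.setdefault("epochs", 30)
        return LstmModel(name, **kw)
    raise ValueError(f"unknown model name {name!r}")


# ---------------------------------------------------------------------------
# the harness
# ---------------------------------------------------------------------------


@dataclass
class CvResultTable:
    """Per-cycle PA rows plus per-model summaries."""

    table: pd.DataFrame  # columns: model, trait, cycle, pa, train_n, valid_n, seed

    def summary(self, alpha: float = 0.05, letters: bool = True) -> pd.DataFrame:
        rows = []
        for (trait, model), grp in self.table.groupby(["trait", "model"], sort=False):
            pa = grp["pa"].dropna()
            rows.append(
                {
                    "trait": trait,
                    "model": model,
                    "mean_pa": pa.mean(),
                    "sd_pa": pa.std(ddof=1),
                    "n_cycles": len(pa),
                }
            )
        out = pd.DataFrame(rows)
        if letters:
            try:
                cld = tukey_kramer_cld(self, alpha=alpha)
                out["letters"] = [
                    cld[r.trait][r.model] for r in out.itertuples()
                ]
            except ValueError:
                out["letters"] = ""
        return out


def run_cv(
    models,
    G: GenotypeMatrix,
    y: PhenotypeTable | dict[str, PhenotypeTable],
    n_cycles: int = 10,
    train_frac: float = 0.9,
    seed: int = 0,
) -> CvResultTable:
    """Repeated random-split cross-validation with splits shared across models.

    ``models`` is a list of model names (see :func:`make_model`) or wrapper
    objects with ``name`` and ``fit_predict``. Each cycle's split has
    round(train_frac * n) training samples; the same split is used by every
    model and every trait in that cycle so the comparisons are paired.
    """
    if G.n_samples < 20:
        raise ValueError("cross-validation requires n >= 20")
    models = [make_model(mdl) if isinstance(mdl, str) else mdl for mdl in models]
    traits = y if isinstance(y, dict) else {y.trait: y}
    n = G.n_samples
    train_n = int(round(train_frac * n))
    rng = np.random.default_rng(seed)
    rows = []
    for cycle in range(1, n_cycles + 1):
        perm = rng.permutation(n)
        tr_idx, va_idx = perm[:train_n], perm[train_n:]
        G_tr = G.subset_samples(tr_idx)
        G_va = G.subset_samples(va_idx)
        for trait_name, table in traits.items():
            yv = table.aligned_to(G)
            y_tr = PhenotypeTable(
                [G.sample_ids[i] for i in tr_idx], trait_name, yv[tr_idx]
            )
            y_va = yv[va_idx]
            for mdl in models:
                pred = mdl.fit_predict(G_tr, y_tr, G_va)
                pa = predictive_ability(y_va, pred)
                if np.isnan(pa):
                    warnings.warn(
                        f"constant predictions for {mdl.name} on cycle {cycle}; "
                        "PA recorded as missing"
                    )
                rows.append(
                    {
                        "model": mdl.name,
                        "trait": trait_name,
                        "cycle": cycle,
                        "pa": pa,
                        "train_n": train_n,
                        "valid_n": n - train_n,
                        "seed": seed,
                    }
                )
    return CvResultTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Tukey-Kramer with compact letter display
# ---------------------------------------------------------------------------


def tukey_kramer_pairwise(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, float]]:
    """All pairwise Tukey-Kramer comparisons on a one-way layout.

    Uses the studentized-range statistic q = |m_i - m_j| /
    sqrt(MSE/2 (1/n_i + 1/n_j)) against the 1-alpha studentized-range quantile
    with (k, N-k) parameters. Returns the pairwise decision table and group means.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(values_by_group[g], dtype=float) for g in groups}
    data = {g: v[~np.isnan(v)] for g, v in data.items()}
    if any(v.size < 2 for v in data.values()):
        raise ValueError("each group needs >= 2 non-missing values")
    k = len(groups)
    N = sum(v.size for v in data.values())
    means = {g: float(v.mean()) for g, v in data.items()}
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values())
    df = N - k
    mse = sse / df
    if mse == 0.0:
        raise ValueError("zero within-group variance everywhere")
    q_crit = studentized_range.ppf(1.0 - alpha, k, df)
    rows = []
    for g1, g2 in combinations(groups, 2):
        se = np.sqrt(mse / 2.0 * (1.0 / data[g1].size + 1.0 / data[g2].size))
        q = abs(means[g1] - means[g2]) / se
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "mean_diff": means[g1] - means[g2],
                "q": q,
                "q_crit": q_crit,
                "significant": bool(q > q_crit),
            }
        )
    return pd.DataFrame(rows), means


def _compact_letters(groups: list[str], sig: dict[frozenset, bool], means: dict) -> dict:
    """Letters from maximal cliques of the non-significance graph."""
    if len(groups) > 20:
        raise ValueError("too many groups for exact letter assignment")
    cliques = []
    for r in range(len(groups), 0, -1):
        for sub in combinations(groups, r):
            if any(set(sub) <= c for c in cliques):
                continue
            if all(not sig[frozenset((a, b))] for a, b in combinations(sub, 2)):
                cliques.append(set(sub))
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in groups}
    for letter_i, c in enumerate(cliques):
        letter = chr(ord("a") + letter_i)
        for g in groups:
            if g in c:
                letters[g] += letter
    return letters


def tukey_kramer_cld(
    cv: CvResultTable | pd.DataFrame, alpha: float = 0.05
) -> dict[str, dict[str, str]]:
    """Per-trait compact letter display over models' per-cycle PA values.

    Models sharing a letter are not significantly different at level alpha.
    """
    table = cv.table if isinstance(cv, CvResultTable) else cv
    out: dict[str, dict[str, str]] = {}
    for trait, sub in table.groupby("trait", sort=False):
        values = {
            str(model): grp["pa"].to_numpy()
            for model, grp in sub.groupby("model", sort=False)
        }
        pairwise, means = tukey_kramer_pairwise(values, alpha=alpha)
        sig = {
            frozenset((r.group1, r.group2)): r.significant
            for r in pairwise.itertuples()
        }
        out[str(trait)] = _compact_letters(list(values), sig, means)
    return out
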