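"""Synthetic genotype and trait generators with recorded truth.

The generators emulate the structure of diploid outcrossing breeding panels:
a few hundred samples, 10k-scale biallelic SNP panels spread over 10
chromosomes, traits controlled by a handful of large-effect QTL on top of a
polygenic background, with additive and (optional) dominance variance and
optional full-sib family structure. Total phenotypic variance is normalized to
1 so heritabilities are variances directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io import GenotypeMatrix, PhenotypeTable

__all__ = ["TruthRecord", "simulate_genotypes", "simulate_trait"]

N_CHROMOSOMES = 10


@dataclass
class TruthRecord:
    """Ground truth of a simulated trait, for parameter-recovery tests."""

    qtl_indices: np.ndarray
    add_effects: np.ndarray  # per marker, on the centered 0/1/2 design
    dom_effects: np.ndarray  # per marker, on the centered {0,1,0} design
    breeding_values: np.ndarray
    genotypic_values: np.ndarray
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float


def _chrom_assignment(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Markers in 10 equal blocks of increasing 1-based positions."""
    chrom_idx = (np.arange(p) * N_CHROMOSOMES) // max(p, 1)
    chrom = np.array([str(c + 1) for c in chrom_idx], dtype=object)
    pos = np.empty(p, dtype=int)
    for c in range(N_CHROMOSOMES):
        mask = chrom_idx == c
        pos[mask] = 1 + 1000 * np.arange(mask.sum())
    return chrom, pos


def _draw_haplotypes(n_hap: int, freqs: np.ndarray, chrom: np.ndarray, ld_rho: float, rng) -> np.ndarray:
    """Haplotypes (n_hap x p of 0/1 alleles) with AR(1) latent correlation within chromosomes."""
    p = freqs.size
    if ld_rho == 0.0:
        return (rng.random((n_hap, p)) < freqs).astype(np.int8)
    z = rng.standard_normal((n_hap, p))
    out = np.empty((n_hap, p))
    start = 0
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        block = z[:, idx]
        for j in range(1, idx.size):
            block[:, j] = ld_rho * block[:, j - 1] + np.sqrt(1 - ld_rho**2) * block[:, j]
        out[:, idx] = block
        start += idx.size
    thresh = norm.ppf(freqs)  # allele 1 iff latent below its quantile
    return (out < thresh).astype(np.int8)


def simulate_genotypes(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_families: int = 0,
    offspring_per_family: int = 0,
    ld_rho: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a biallelic SNP dosage panel.

    Allele frequencies are uniform on ``maf_range``. With ``ld_rho`` > 0,
    adjacent markers on a chromosome are correlated through AR(1) latent
    haplotypes. In family mode (``n_families`` > 0, requiring
    ``n == n_families * offspring_per_family``) two parents are drawn per
    family and each offspring receives one uniformly drawn parental allele per
    locus from each parent (unlinked transmission).
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_range[0], maf_range[1], size=p)
    chrom, pos = _chrom_assignment(p)

    if n_families > 0:
        if n != n_families * offspring_per_family:
            raise ValueError(
                "family mode requires n == n_families * offspring_per_family"
            )
        dosage = np.empty((n, p), dtype=np.int8)
        row = 0
        for _ in range(n_families):
            par_haps = _draw_haplotypes(4, freqs, chrom, ld_rho, rng)  # 2 per parent
            for _ in range(offspring_per_family):
                pick1 = rng.integers(0, 2, size=p)
                pick2 = rng.integers(0, 2, size=p)
                gamete1 = np.where(pick1 == 0, par_haps[0], par_haps[1])
                gamete2 = np.where(pick2 == 0, par_haps[2], par_haps[3])
                dosage[row] = gamete1 + gamete2
                row += 1
    else:
        haps = _draw_haplotypes(2 * n, freqs, chrom, ld_rho, rng)
        dosage = (haps[:n] + haps[n:]).astype(np.int8)

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    marker_ids = [f"M{j + 1:06d}" for j in range(p)]
    return GenotypeMatrix(sample_ids, marker_ids, chrom, pos, dosage.astype(float))


def _rescale(v: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Scale factor making the realized variance of v equal target_var."""
    realized = v.var()
    if target_var == 0.0 or realized == 0.0:
        return np.zeros_like(v), 0.0
    s = np.sqrt(target_var / realized)
    return v * s, s


def simulate_trait(
    G: GenotypeMatrix,
    n_qtl: int,
    h2a: float,
    h2d: float = 0.0,
    qtl_share: float = 0.9,
    mu: float = 0.0,
    seed: int = 0,
) -> tuple[PhenotypeTable, TruthRecord]:
    """Simulate a trait with QTL + polygenic architecture on an existing panel.

    ``n_qtl`` markers receive large additive effects carrying ``qtl_share`` of
    the additive variance; every other marker gets a small Normal background
    effect. Dominance effects (on the centered {0,1,0} heterozygosity design)
    are placed on the QTL only. Effect vectors and the residual are rescaled so
    the *realized* variances equal ``h2a``, ``h2d`` and ``1 - h2a - h2d``
    (total phenotypic variance 1), giving exact desk-scale recovery targets.
    """
    if h2a + h2d > 1 + 1e-12:
        raise ValueError("h2a + h2d must be <= 1")
    if n_qtl > G.n_markers:
        raise ValueError("n_qtl exceeds marker count")
    rng = np.random.default_rng(seed)
    n, p = G.dosage.shape
    X = G.dosage
    pfreq = G.allele_freq
    W = X - 2.0 * pfreq  # centered additive design
    het = np.where(np.abs(X - 1.0) < 1e-9, 1.0, 0.0)
    H = het - 2.0 * pfreq * (1.0 - pfreq)  # centered dominance design

    qtl = np.sort(rng.choice(p, size=n_qtl, replace=False))
    is_qtl = np.zeros(p, dtype=bool)
    is_qtl[qtl] = True

    a = np.zeros(p)
    # large-effect QTL specified by variance explained: each contributes a
    # comparable share (scaled by 1/sqrt(2 p q), jittered, random sign) so
    # every QTL is a genuine signal; the rest is a small Normal background
    two_pq_qtl = np.maximum(2.0 * pfreq[qtl] * (1.0 - pfreq[qtl]), 1e-6)
    a[qtl] = (
        rng.uniform(0.8, 1.2, size=n_qtl)
        * rng.choice([-1.0, 1.0], size=n_qtl)
        / np.sqrt(two_pq_qtl)
    )
    a[~is_qtl] = rng.standard_normal(p - n_qtl) * 0.05
    sigma2_a = h2a
    bv_q, sq = _rescale(W[:, is_qtl] @ a[qtl], qtl_share * sigma2_a)
    bv_b, sb = _rescale(W[:, ~is_qtl] @ a[~is_qtl], (1 - qtl_share) * sigma2_a)
    a[qtl] *= sq
    a[~is_qtl] *= sb
    bv = W @ a
    # cross-covariance between QTL and background parts can leave a small gap
    bv, s_all = _rescale(bv, sigma2_a)
    a *= s_all

    d = np.zeros(p)
    sigma2_d = h2d
    if h2d > 0:
        d[qtl] = rng.standard_normal(n_qtl)
        dv, sd = _rescale(H @ d, sigma2_d)
        d *= sd
    dv = H @ d

    sigma2_e = max(1.0 - h2a - h2d, 0.0)
    e = rng.standard_normal(n)
    e, _ = _rescale(e, sigma2_e)

    gval = bv + dv
    y = mu + gval + e
    pheno = PhenotypeTable(list(G.sample_ids), trait="sim", value=y)
    truth = TruthRecord(
        qtl_indices=qtl,
        add_effects=a,
        dom_effects=d,
        breeding_values=bv,
        genotypic_values=gval,
        sigma2_a=sigma2_a,
        sigma2_d=sigma2_d,
        sigma2_e=sigma2_e,
    )
    return pheno, truth
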