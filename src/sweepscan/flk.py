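"""Reynolds distance, kinship construction, FLK and the hapFLK-style scan.

FLK tests whether a SNP's allele frequencies across populations deviate more
than neutral drift allows.  The drift model is encoded in a kinship matrix F
whose diagonal holds per-population drift coefficients; the variance model
for observed sample frequencies adds binomial sampling on top of drift:

    Var(p̂_g) = p0 (1 − p0) · (F_gg + (1 − F_gg) / m_g)

with m_g the allele count of group g.  Helper
:func:`sampling_corrected_kinship` folds the sampling term into the matrix,
so :func:`flk_stat` itself is agnostic: it evaluates the quadratic form
against whatever kinship it is given (under a plain symmetric diag(f, f) it
reduces exactly to T = (p_A − p_B)² / (2 f p0 q0)).

The hapFLK-style extension applies the same quadratic form to local
haplotype-cluster frequencies from the EM-fitted LD model, one cluster
against the rest, summed over clusters and averaged across EM runs, then
standardized genome-wide with upper-tail normal p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .cluster import ClusterModel, fit_cluster_model
from .fst import allele_freqs_by_group
from .panels import GenotypePanel, HaplotypePanel


# --------------------------------------------------------------- Reynolds θ

def reynolds_distance(panel: GenotypePanel, contrast: tuple[str, str] | None = None) -> float:
    """Sample-size-corrected coancestry estimate θ between the two groups.

    Per-locus numerators (squared frequency difference minus its binomial
    sampling bias) and denominators (expected heterozygosity between groups)
    are summed over loci before the ratio; the result is clipped to [0, 1).
    """
    if contrast is None:
        gs = panel.groups()
        if len(gs) != 2:
            raise ValueError(f"need exactly two groups, found {gs}")
        contrast = (gs[0], gs[1])
    num_total = 0.0
    den_total = 0.0
    p = []
    m = []
    from .panels import MISSING

    for g in contrast:
        idx = panel.group_index(g)
        calls = panel.calls[idx]
        obs = calls != MISSING
        n_obs = obs.sum(axis=0)
        alleles = 2.0 * n_obs
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p.append(np.where(alleles > 0, alt / np.maximum(alleles, 1), np.nan))
        m.append(alleles)
    p1, p2 = p
    m1, m2 = m
    ok = (m1 >= 2) & (m2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    q1, q2 = 1.0 - p1, 1.0 - p2
    num = (p1 - p2) ** 2 - p1 * q1 / np.maximum(m1 - 1, 1) - p2 * q2 / np.maximum(m2 - 1, 1)
    den = 1.0 - p1 * p2 - q1 * q2
    num_total = float(num[ok].sum())
    den_total = float(den[ok].sum())
    if den_total <= 0:
        raise ValueError("no polymorphic loci: Reynolds distance undefined")
    return float(np.clip(num_total / den_total, 0.0, 1.0 - 1e-12))


def kinship_from_distance(theta: float) -> np.ndarray:
    """Two-group star tree with a midpoint root: F = diag(θ/2, θ/2)."""
    if not (0.0 <= theta < 1.0):
        raise ValueError("theta must lie in [0, 1)")
    return np.diag([theta / 2.0, theta / 2.0])


def sampling_corrected_kinship(F: np.ndarray, n_alleles) -> np.ndarray:
    """Add the binomial sampling term (1 − F_gg)/m_g to the diagonal."""
    F = np.asarray(F, dtype=float)
    m = np.asarray(n_alleles, dtype=float)
    out = F.copy()
    out[np.diag_indices_from(out)] += (1.0 - np.diag(F)) / m
    return out


# --------------------------------------------------------------- FLK per SNP

def _diag_weights(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.shape != (2, 2) or not np.allclose(F, F.T):
        raise ValueError("kinship must be a symmetric 2x2 matrix")
    if np.abs(F[0, 1]) > 1e-12:
        raise ValueError("only diagonal (star-tree) kinship matrices are supported")
    w = np.diag(F).copy()
    if np.any(w <= 0):
        raise ValueError("kinship diagonal must be positive (θ=0 leaves FLK undefined)")
    return w


def flk_stat(p_a, p_b, F: np.ndarray):
    """FLK statistic and chi-square (df=1) p-value per SNP (vectorized).

    p0 is the GLS mean (weights 1/V_gg are frequency-free for diagonal F, so
    the one-step plug-in refinement is already exact).  SNPs whose estimated
    ancestral frequency hits 0 or 1 return NaN and are excluded upstream.
    """
    w = _diag_weights(F)
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    inv_w = 1.0 / w
    p0 = (p_a * inv_w[0] + p_b * inv_w[1]) / inv_w.sum()
    var0 = p0 * (1.0 - p0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(
            var0 > 0,
            ((p_a - p0) ** 2 * inv_w[0] + (p_b - p0) ** 2 * inv_w[1])
            / np.where(var0 > 0, var0, 1.0),
            np.nan,
        )
    pval = chi2.sf(t, df=1)
    if np.ndim(p_a) == 0 and np.ndim(p_b) == 0:
        return float(t), float(pval)
    return t, pval


# ----------------------------------------------------------------- hapFLK

def hapflk_stat(models: list[ClusterModel], F: np.ndarray) -> np.ndarray:
    """Run-averaged hapFLK-style statistic per SNP.

    For each EM run and SNP, every cluster's group frequencies are tested
    one-vs-rest with the FLK quadratic form and summed over clusters;
    clusters whose pooled frequency is degenerate (0 or 1) are skipped.  The
    per-run sums are averaged across runs.  Result is >= 0 and invariant to
    cluster relabeling.
    """
    if not models:
        raise ValueError("no fitted cluster models given")
    w = _diag_weights(F)
    inv_w = 1.0 / w
    acc = np.zeros(models[0].group_freqs.shape[2])
    for model in models:
        freqs = model.group_freqs  # (2, K, n_snps)
        if freqs.shape[0] != 2:
            raise ValueError("hapFLK here supports exactly two groups")
        p_a, p_b = freqs[0], freqs[1]
        p0 = (p_a * inv_w[0] + p_b * inv_w[1]) / inv_w.sum()
        var0 = p0 * (1.0 - p0)
        ok = var0 > 1e-12
        t = np.where(
            ok,
            ((p_a - p0) ** 2 * inv_w[0] + (p_b - p0) ** 2 * inv_w[1])
            / np.where(ok, var0, 1.0),
            0.0,
        )
        acc += t.sum(axis=0)
    return acc / len(models)


def standardize_hapflk(raw: np.ndarray, alpha: float = 0.001):
    """Genome-wide z-standardization with one-sided upper-tail p-values."""
    raw = np.asarray(raw, dtype=float)
    defined = np.isfinite(raw)
    if defined.sum() < 2:
        raise ValueError("need at least 2 hapFLK values to standardize")
    mean = float(raw[defined].mean())
    sd = float(raw[defined].std(ddof=0))
    if sd == 0:
        raise ValueError("constant hapFLK series; cannot standardize")
    z = (raw - mean) / sd
    p = norm.sf(z)
    sig = np.where(defined, p < alpha, False)
    return z, p, sig


# ------------------------------------------------------------------- scan

@dataclass
class FlkTrack:
    """Single-SNP FLK plus run-averaged hapFLK for one contrast."""

    table: pd.DataFrame
    theta: float
    kinship: np.ndarray


def scan_flk(
    haplotypes: HaplotypePanel,
    contrast: tuple[str, str] | None = None,
    K: int = 10,
    n_fit: int = 20,
    alpha: float = 0.001,
    seed: int = 0,
    kinship: np.ndarray | None = None,
    max_iter: int = 100,
) -> FlkTrack:
    """Full FLK + hapFLK scan from a phased panel.

    The kinship defaults to the midpoint split of the Reynolds estimate with
    the binomial sampling term added per group.
    """
    genotypes = haplotypes.to_genotypes()
    if contrast is None:
        gs = genotypes.groups()
        if len(gs) != 2:
            raise ValueError(f"need exactly two groups, found {gs}")
        contrast = (gs[0], gs[1])
    theta = reynolds_distance(genotypes, contrast)
    n_alleles = [2 * len(genotypes.group_index(g)) for g in contrast]
    if kinship is None:
        kinship = sampling_corrected_kinship(kinship_from_distance(theta), n_alleles)

    p_a, p_b, defined = allele_freqs_by_group(genotypes, contrast)
    flk, flk_p = flk_stat(p_a, p_b, kinship)
    flk = np.where(defined, flk, np.nan)
    flk_p = np.where(defined, flk_p, np.nan)

    models = fit_cluster_model(haplotypes, K=K, n_fit=n_fit, seed=seed, max_iter=max_iter)
    # group_freqs rows follow the panel's group order; align to the contrast
    order = [models[0].groups.index(g) for g in contrast]
    for m in models:
        m.group_freqs = m.group_freqs[order]
        m.groups = [m.groups[i] for i in order]
    hapflk_raw = hapflk_stat(models, kinship)
    z, p, sig = standardize_hapflk(hapflk_raw, alpha)

    table = pd.DataFrame(
        dict(
            chrom=haplotypes.variants["chrom"],
            pos=haplotypes.variants["pos"],
            snp_id=haplotypes.variants["snp_id"],
            flk=flk,
            flk_p=flk_p,
            hapflk=hapflk_raw,
            hapflk_std=z,
            hapflk_p=p,
            significant=sig.astype(int),
        )
    )
    return FlkTrack(table, theta, kinship)
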