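"""Per-SNP FST between two groups, kernel smoothing, and outlier calling.

The per-SNP statistic is the averaged squared deviation of each group's
allele frequency from the cross-group mean, normalized by the allele
frequency variance p̄q̄:

    FST = ½ Σ_g (p_g − p̄)² / (p̄ q̄),   p̄ = (p_A + p_B) / 2.

A fixed difference (p_A=1, p_B=0) gives 1; identical frequencies give 0.
Monomorphic SNPs (p̄ ∈ {0,1}) return 0 so the smoother has no holes; such
SNPs can never be outliers.

Smoothing is Nadaraya–Watson local averaging with an Epanechnikov kernel
whose bandwidth at each SNP is the physical distance to its k-th nearest
neighbour (self included), so the "window of k SNPs" retains its meaning on
irregularly spaced maps.  Smoothing never crosses chromosome boundaries.
Outliers are smoothed values strictly above the genome-wide mean + m·SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel


def snp_fst(p_a, p_b):
    """Two-group FST from allele frequencies (vectorized, total on [0,1]^2)."""
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    pbar = (p_a + p_b) / 2.0
    var = pbar * (1.0 - pbar)
    num = ((p_a - pbar) ** 2 + (p_b - pbar) ** 2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(var > 0, num / np.where(var > 0, var, 1.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def allele_freqs_by_group(
    panel: GenotypePanel, contrast: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternate-allele frequency per SNP in each group of the contrast.

    Missing calls are excluded from the denominators.  Returns
    (p_A, p_B, defined) where ``defined`` flags SNPs with at least one
    observed call in *both* groups; undefined SNPs carry NaN frequencies and
    are excluded from downstream tracks.
    """
    freqs = []
    defined = np.ones(panel.n_snps, dtype=bool)
    for group in contrast:
        idx = panel.group_index(group)
        calls = panel.calls[idx]
        obs = calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
        defined &= n_obs > 0
        freqs.append(p)
    return freqs[0], freqs[1], defined


def kernel_smooth(
    positions: np.ndarray, values: np.ndarray, window_snps: int = 5
) -> np.ndarray:
    """Nadaraya–Watson smoothing on one chromosome.

    ``positions`` must be strictly increasing.  The Epanechnikov bandwidth at
    SNP i is the distance to its ``window_snps``-th nearest neighbour (self
    included); ``window_snps=1`` therefore returns the input unchanged.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    n = positions.size
    if n == 0:
        return values.copy()
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing within a chromosome")
    k = int(window_snps)
    if k < 1:
        raise ValueError("window_snps must be >= 1")
    if k > n:
        warnings.warn(
            f"chromosome has {n} SNPs < window of {k}; window shrunk to {n}",
            stacklevel=2,
        )
        k = n
    if k == 1:
        return values.copy()

    # neighbourhood of the k nearest SNPs is contained in offsets -(k-1)..(k-1)
    m = 2 * k - 1
    dist = np.full((n, m), np.inf)
    vals = np.zeros((n, m))
    for c, off in enumerate(range(-(k - 1), k)):
        lo = max(0, -off)
        hi = min(n, n - off)
        rows = np.arange(lo, hi)
        dist[rows, c] = np.abs(positions[rows + off] - positions[rows])
        vals[rows, c] = values[rows + off]
    h = np.partition(dist, k - 1, axis=1)[:, k - 1]  # k-th nearest distance
    with np.errstate(invalid="ignore", divide="ignore"):
        u = dist / h[:, None]
    w = np.maximum(0.0, 1.0 - u ** 2)
    w[~np.isfinite(w)] = 0.0
    wsum = w.sum(axis=1)
    smoothed = np.where(wsum > 0, (w * vals).sum(axis=1) / np.where(wsum > 0, wsum, 1.0), values)
    degenerate = h <= 0
    if degenerate.any():
        smoothed[degenerate] = values[degenerate]
    return smoothed


def smooth_by_chromosome(
    variants: pd.DataFrame, values: np.ndarray, window_snps: int = 5
) -> np.ndarray:
    out = np.empty_like(np.asarray(values, dtype=float))
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        out[idx] = kernel_smooth(pos[idx], np.asarray(values, float)[idx], window_snps)
    return out


@dataclass
class FstTrack:
    """Genome-wide FST scan result for one contrast."""

    table: pd.DataFrame  # chrom, pos, snp_id, p_a, p_b, raw_fst, smoothed_fst, significant
    mean_smoothed: float
    sd_smoothed: float
    threshold: float


def call_fst_outliers(smoothed: np.ndarray, sd_mult: float = 3.0) -> tuple[np.ndarray, float, float, float]:
    """Flag smoothed values strictly above mean + sd_mult·SD (genome-wide)."""
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size < 2:
        raise ValueError("need at least 2 SNPs to define an outlier threshold")
    mean = float(smoothed.mean())
    sd = float(smoothed.std(ddof=0))
    threshold = mean + sd_mult * sd
    flags = smoothed > threshold
    return flags, mean, sd, threshold


def scan_fst(
    panel: GenotypePanel,
    contrast: tuple[str, str] | None = None,
    window_snps: int = 5,
    sd_mult: float = 3.0,
) -> FstTrack:
    """Full smoothed-FST scan: frequencies, per-SNP FST, smoothing, outliers."""
    if contrast is None:
        gs = panel.groups()
        if len(gs) != 2:
            raise ValueError(f"need exactly two groups for a contrast, found {gs}")
        contrast = (gs[0], gs[1])
    p_a, p_b, defined = allele_freqs_by_group(panel, contrast)
    keep = np.flatnonzero(defined)
    variants = panel.variants.iloc[keep].reset_index(drop=True)
    raw = snp_fst(p_a[keep], p_b[keep])
    smoothed = smooth_by_chromosome(variants, raw, window_snps)
    flags, mean, sd, threshold = call_fst_outliers(smoothed, sd_mult)
    table = pd.DataFrame(
        dict(
            chrom=variants["chrom"],
            pos=variants["pos"],
            snp_id=variants["snp_id"],
            p_a=p_a[keep],
            p_b=p_b[keep],
            raw_fst=raw,
            smoothed_fst=smoothed,
            significant=flags.astype(int),
        )
    )
    return FstTrack(table, mean, sd, threshold)
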