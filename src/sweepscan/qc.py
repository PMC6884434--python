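"""Genotype quality control and the PCA structure check.

Filter thresholds follow the usual array-QC wording: a record is removed when
its metric is *strictly below* the stated minimum (a SNP with call rate
exactly 0.95 is retained).  Filters are applied in a fixed, documented order
— samples by missingness first, then SNP filters (position known, call rate,
MAF, HWE) — because per-SNP metrics are recomputed after sample removal and
the order changes the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panels import MISSING, GenotypePanel


@dataclass
class QCThresholds:
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    sample_call_rate_min: float = 0.90

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "maf_min", "hwe_p_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional (Wigginton-style) two-sided HWE p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed one.  Monomorphic SNPs return 1 by convention.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped samples")
    rare = 2 * n_hom_ref + n_het
    common = 2 * n_hom_alt + n_het
    if rare > common:
        rare, common = common, rare
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = (common - hets) // 2
    # P(h | allele counts) ∝ 2^h * n! / (hom_rare! h! hom_common!)
    logp = hets * np.log(2.0) - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


def _snp_metrics(calls: np.ndarray):
    """Per-SNP call rate, MAF and genotype counts (missing excluded)."""
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / calls.shape[0]
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    n_het = ((calls == 1) & obs).sum(axis=0)
    n_hom_alt = ((calls == 2) & obs).sum(axis=0)
    n_hom_ref = n_obs - n_het - n_hom_alt
    return call_rate, maf, n_hom_ref, n_het, n_hom_alt


@dataclass
class QCReport:
    """Per-criterion removal counts and identifiers."""

    removed_samples_missingness: list[str] = field(default_factory=list)
    removed_snps_no_position: list[str] = field(default_factory=list)
    removed_snps_call_rate: list[str] = field(default_factory=list)
    removed_snps_maf: list[str] = field(default_factory=list)
    removed_snps_hwe: list[str] = field(default_factory=list)

    @property
    def n_samples_removed(self) -> int:
        return len(self.removed_samples_missingness)

    @property
    def n_snps_removed(self) -> int:
        return (
            len(self.removed_snps_no_position)
            + len(self.removed_snps_call_rate)
            + len(self.removed_snps_maf)
            + len(self.removed_snps_hwe)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("sample_missingness", "sample", i) for i in self.removed_samples_missingness
        ] + [
            ("no_position", "snp", i) for i in self.removed_snps_no_position
        ] + [
            ("call_rate", "snp", i) for i in self.removed_snps_call_rate
        ] + [
            ("maf", "snp", i) for i in self.removed_snps_maf
        ] + [
            ("hwe", "snp", i) for i in self.removed_snps_hwe
        ]
        return pd.DataFrame(rows, columns=["criterion", "kind", "id"])


def apply_qc(
    panel: GenotypePanel, thresholds: QCThresholds | None = None
) -> tuple[GenotypePanel, QCReport]:
    """Apply the standard array-QC filters in fixed order.

    Sex-chromosome SNPs are treated like any other chromosome (the X is
    retained; only the generic per-SNP filters can remove its SNPs).
    """
    th = thresholds or QCThresholds()
    if panel.n_samples == 0 or panel.n_snps == 0:
        raise ValueError("cannot QC an empty panel")
    report = QCReport()

    # 1. samples by missingness (call rate strictly below the minimum)
    sample_call_rate = (panel.calls != MISSING).mean(axis=1)
    keep_samples = sample_call_rate >= th.sample_call_rate_min
    report.removed_samples_missingness = (
        panel.samples["sample_id"].to_numpy()[~keep_samples].tolist()
    )
    if not keep_samples.any():
        raise ValueError("QC removed every sample")
    calls = panel.calls[keep_samples]
    snp_ids = panel.variants["snp_id"].to_numpy()

    keep = np.ones(panel.n_snps, dtype=bool)

    # 2. SNPs without a known genomic position
    pos_known = (panel.variants["pos"].to_numpy() > 0) & (
        panel.variants["chrom"].astype(str).to_numpy() != "0"
    )
    report.removed_snps_no_position = snp_ids[keep & ~pos_known].tolist()
    keep &= pos_known

    call_rate, maf, n_rr, n_het, n_aa = _snp_metrics(calls)

    # 3. SNP call rate
    fail_cr = call_rate < th.snp_call_rate_min
    report.removed_snps_call_rate = snp_ids[keep & fail_cr].tolist()
    keep &= ~fail_cr

    # 4. minor allele frequency (all-missing SNPs fail call rate first)
    fail_maf = np.where(np.isnan(maf), True, maf < th.maf_min)
    report.removed_snps_maf = snp_ids[keep & fail_maf].tolist()
    keep &= ~fail_maf

    # 5. HWE exact test on the surviving SNPs
    hwe_fail = np.zeros(panel.n_snps, dtype=bool)
    for j in np.flatnonzero(keep):
        if hwe_exact_test(int(n_rr[j]), int(n_het[j]), int(n_aa[j])) < th.hwe_p_min:
            hwe_fail[j] = True
    report.removed_snps_hwe = snp_ids[keep & hwe_fail].tolist()
    keep &= ~hwe_fail

    if not keep.any():
        raise ValueError("QC removed every SNP")
    out = panel.subset(sample_idx=np.flatnonzero(keep_samples), snp_idx=np.flatnonzero(keep))
    return out, report


def pca(
    panel: GenotypePanel, n_components: int = 10, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centered genotype matrix (missing calls mean-imputed).

    Returns sample coordinates (n_samples x n_components) and the percent of
    total genetic variance carried by each returned component.
    """
    if n_components > min(panel.n_samples, panel.n_snps):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, SNPs)="
            f"{min(panel.n_samples, panel.n_snps)}"
        )
    calls = panel.calls.astype(float)
    obs = panel.calls != MISSING
    n_obs = obs.sum(axis=0)
    col_mean = np.where(n_obs > 0, np.where(obs, calls, 0.0).sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    x = np.where(obs, calls, col_mean[None, :]) - col_mean[None, :]
    if scale:
        p = col_mean / 2.0
        denom = np.sqrt(np.maximum(p * (1.0 - p), 1e-12))
        x = x / denom[None, :]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = (s ** 2).sum()
    if total <= 0:
        raise ValueError("genotype matrix has zero variance")
    coords = u[:, :n_components] * s[:n_components]
    pct_var = 100.0 * (s[:n_components] ** 2) / total
    return coords, pct_var
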