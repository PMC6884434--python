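"""Core in-memory containers for genotype and phased-haplotype panels.

A :class:`GenotypePanel` holds diploid calls coded as counts of the alternate
allele (0, 1, 2) with ``-1`` marking a missing call.  A
:class:`HaplotypePanel` holds the phased binary haplotypes (two rows per
diploid sample) over the same variant map; collapsing adjacent haplotype rows
must reproduce the genotype calls exactly.

Variant maps are pandas DataFrames with columns ``chrom`` (str), ``pos``
(1-based bp, int), ``snp_id``, ``ref``, ``alt``; sample tables have columns
``sample_id`` and ``group``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "snp_id", "ref", "alt"]
SAMPLE_COLUMNS = ["sample_id", "group"]


class PanelError(ValueError):
    """Raised when a panel violates its structural invariants."""


def _check_variants(variants: pd.DataFrame) -> None:
    missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing_cols:
        raise PanelError(f"variant table missing columns {missing_cols}")
    for chrom, sub in variants.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            i = int(np.argmax(np.diff(pos) <= 0))
            raise PanelError(
                f"positions not strictly increasing on chromosome {chrom} "
                f"near {sub['snp_id'].iloc[i + 1]} (pos {pos[i + 1]})"
            )


@dataclass
class GenotypePanel:
    """Samples x SNPs alternate-allele counts plus variant and sample maps."""

    calls: np.ndarray  # (n_samples, n_snps) int8, values {0,1,2,MISSING}
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise PanelError("calls must be a 2-D samples x SNPs matrix")
        if self.calls.shape[0] != len(self.samples):
            raise PanelError(
                f"{self.calls.shape[0]} call rows but {len(self.samples)} samples"
            )
        if self.calls.shape[1] != len(self.variants):
            raise PanelError(
                f"{self.calls.shape[1]} call columns but {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelError("calls contain values outside {0,1,2,missing}")
        _check_variants(self.variants)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def groups(self) -> list[str]:
        return list(pd.unique(self.samples["group"]))

    def group_index(self, group: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["group"] == group).to_numpy())
        if idx.size == 0:
            raise PanelError(f"no samples in group {group!r}")
        return idx

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypePanel":
        calls = self.calls
        variants = self.variants
        samples = self.samples
        if sample_idx is not None:
            calls = calls[np.asarray(sample_idx)]
            samples = samples.iloc[np.asarray(sample_idx)]
        if snp_idx is not None:
            calls = calls[:, np.asarray(snp_idx)]
            variants = variants.iloc[np.asarray(snp_idx)]
        return GenotypePanel(calls.copy(), variants.reset_index(drop=True),
                             samples.reset_index(drop=True))

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            np.array_equal(self.calls, other.calls)
            and self.variants[VARIANT_COLUMNS].equals(other.variants[VARIANT_COLUMNS])
            and self.samples[SAMPLE_COLUMNS].equals(other.samples[SAMPLE_COLUMNS])
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes, two consecutive rows per diploid sample."""

    haps: np.ndarray  # (2*n_samples, n_snps) uint8 in {0,1}
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.uint8)
        if self.haps.ndim != 2:
            raise PanelError("haps must be 2-D")
        if self.haps.shape[0] != 2 * len(self.samples):
            raise PanelError(
                f"{self.haps.shape[0]} haplotype rows for {len(self.samples)} samples"
            )
        if self.haps.shape[1] != len(self.variants):
            raise PanelError("haplotype column count does not match variant map")
        if self.haps.max(initial=0) > 1:
            raise PanelError("haplotypes must be binary (phased, complete)")
        _check_variants(self.variants)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.haps.shape[1]

    def hap_groups(self) -> np.ndarray:
        """Group label of each haplotype row."""
        return np.repeat(self.samples["group"].to_numpy(), 2)

    def group_hap_index(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(self.hap_groups() == group)
        if idx.size == 0:
            raise PanelError(f"no haplotypes in group {group!r}")
        return idx

    def to_genotypes(self) -> GenotypePanel:
        """Collapse phased haplotypes to diploid alternate-allele counts."""
        calls = (self.haps[0::2].astype(np.int8) + self.haps[1::2].astype(np.int8))
        return GenotypePanel(calls, self.variants.copy(), self.samples.copy())

    def subset_snps(self, snp_idx) -> "HaplotypePanel":
        snp_idx = np.asarray(snp_idx)
        return HaplotypePanel(
            self.haps[:, snp_idx].copy(),
            self.variants.iloc[snp_idx].reset_index(drop=True),
            self.samples.copy(),
        )

    def chromosome_blocks(self) -> list[tuple[str, np.ndarray]]:
        """(chrom, column indices) per chromosome, in map order."""
        out = []
        chroms = self.variants["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            out.append((chrom, np.flatnonzero(chroms == chrom)))
        return out
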