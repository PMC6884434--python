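"""Two-group genotype/haplotype simulator with implanted selective sweeps.

The neutral model is a Balding–Nichols draw: each SNP has an ancestral
frequency p sampled from a configurable MAF band, and each group's population
frequency is drawn from Beta with mean p and variance F·p(1−p), where F is the
background differentiation level.  Haplotypes are then assembled SNP-by-SNP
from the group frequency (linkage equilibrium), so extended-haplotype
statistics see a fast-decaying background against which implanted sweep
blocks stand out unambiguously.

A sweep is implanted by (a) forcing the focal-SNP allele frequency in each
group to a requested value and (b) copying one core haplotype across a block
of surrounding SNPs onto a fraction of the focal-allele carriers in the
target group, creating both allele-frequency differentiation and extended
haplotype homozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel, HaplotypePanel

GROUP_A = "prolific"
GROUP_B = "non_prolific"


def child_rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic per-stage generator fanned out from one master seed."""
    key = [hash_label(str(lab)) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(key)))


def hash_label(label: str) -> int:
    # stable across processes (unlike built-in hash)
    h = 2166136261
    for ch in label.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


@dataclass
class SimConfig:
    """Study-design parameters for the neutral two-group panel.

    Defaults mirror the contrast this package is built around: 64 vs 20 ewes
    genotyped on an HD array (one SNP per ~5 kb), with background
    differentiation of the order seen between phenotype groups within one
    breed.
    """

    n_samples_a: int = 64
    n_samples_b: int = 20
    n_chromosomes: int = 4
    snps_per_chromosome: int = 5000
    chrom_length_bp: int = 25_000_000
    background_fst: float = 0.02
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_a < 2 or self.n_samples_b < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("need at least one chromosome with at least one SNP")
        if not (0 <= self.background_fst < 1):
            raise ValueError("background_fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.chrom_length_bp < self.snps_per_chromosome:
            raise ValueError("chromosome shorter than its SNP count")


@dataclass
class SweepSpec:
    """One implanted sweep: focal-SNP frequencies plus a shared haplotype block."""

    chromosome: str
    position_bp: int
    target_group: str = GROUP_A
    freq_in_target: float = 0.9
    freq_in_other: float = 0.1
    haplotype_block_bp: int = 500_000
    block_carrier_fraction: float = 1.0

    def __post_init__(self) -> None:
        for f in (self.freq_in_target, self.freq_in_other):
            if not (0.0 <= f <= 1.0):
                raise ValueError("sweep frequencies must lie in [0, 1]")
        if not (0.0 <= self.block_carrier_fraction <= 1.0):
            raise ValueError("block_carrier_fraction must lie in [0, 1]")
        if self.haplotype_block_bp < 0:
            raise ValueError("haplotype_block_bp must be non-negative")


@dataclass
class SweepRealization:
    """What a sweep actually looked like after implantation."""

    spec: SweepSpec
    snp_id: str
    focal_pos: int
    realized_freq_target: float
    realized_freq_other: float
    block_start: int
    block_end: int
    n_block_carriers: int


@dataclass
class SweepTruth:
    """Ground-truth record of every implanted sweep."""

    sweeps: list[SweepRealization] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sweeps:
            rows.append(
                dict(
                    chrom=s.spec.chromosome,
                    pos=s.focal_pos,
                    snp_id=s.snp_id,
                    target_group=s.spec.target_group,
                    freq_target=s.realized_freq_target,
                    freq_other=s.realized_freq_other,
                    block_start=s.block_start,
                    block_end=s.block_end,
                    n_block_carriers=s.n_block_carriers,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "snp_id", "target_group", "freq_target",
                "freq_other", "block_start", "block_end", "n_block_carriers",
            ],
        )


@dataclass
class NeutralSim:
    """Simulated panels plus the latent per-group population frequencies."""

    genotypes: GenotypePanel
    haplotypes: HaplotypePanel
    pop_freqs: np.ndarray  # (2, n_snps): rows = (group A, group B) alt-allele freq


def _positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """Uniformly spaced 1-based positions with jitter, strictly increasing."""
    spacing = length / n
    base = (np.arange(n) + 0.5) * spacing
    jitter = rng.uniform(-0.4, 0.4, size=n) * spacing
    pos = np.sort(np.round(base + jitter)).astype(np.int64)
    pos = np.maximum(pos, 1)
    # enforce strict monotonicity (jitter may create ties at coarse spacing)
    pos = np.maximum.accumulate(pos + np.arange(n) * 0)
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    return np.minimum(pos, length - n + np.arange(n) + 1)


def simulate_neutral_panel(config: SimConfig) -> NeutralSim:
    """Draw a neutral two-group panel under the Balding–Nichols drift model.

    Deterministic given ``config.seed``: the same config yields bit-identical
    panels.
    """
    rng = child_rng(config.seed, "neutral")
    n_a, n_b = config.n_samples_a, config.n_samples_b
    n_chrom = config.n_chromosomes
    n_per = config.snps_per_chromosome
    n_snps = n_chrom * n_per
    F = config.background_fst

    chroms = np.repeat([str(c + 1) for c in range(n_chrom)], n_per)
    pos = np.concatenate(
        [_positions(rng, n_per, config.chrom_length_bp) for _ in range(n_chrom)]
    )
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
    flip = rng.random(n_snps) < 0.5
    p_anc = np.where(flip, 1.0 - maf, maf)

    if F > 0:
        shape = (1.0 - F) / F
        p_groups = np.vstack([
            rng.beta(p_anc * shape, (1.0 - p_anc) * shape),
            rng.beta(p_anc * shape, (1.0 - p_anc) * shape),
        ])
        p_groups = np.clip(p_groups, 0.0, 1.0)
    else:
        p_groups = np.vstack([p_anc, p_anc])

    haps_a = (rng.random((2 * n_a, n_snps)) < p_groups[0]).astype(np.uint8)
    haps_b = (rng.random((2 * n_b, n_snps)) < p_groups[1]).astype(np.uint8)
    haps = np.vstack([haps_a, haps_b])

    snp_ids = np.array([f"snp_{c}_{i}" for c, i in zip(chroms, range(n_snps))])
    variants = pd.DataFrame(
        dict(chrom=chroms, pos=pos, snp_id=snp_ids,
             ref=np.full(n_snps, "A"), alt=np.full(n_snps, "C"))
    )
    samples = pd.DataFrame(
        dict(
            sample_id=[f"A{i:03d}" for i in range(n_a)] + [f"B{i:03d}" for i in range(n_b)],
            group=[GROUP_A] * n_a + [GROUP_B] * n_b,
        )
    )
    hpanel = HaplotypePanel(haps, variants, samples)
    return NeutralSim(hpanel.to_genotypes(), hpanel, p_groups)


def implant_sweep(
    panel: HaplotypePanel, spec: SweepSpec, seed: int = 0
) -> tuple[HaplotypePanel, SweepRealization]:
    """Implant one sweep into a phased panel (returns a modified copy).

    The focal SNP's alternate-allele frequency is forced to the requested
    value in both groups (carriers chosen at random); one core haplotype over
    the block is then copied onto ``block_carrier_fraction`` of the
    target-group haplotypes that carry the focal allele.  Haplotypes of the
    contrast group keep their neutral background outside the focal SNP.
    """
    rng = child_rng(seed, "sweep", spec.chromosome, spec.position_bp)
    variants = panel.variants
    on_chrom = np.flatnonzero((variants["chrom"] == spec.chromosome).to_numpy())
    if on_chrom.size == 0:
        raise ValueError(f"chromosome {spec.chromosome!r} not in panel")
    pos = variants["pos"].to_numpy()[on_chrom]
    if not (pos[0] <= spec.position_bp <= pos[-1]):
        raise ValueError(
            f"sweep position {spec.position_bp} outside chromosome "
            f"{spec.chromosome} span [{pos[0]}, {pos[-1]}]"
        )
    focal = on_chrom[int(np.argmin(np.abs(pos - spec.position_bp)))]
    focal_pos = int(variants["pos"].iloc[focal])

    haps = panel.haps.copy()
    groups = panel.hap_groups()
    target_idx = np.flatnonzero(groups == spec.target_group)
    other_idx = np.flatnonzero(groups != spec.target_group)
    if target_idx.size == 0:
        raise ValueError(f"target group {spec.target_group!r} not in panel")

    def _force_freq(idx: np.ndarray, freq: float) -> tuple[float, np.ndarray]:
        k = int(round(freq * idx.size))
        carriers = rng.choice(idx, size=k, replace=False)
        haps[idx, focal] = 0
        haps[carriers, focal] = 1
        return k / idx.size, carriers

    realized_t, carriers = _force_freq(target_idx, spec.freq_in_target)
    realized_o, _ = _force_freq(other_idx, spec.freq_in_other)

    if realized_t in (0.0, 1.0) and realized_o == realized_t:
        raise ValueError("focal SNP monomorphic in both groups: undetectable sweep")

    half = spec.haplotype_block_bp // 2
    block_cols = on_chrom[
        (variants["pos"].to_numpy()[on_chrom] >= focal_pos - half)
        & (variants["pos"].to_numpy()[on_chrom] <= focal_pos + half)
    ]
    n_block = int(round(spec.block_carrier_fraction * carriers.size))
    if n_block > 0 and block_cols.size > 0 and carriers.size > 0:
        core = haps[carriers[0], block_cols].copy()
        core[block_cols == focal] = 1
        chosen = rng.choice(carriers, size=n_block, replace=False)
        haps[np.ix_(chosen, block_cols)] = core

    out = HaplotypePanel(haps, panel.variants.copy(), panel.samples.copy())
    realization = SweepRealization(
        spec=spec,
        snp_id=str(variants["snp_id"].iloc[focal]),
        focal_pos=focal_pos,
        realized_freq_target=realized_t,
        realized_freq_other=realized_o,
        block_start=int(variants["pos"].iloc[block_cols[0]]) if block_cols.size else focal_pos,
        block_end=int(variants["pos"].iloc[block_cols[-1]]) if block_cols.size else focal_pos,
        n_block_carriers=n_block,
    )
    return out, realization


@dataclass
class ViolationManifest:
    """Exactly which SNPs/samples were degraded, by QC criterion."""

    low_callrate_snps: list[str]
    low_maf_snps: list[str]
    hwe_fail_snps: list[str]
    bad_samples: list[str]


def inject_qc_violations(
    panel: GenotypePanel,
    n_low_callrate: int = 0,
    n_low_maf: int = 0,
    n_hwe_fail: int = 0,
    n_bad_samples: int = 0,
    seed: int = 0,
) -> tuple[GenotypePanel, ViolationManifest]:
    """Degrade designated SNPs/samples so the QC filters have known targets.

    Designations are disjoint, drawn in fixed priority order (low call rate,
    then low MAF, then HWE failure); degraded entries are placed only in
    samples that are *not* designated bad, so each SNP designation survives
    the sample-first filter order.
    """
    rng = child_rng(seed, "qc_violations")
    n_snps_needed = n_low_callrate + n_low_maf + n_hwe_fail
    if n_snps_needed > panel.n_snps:
        raise ValueError("more SNP violations requested than SNPs available")
    if n_bad_samples > panel.n_samples:
        raise ValueError("more bad samples requested than samples available")

    calls = panel.calls.copy()
    snp_ids = panel.variants["snp_id"].to_numpy()
    sample_ids = panel.samples["sample_id"].to_numpy()

    bad_samples = rng.choice(panel.n_samples, size=n_bad_samples, replace=False)
    good_samples = np.setdiff1d(np.arange(panel.n_samples), bad_samples)
    if n_snps_needed and good_samples.size < 2:
        raise ValueError("not enough intact samples to host SNP violations")

    chosen = rng.choice(panel.n_snps, size=n_snps_needed, replace=False)
    lc = chosen[:n_low_callrate]
    lm = chosen[n_low_callrate:n_low_callrate + n_low_maf]
    hw = chosen[n_low_callrate + n_low_maf:]

    # call rate strictly below 95% among intact samples
    n_miss = int(np.floor(0.05 * good_samples.size)) + 1
    for j in lc:
        rows = rng.choice(good_samples, size=min(n_miss, good_samples.size), replace=False)
        calls[rows, j] = MISSING

    # MAF strictly below 1%: at most one heterozygote among intact samples
    for j in lm:
        calls[:, j] = 0
        if 1.0 / (2 * good_samples.size) < 0.01:
            calls[rng.choice(good_samples), j] = 1

    # guaranteed HWE failure: every call heterozygous
    for j in hw:
        calls[:, j] = 1

    # samples with more than 10% missing genotypes
    n_miss_s = int(np.floor(0.10 * panel.n_snps)) + 1
    for i in bad_samples:
        cols = rng.choice(panel.n_snps, size=n_miss_s, replace=False)
        calls[i, cols] = MISSING

    manifest = ViolationManifest(
        low_callrate_snps=sorted(snp_ids[lc].tolist()),
        low_maf_snps=sorted(snp_ids[lm].tolist()),
        hwe_fail_snps=sorted(snp_ids[hw].tolist()),
        bad_samples=sorted(sample_ids[bad_samples].tolist()),
    )
    out = GenotypePanel(calls, panel.variants.copy(), panel.samples.copy())
    return out, manifest
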