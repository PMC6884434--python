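"""Extended haplotype homozygosity, integrated EHH, and the XP-EHH scan.

EHH here is the site (cross-population) variant: at a core SNP, all
haplotypes of a group are followed outward together, and EHH at extension x
is the probability that two random haplotypes are identical over the span
core..x,

    EHH(x) = Σ_h C(n_h, 2) / C(n, 2)

summed over distinct haplotype strings.  EHH at zero extension is defined as
1.  Curves are computed leftwards and rightwards until EHH drops below a
cutoff (default 0.05) or the chromosome ends (the curve is then flagged
truncated).  iHH is the trapezoidal integral of EHH over physical bp, both
sides summed, integrating down to the linearly interpolated cutoff crossing;
XP-EHH is ln(iHH_A / iHH_B), standardized genome-wide and tested against the
standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm

from .panels import HaplotypePanel


@dataclass
class EhhCurve:
    """One direction of an EHH decay curve around a core SNP."""

    core: int  # SNP index within the chromosome block
    direction: str  # "left" or "right"
    offsets: np.ndarray  # bp distances from the core, starting at 0
    ehh: np.ndarray  # values in [0,1], starting at 1
    truncated: bool  # hit the chromosome edge before the cutoff


def _refine(ids: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Split haplotype classes by the next column (pure-python reference)."""
    pairs = ids.astype(np.int64) * 2 + alleles.astype(np.int64)
    _, new = np.unique(pairs, return_inverse=True)
    return new


def _homozygosity(ids: np.ndarray) -> float:
    n = ids.size
    _, counts = np.unique(ids, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_at(
    haps: np.ndarray,
    core: int,
    boundary: tuple[int, int] | None = None,
    cutoff: float = 0.05,
) -> tuple[EhhCurve, EhhCurve]:
    """EHH decay curves (left, right) for one group's haplotypes.

    ``haps`` is the (n_haplotypes x n_snps) binary matrix of one chromosome;
    ``boundary`` restricts the usable SNP index range (inclusive).  The core
    allele is part of every extended string.  Requires >= 2 haplotypes.
    """
    haps = np.asarray(haps)
    n = haps.shape[0]
    if n < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    lo, hi = (0, haps.shape[1] - 1) if boundary is None else boundary
    if not (lo <= core <= hi):
        raise ValueError(f"core {core} outside boundary [{lo}, {hi}]")
    pos = np.arange(haps.shape[1], dtype=float)  # unit spacing placeholder
    return _ehh_curves(haps, pos, core, lo, hi, cutoff)


def _ehh_curves(haps, pos, core, lo, hi, cutoff):
    curves = []
    for direction, step, stop in (("left", -1, lo), ("right", 1, hi)):
        ids = _refine(np.zeros(haps.shape[0], dtype=np.int64), haps[:, core])
        offsets = [0.0]
        ehh_vals = [1.0]
        truncated = True
        j = core
        while j != stop:
            j += step
            ids = _refine(ids, haps[:, j])
            e = _homozygosity(ids)
            offsets.append(abs(pos[j] - pos[core]))
            ehh_vals.append(e)
            if e < cutoff:
                truncated = False
                break
        curves.append(
            EhhCurve(core, direction, np.array(offsets), np.array(ehh_vals), truncated)
        )
    return curves[0], curves[1]


def ehh_at_positions(
    haps: np.ndarray, positions: np.ndarray, core: int, cutoff: float = 0.05
) -> tuple[EhhCurve, EhhCurve]:
    """Like :func:`ehh_at` but with physical bp positions for the offsets."""
    if haps.shape[0] < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    return _ehh_curves(haps, np.asarray(positions, float), core, 0, haps.shape[1] - 1, cutoff)


def _integrate_side(offsets: np.ndarray, ehh: np.ndarray, cutoff: float) -> float:
    """Trapezoid over one side, stopping at the interpolated cutoff crossing."""
    area = 0.0
    for i in range(1, offsets.size):
        x0, x1 = offsets[i - 1], offsets[i]
        e0, e1 = ehh[i - 1], ehh[i]
        if e1 < cutoff:
            if e0 > cutoff:
                xc = x0 + (x1 - x0) * (e0 - cutoff) / (e0 - e1)
                area += 0.5 * (e0 + cutoff) * (xc - x0)
            break
        area += 0.5 * (e0 + e1) * (x1 - x0)
    return area


def ihh(left: EhhCurve, right: EhhCurve, cutoff: float = 0.05) -> float:
    """Integrated EHH (bp): left plus right trapezoidal areas."""
    if left.core != right.core:
        raise ValueError("curves do not share a core SNP")
    if left.offsets.size == 0 or right.offsets.size == 0:
        raise ValueError("empty EHH curve")
    return _integrate_side(left.offsets, left.ehh, cutoff) + _integrate_side(
        right.offsets, right.ehh, cutoff
    )


def xpehh_raw(ihh_a: float, ihh_b: float) -> float:
    """ln(iHH_A / iHH_B); antisymmetric under group swap."""
    if ihh_a <= 0 or ihh_b <= 0:
        raise ValueError("XP-EHH requires strictly positive integrals")
    return float(np.log(ihh_a / ihh_b))


# ------------------------------------------------------------- numba kernel

@njit(cache=True)
def _ihh_all_numba(haps, pos, cutoff):  # pragma: no cover - exercised via scan
    n_hap, n_snp = haps.shape
    pairs_tot = n_hap * (n_hap - 1) / 2.0
    ihh_out = np.zeros(n_snp)
    trunc_out = np.zeros(n_snp, np.uint8)
    ids = np.empty(n_hap, np.int64)
    map_buf = np.empty(2 * n_hap + 2, np.int64)
    counts = np.empty(n_hap + 1, np.int64)
    for core in range(n_snp):
        total = 0.0
        truncated = False
        for d in range(2):
            step = -1 if d == 0 else 1
            stop = 0 if d == 0 else n_snp - 1
            # refine by the core column first (EHH at offset 0 is defined 1)
            k = 0
            for key in range(2):
                map_buf[key] = -1
            for i in range(n_hap):
                key = np.int64(haps[i, core])
                if map_buf[key] == -1:
                    map_buf[key] = k
                    k += 1
                ids[i] = map_buf[key]
            ehh_prev = 1.0
            x_prev = 0.0
            j = core
            side_trunc = True
            while j != stop:
                j += step
                # refine classes by column j
                for key in range(2 * k):
                    map_buf[key] = -1
                knew = 0
                for i in range(n_hap):
                    key = ids[i] * 2 + np.int64(haps[i, j])
                    if map_buf[key] == -1:
                        map_buf[key] = knew
                        knew += 1
                    ids[i] = map_buf[key]
                k = knew
                for c in range(k):
                    counts[c] = 0
                for i in range(n_hap):
                    counts[ids[i]] += 1
                s = 0.0
                for c in range(k):
                    s += counts[c] * (counts[c] - 1) / 2.0
                e = s / pairs_tot
                x = abs(pos[j] - pos[core])
                if e < cutoff:
                    if ehh_prev > cutoff:
                        xc = x_prev + (x - x_prev) * (ehh_prev - cutoff) / (ehh_prev - e)
                        total += 0.5 * (ehh_prev + cutoff) * (xc - x_prev)
                    side_trunc = False
                    break
                total += 0.5 * (ehh_prev + e) * (x - x_prev)
                ehh_prev = e
                x_prev = x
            if side_trunc:
                truncated = True
        ihh_out[core] = total
        trunc_out[core] = 1 if truncated else 0
    return ihh_out, trunc_out


def ihh_scan_group(haps: np.ndarray, positions: np.ndarray, cutoff: float = 0.05):
    """iHH at every SNP of one chromosome for one group's haplotypes."""
    haps = np.ascontiguousarray(haps, dtype=np.uint8)
    if haps.shape[0] < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    return _ihh_all_numba(haps, pos, float(cutoff))


# ------------------------------------------------------------ scan + z-test

@dataclass
class XpehhTrack:
    """Genome-wide XP-EHH scan for one contrast (sign > 0 favours group A)."""

    table: pd.DataFrame
    mean_raw: float
    sd_raw: float


def standardize_and_test(raw: np.ndarray, alpha: float = 0.001, two_sided: bool = True):
    """Genome-wide z-standardization and normal-theory p-values.

    NaN entries (excluded SNPs) are ignored for the mean/SD and propagate as
    NaN in the output.  Raises if fewer than 2 defined values or zero SD.
    """
    raw = np.asarray(raw, dtype=float)
    defined = np.isfinite(raw)
    if defined.sum() < 2:
        raise ValueError("need at least 2 defined raw values to standardize")
    mean = float(raw[defined].mean())
    sd = float(raw[defined].std(ddof=0))
    if sd == 0:
        raise ValueError("raw XP-EHH series has zero variance; cannot standardize")
    z = (raw - mean) / sd
    if two_sided:
        p = 2.0 * norm.sf(np.abs(z))
    else:
        p = norm.sf(z)
    sig = np.where(defined, p < alpha, False)
    return z, p, sig, mean, sd


def scan_xpehh(
    panel: HaplotypePanel,
    contrast: tuple[str, str] | None = None,
    cutoff: float = 0.05,
    alpha: float = 0.001,
    drop_truncated: bool = False,
    two_sided: bool = True,
) -> XpehhTrack:
    """Full XP-EHH scan over every chromosome of a phased panel."""
    if contrast is None:
        gs = list(pd.unique(panel.samples["group"]))
        if len(gs) != 2:
            raise ValueError(f"need exactly two groups, found {gs}")
        contrast = (gs[0], gs[1])
    idx_a = panel.group_hap_index(contrast[0])
    idx_b = panel.group_hap_index(contrast[1])

    ihh_a = np.empty(panel.n_snps)
    ihh_b = np.empty(panel.n_snps)
    trunc = np.empty(panel.n_snps, dtype=bool)
    pos_all = panel.variants["pos"].to_numpy()
    for _, cols in panel.chromosome_blocks():
        block = panel.haps[:, cols]
        a, ta = ihh_scan_group(block[idx_a], pos_all[cols], cutoff)
        b, tb = ihh_scan_group(block[idx_b], pos_all[cols], cutoff)
        ihh_a[cols] = a
        ihh_b[cols] = b
        trunc[cols] = (ta | tb).astype(bool)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where((ihh_a > 0) & (ihh_b > 0), np.log(ihh_a / np.maximum(ihh_b, 1e-300)), np.nan)
    if drop_truncated:
        raw = np.where(trunc, np.nan, raw)
    z, p, sig, mean, sd = standardize_and_test(raw, alpha, two_sided)
    table = pd.DataFrame(
        dict(
            chrom=panel.variants["chrom"],
            pos=panel.variants["pos"],
            snp_id=panel.variants["snp_id"],
            ihh_a=ihh_a,
            ihh_b=ihh_b,
            xpehh_raw=raw,
            xpehh_std=z,
            p=p,
            significant=sig.astype(int),
            sign_group=np.where(z > 0, contrast[0], contrast[1]),
            truncated=trunc.astype(int),
        )
    )
    return XpehhTrack(table, mean, sd)
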