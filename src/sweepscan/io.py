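"""Reading and writing genotype panels: PLINK .ped/.map, .bed/.bim/.fam, VCF.

PLINK dialects are parsed directly (text and v1.00 SNP-major binary).  VCF is
written as plain VCF 4.2 text with GT-only FORMAT and read back through
cyvcf2, so the round-trip tests double as a conformance check against an
independent parser.  Group labels travel either in a two-column TSV
(sample_id, group) or, for the PLINK dialects, in the family-ID column.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel, HaplotypePanel, PanelError

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


# ---------------------------------------------------------------- groups TSV

def write_groups(samples: pd.DataFrame, path: str) -> None:
    samples[["sample_id", "group"]].to_csv(path, sep="\t", index=False)


def read_groups(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(df.columns):
        raise PanelError(f"groups file {path} needs columns sample_id, group")
    return df[["sample_id", "group"]]


def _apply_groups(samples: pd.DataFrame, groups_path: str | None) -> pd.DataFrame:
    if groups_path is None:
        return samples
    groups = read_groups(groups_path)
    merged = samples.drop(columns=["group"]).merge(groups, on="sample_id", how="left")
    if merged["group"].isna().any():
        missing = merged.loc[merged["group"].isna(), "sample_id"].tolist()
        raise PanelError(f"samples absent from groups file {groups_path}: {missing[:5]}")
    return merged


# ------------------------------------------------------------------ ped/map

def write_ped_map(panel: GenotypePanel, prefix: str) -> None:
    v = panel.variants
    map_df = pd.DataFrame(
        dict(chrom=v["chrom"], snp_id=v["snp_id"], cm=0, pos=v["pos"])
    )
    map_df.to_csv(prefix + ".map", sep="\t", header=False, index=False)

    ref = v["ref"].to_numpy()
    alt = v["alt"].to_numpy()
    with open(prefix + ".ped", "w") as fh:
        for i in range(panel.n_samples):
            row = panel.samples.iloc[i]
            fields = [str(row["group"]), str(row["sample_id"]), "0", "0", "0", "-9"]
            calls = panel.calls[i]
            a1 = np.where(calls >= 1, alt, ref)
            a2 = np.where(calls == 2, alt, ref)
            a1 = np.where(calls == MISSING, "0", a1)
            a2 = np.where(calls == MISSING, "0", a2)
            pairs = np.empty(2 * panel.n_snps, dtype=object)
            pairs[0::2] = a1
            pairs[1::2] = a2
            fh.write(" ".join(fields) + " " + " ".join(pairs) + "\n")


def read_ped_map(prefix: str, groups_path: str | None = None) -> GenotypePanel:
    map_df = pd.read_csv(
        prefix + ".map", sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos"], dtype={"chrom": str, "snp_id": str},
    )
    n_snps = len(map_df)
    sample_rows = []
    geno_rows = []
    with open(prefix + ".ped") as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise PanelError(
                    f"{prefix}.ped line {line_no}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)} (mismatch with {prefix}.map)"
                )
            sample_rows.append(dict(sample_id=parts[1], group=parts[0]))
            geno_rows.append(np.array(parts[6:], dtype=object))
    if not sample_rows:
        raise PanelError(f"{prefix}.ped contains no samples")
    geno = np.stack(geno_rows)  # (n_samples, 2*n_snps)
    a1 = geno[:, 0::2]
    a2 = geno[:, 1::2]

    calls = np.full((len(sample_rows), n_snps), MISSING, dtype=np.int8)
    refs, alts = [], []
    for j in range(n_snps):
        col = np.concatenate([a1[:, j], a2[:, j]])
        obs = sorted(set(col) - {"0"})
        if len(obs) > 2:
            raise PanelError(f"SNP {map_df['snp_id'][j]} has >2 alleles: {obs}")
        ref = obs[0] if obs else "N"
        alt = obs[1] if len(obs) == 2 else "N"
        refs.append(ref)
        alts.append(alt)
        known = (a1[:, j] != "0") & (a2[:, j] != "0")
        calls[known, j] = (a1[known, j] == alt).astype(np.int8) + (
            a2[known, j] == alt
        ).astype(np.int8)

    variants = map_df[["chrom", "pos", "snp_id"]].copy()
    variants["ref"] = refs
    variants["alt"] = alts
    samples = _apply_groups(pd.DataFrame(sample_rows), groups_path)
    return GenotypePanel(calls, variants, samples)


# ------------------------------------------------------------- bed/bim/fam

def write_bed(panel: GenotypePanel, prefix: str) -> None:
    """PLINK 1 binary, v1.00 magic, SNP-major; A1 = alt, A2 = ref."""
    v = panel.variants
    pd.DataFrame(
        dict(chrom=v["chrom"], snp_id=v["snp_id"], cm=0, pos=v["pos"],
             a1=v["alt"], a2=v["ref"])
    ).to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    pd.DataFrame(
        dict(fid=panel.samples["group"], iid=panel.samples["sample_id"],
             pat=0, mat=0, sex=0, pheno=-9)
    ).to_csv(prefix + ".fam", sep="\t", header=False, index=False)

    # alt-count -> 2-bit code: 2->00 (hom A1), 1->10 (het), 0->11 (hom A2), miss->01
    lut = np.zeros(4, dtype=np.uint8)
    lut[0] = 0b11
    lut[1] = 0b10
    lut[2] = 0b00
    codes = lut[np.where(panel.calls == MISSING, 3, panel.calls)]
    codes[panel.calls == MISSING] = 0b01
    n_samples, n_snps = codes.shape
    pad = (-n_samples) % 4
    if pad:
        codes = np.vstack([codes, np.zeros((pad, n_snps), dtype=np.uint8)])
    c = codes.T.reshape(n_snps, -1, 4)
    packed = c[:, :, 0] | (c[:, :, 1] << 2) | (c[:, :, 2] << 4) | (c[:, :, 3] << 6)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_bed(prefix: str, groups_path: str | None = None) -> GenotypePanel:
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n_snps, n_samples = len(bim), len(fam)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise PanelError(f"{prefix}.bed lacks the PLINK v1.00 SNP-major magic bytes")
    bytes_per_snp = (n_samples + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * n_snps:
        raise PanelError(
            f"{prefix}.bed size inconsistent with {n_samples} samples x {n_snps} SNPs"
        )
    body = body.reshape(n_snps, bytes_per_snp)
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    codes = codes[:, :n_samples].T  # samples x snps
    calls = np.full(codes.shape, MISSING, dtype=np.int8)
    calls[codes == 0b00] = 2
    calls[codes == 0b10] = 1
    calls[codes == 0b11] = 0

    variants = pd.DataFrame(
        dict(chrom=bim["chrom"], pos=bim["pos"], snp_id=bim["snp_id"],
             ref=bim["a2"], alt=bim["a1"])
    )
    samples = _apply_groups(
        pd.DataFrame(dict(sample_id=fam["iid"], group=fam["fid"])), groups_path
    )
    return GenotypePanel(calls, variants, samples)


# ------------------------------------------------------------------ VCF 4.2

def write_vcf(panel: GenotypePanel | HaplotypePanel, path: str) -> None:
    """Plain-text VCF 4.2, GT-only; phased pipes when given haplotypes."""
    phased = isinstance(panel, HaplotypePanel)
    v = panel.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom, sub in v.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["sample_id"].astype(str))
            + "\n"
        )
        n = len(panel.samples)
        for j in range(len(v)):
            if phased:
                a = panel.haps[0::2, j].astype(str)
                b = panel.haps[1::2, j].astype(str)
                gts = np.char.add(np.char.add(a, "|"), b)
            else:
                calls = panel.calls[:, j]
                gts = np.select(
                    [calls == 0, calls == 1, calls == 2],
                    ["0/0", "0/1", "1/1"],
                    default="./.",
                )
            fh.write(
                f"{v['chrom'].iloc[j]}\t{int(v['pos'].iloc[j])}\t{v['snp_id'].iloc[j]}\t"
                f"{v['ref'].iloc[j]}\t{v['alt'].iloc[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(
    path: str, groups_path: str | None = None, require_phased: bool = False
) -> tuple[GenotypePanel, HaplotypePanel | None]:
    """Read a GT-only VCF; returns the genotype panel and, when every call is
    phased, the haplotype panel (None otherwise; error if phase is required).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    rows, haps_a, haps_b, calls_cols = [], [], [], []
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1:
            raise PanelError(f"variant {var.ID} at {var.CHROM}:{var.POS} is not bi-allelic")
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        a = np.array([g[0] for g in gts], dtype=np.int16)
        b = np.array([g[1] for g in gts], dtype=np.int16)
        phased_flags = np.array([bool(g[2]) for g in gts])
        miss = (a < 0) | (b < 0)
        if not phased_flags.all() or miss.any():
            all_phased = False
            if require_phased:
                bad = sample_ids[int(np.argmax(~phased_flags | miss))]
                raise PanelError(
                    f"unphased genotype for sample {bad} at {var.CHROM}:{var.POS}; "
                    "haplotypes require fully phased calls"
                )
        call = np.where(miss, MISSING, a + b).astype(np.int8)
        calls_cols.append(call)
        haps_a.append(np.where(miss, 0, a).astype(np.uint8))
        haps_b.append(np.where(miss, 0, b).astype(np.uint8))
        rows.append(
            dict(chrom=var.CHROM, pos=var.POS, snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                 ref=var.REF, alt=var.ALT[0])
        )
    if not rows:
        raise PanelError(f"{path} contains no variants")
    variants = pd.DataFrame(rows)
    samples = pd.DataFrame(dict(sample_id=sample_ids, group="unknown"))
    samples = _apply_groups(samples, groups_path)
    calls = np.stack(calls_cols, axis=1)
    gpanel = GenotypePanel(calls, variants, samples)
    hpanel = None
    if all_phased:
        haps = np.empty((2 * n, len(rows)), dtype=np.uint8)
        haps[0::2] = np.stack(haps_a, axis=1)
        haps[1::2] = np.stack(haps_b, axis=1)
        hpanel = HaplotypePanel(haps, variants.copy(), samples.copy())
    return gpanel, hpanel


# ------------------------------------------------------------------ dispatch

DIALECTS = ("ped", "bed", "vcf")


def write_panel(panel, prefix: str, dialect: str) -> None:
    if dialect == "ped":
        write_ped_map(panel if isinstance(panel, GenotypePanel) else panel.to_genotypes(), prefix)
    elif dialect == "bed":
        write_bed(panel if isinstance(panel, GenotypePanel) else panel.to_genotypes(), prefix)
    elif dialect == "vcf":
        write_vcf(panel, prefix if prefix.endswith(".vcf") else prefix + ".vcf")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_panel(prefix: str, dialect: str, groups_path: str | None = None):
    """Read a panel; returns (GenotypePanel, HaplotypePanel-or-None)."""
    if dialect == "ped":
        return read_ped_map(prefix, groups_path), None
    if dialect == "bed":
        return read_bed(prefix, groups_path), None
    if dialect == "vcf":
        path = prefix if os.path.exists(prefix) else prefix + ".vcf"
        return read_vcf(path, groups_path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
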