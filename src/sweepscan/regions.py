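"""Candidate-region construction, cross-method intersection, gene annotation.

Significant SNPs are merged into regions whenever consecutive significant
SNPs on one chromosome are separated by at most ``max_gap_bp`` (default
500 kb, comfortably above the distance over which LD decays on an ovine-like
array map).  Region bounds are the first and last significant SNP positions,
1-based inclusive; BED output converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MAX_GAP_BP = 500_000


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    method: str
    snp_ids: list[str] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return len(self.snp_ids)

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start must not exceed end")

    def overlaps(self, other: "CandidateRegion") -> bool:
        return self.chrom == other.chrom and (
            self.start_bp <= other.end_bp and other.start_bp <= self.end_bp
        )


@dataclass
class GeneAnnotation:
    gene_id: str
    name: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


def merge_significant(
    track: pd.DataFrame,
    method: str,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> list[CandidateRegion]:
    """Merge flagged SNPs into maximal gap-limited runs per chromosome.

    ``track`` needs columns chrom, pos, snp_id, significant.  Idempotent and
    independent of input row order (rows are sorted internally).
    """
    sig = track.loc[track["significant"].astype(bool)]
    if sig.empty:
        return []
    sig = sig.sort_values(["chrom", "pos"], kind="mergesort")
    regions: list[CandidateRegion] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        ids = sub["snp_id"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, pos.size - 1]
        for s, e in zip(starts, ends):
            regions.append(
                CandidateRegion(
                    chrom=str(chrom),
                    start_bp=int(pos[s]),
                    end_bp=int(pos[e]),
                    method=method,
                    snp_ids=list(ids[s : e + 1]),
                )
            )
    return regions


@dataclass
class GeneOverlap:
    """Genes touched by one region, or the nearest gene if none overlap."""

    region: CandidateRegion
    full: list[GeneAnnotation] = field(default_factory=list)
    partial: list[GeneAnnotation] = field(default_factory=list)
    nearest: GeneAnnotation | None = None
    nearest_distance: int | None = None  # bp between closest edges
    nearest_side: str | None = None  # "before" (upstream) or "after" (downstream)
    chromosome_annotated: bool = True


def overlap_genes(
    region: CandidateRegion, genes: list[GeneAnnotation]
) -> GeneOverlap:
    """Classify genes as fully covered / partially overlapping the region.

    If no gene overlaps, the nearest gene on the chromosome is reported with
    the bp distance between closest edges and which side of the region it
    lies on.  Intervals are closed on both ends.
    """
    out = GeneOverlap(region)
    on_chrom = [g for g in genes if g.chrom == region.chrom]
    if not on_chrom:
        out.chromosome_annotated = False
        return out
    best = None
    best_d = None
    for g in on_chrom:
        if g.start_bp <= region.end_bp and g.end_bp >= region.start_bp:
            if g.start_bp >= region.start_bp and g.end_bp <= region.end_bp:
                out.full.append(g)
            else:
                out.partial.append(g)
        else:
            d = (
                region.start_bp - g.end_bp
                if g.end_bp < region.start_bp
                else g.start_bp - region.end_bp
            )
            if best_d is None or d < best_d:
                best, best_d = g, d
    if not out.full and not out.partial and best is not None:
        out.nearest = best
        out.nearest_distance = int(best_d)
        out.nearest_side = "before" if best.end_bp < region.start_bp else "after"
    return out


@dataclass
class OverlapReport:
    """Pairwise and three-way bp intersections of per-method region sets."""

    pairwise: dict  # (method_a, method_b) -> list of (region_a, region_b, span)
    threeway: list  # (region_tuple, span) across all methods


def cross_method_overlap(regions_by_method: dict) -> OverlapReport:
    methods = list(regions_by_method)
    pairwise = {}
    for i, ma in enumerate(methods):
        for mb in methods[i + 1 :]:
            hits = []
            for ra in regions_by_method[ma]:
                for rb in regions_by_method[mb]:
                    if ra.overlaps(rb):
                        span = (
                            ra.chrom,
                            max(ra.start_bp, rb.start_bp),
                            min(ra.end_bp, rb.end_bp),
                        )
                        hits.append((ra, rb, span))
            pairwise[(ma, mb)] = hits
    threeway = []
    if len(methods) >= 3:
        ma, mb, mc = methods[:3]
        for ra in regions_by_method[ma]:
            for rb in regions_by_method[mb]:
                if not ra.overlaps(rb):
                    continue
                lo = max(ra.start_bp, rb.start_bp)
                hi = min(ra.end_bp, rb.end_bp)
                for rc in regions_by_method[mc]:
                    if rc.chrom == ra.chrom and rc.start_bp <= hi and rc.end_bp >= lo:
                        threeway.append(
                            (
                                (ra, rb, rc),
                                (ra.chrom, max(lo, rc.start_bp), min(hi, rc.end_bp)),
                            )
                        )
    return OverlapReport(pairwise, threeway)


# ------------------------------------------------------------- annotation IO

def read_bed_genes(path: str) -> list[GeneAnnotation]:
    """BED (0-based half-open) gene intervals -> 1-based inclusive records."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = []
    for i, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else f"bed_{i}"
        strand = str(row[5]) if df.shape[1] > 5 else "."
        genes.append(
            GeneAnnotation(
                gene_id=name,
                name=name,
                chrom=str(row[0]),
                start_bp=int(row[1]) + 1,
                end_bp=int(row[2]),
                strand=strand,
            )
        )
    return genes


def read_gff3_genes(path: str, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Gene records from GFF3 (1-based inclusive), via gffutils."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [gene_id])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                name=name,
                chrom=str(feat.seqid),
                start_bp=int(feat.start),
                end_bp=int(feat.end),
                strand=feat.strand or ".",
            )
        )
    return genes


def read_genes(path: str) -> list[GeneAnnotation]:
    if path.endswith((".gff", ".gff3")):
        return read_gff3_genes(path)
    return read_bed_genes(path)


# ----------------------------------------------------------------- reporting

def regions_table(
    regions: list[CandidateRegion], genes: list[GeneAnnotation] | None = None
) -> pd.DataFrame:
    """Table-style report: chrom, from, to, n significant SNPs, genes."""
    rows = []
    for r in regions:
        row = dict(
            chrom=r.chrom,
            from_bp=r.start_bp,
            to_bp=r.end_bp,
            n_significant=r.n_significant,
            method=r.method,
        )
        if genes is not None:
            ov = overlap_genes(r, genes)
            row["genes_full"] = ",".join(g.name for g in ov.full)
            row["genes_partial"] = ",".join(g.name for g in ov.partial)
            row["nearest_gene"] = ov.nearest.name if ov.nearest else ""
            row["nearest_distance"] = ov.nearest_distance if ov.nearest else ""
            row["nearest_side"] = ov.nearest_side or ""
        rows.append(row)
    cols = ["chrom", "from_bp", "to_bp", "n_significant", "method"]
    if genes is not None:
        cols += ["genes_full", "genes_partial", "nearest_gene", "nearest_distance", "nearest_side"]
    return pd.DataFrame(rows, columns=cols)


def write_regions_bed(regions: list[CandidateRegion], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.method}\t{r.n_significant}\n")
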