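"""Region merging, gene overlap, cross-method intersection."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.regions import (
    CandidateRegion,
    GeneAnnotation,
    cross_method_overlap,
    merge_significant,
    overlap_genes,
    read_bed_genes,
    read_gff3_genes,
    regions_table,
)


def track_from(positions, flags, chrom="1"):
    return pd.DataFrame(
        dict(
            chrom=[chrom] * len(positions),
            pos=positions,
            snp_id=[f"s{i}" for i in range(len(positions))],
            significant=flags,
        )
    )


def test_gap_rule_splits_runs():
    t = track_from([100, 200, 5000], [1, 1, 1])
    regs = merge_significant(t, "fst", max_gap_bp=1000)
    assert [(r.start_bp, r.end_bp, r.n_significant) for r in regs] == [
        (100, 200, 2),
        (5000, 5000, 1),
    ]


def test_no_significant_snps_give_empty_list():
    assert merge_significant(track_from([10, 20], [0, 0]), "fst") == []


def test_all_significant_gives_one_region_per_chromosome():
    t = pd.concat(
        [track_from([100, 600, 900], [1, 1, 1], "1"),
         track_from([50, 75], [1, 1], "2")],
        ignore_index=True,
    )
    regs = merge_significant(t, "xpehh", max_gap_bp=1000)
    assert len(regs) == 2
    spans = {(r.chrom, r.start_bp, r.end_bp) for r in regs}
    assert spans == {("1", 100, 900), ("2", 50, 75)}


def test_merge_idempotent_and_order_independent(rng):
    pos = np.sort(rng.choice(100_000, 50, replace=False))
    flags = rng.integers(0, 2, 50)
    t = track_from(pos.tolist(), flags.tolist())
    shuffled = t.sample(frac=1, random_state=0)
    a = merge_significant(t, "m", 2000)
    b = merge_significant(shuffled, "m", 2000)
    assert [(r.start_bp, r.end_bp, r.n_significant) for r in a] == [
        (r.start_bp, r.end_bp, r.n_significant) for r in b
    ]


def test_merge_matches_brute_force(rng):
    for _ in range(100):
        n = int(rng.integers(1, 40))
        pos = np.sort(rng.choice(50_000, n, replace=False))
        flags = rng.integers(0, 2, n)
        gap = int(rng.integers(1, 10_000))
        regs = merge_significant(track_from(pos.tolist(), flags.tolist()), "m", gap)
        sig = pos[flags.astype(bool)]
        want = []
        for p in sig:
            if want and p - want[-1][-1] <= gap:
                want[-1].append(p)
            else:
                want.append([p])
        assert [(r.start_bp, r.end_bp, r.n_significant) for r in regs] == [
            (run[0], run[-1], len(run)) for run in want
        ]


def _region(a, b, chrom="1", method="fst"):
    return CandidateRegion(chrom, a, b, method, snp_ids=["x"])


def _gene(a, b, chrom="1", name="g"):
    return GeneAnnotation(name, name, chrom, a, b)


def test_gene_overlap_classification():
    ov = overlap_genes(_region(10, 20), [_gene(15, 30)])
    assert [g.name for g in ov.partial] == ["g"] and not ov.full
    ov = overlap_genes(_region(10, 20), [_gene(12, 18)])
    assert [g.name for g in ov.full] == ["g"] and not ov.partial


def test_nearest_gene_distance_and_side():
    ov = overlap_genes(_region(10, 20), [_gene(30, 40, name="near"), _gene(100, 200, name="far")])
    assert ov.nearest.name == "near"
    assert ov.nearest_distance == 10
    assert ov.nearest_side == "after"
    ov = overlap_genes(_region(50, 60), [_gene(10, 30, name="up")])
    assert ov.nearest_side == "before" and ov.nearest_distance == 20


def test_unannotated_chromosome_flagged():
    ov = overlap_genes(_region(10, 20, chrom="9"), [_gene(1, 5, chrom="1")])
    assert not ov.chromosome_annotated and ov.nearest is None


def test_cross_method_pairwise_span():
    report = cross_method_overlap(
        dict(fst=[_region(100, 500)], hapflk=[_region(400, 900, method="hapflk")])
    )
    hits = report.pairwise[("fst", "hapflk")]
    assert len(hits) == 1
    assert hits[0][2] == ("1", 400, 500)


def test_cross_method_disjoint_empty():
    report = cross_method_overlap(
        dict(fst=[_region(1, 10)], hapflk=[_region(100, 200)], xpehh=[])
    )
    assert all(not v for v in report.pairwise.values())
    assert report.threeway == []


def test_cross_method_identical_sets_self_match():
    regs = [_region(5, 50), _region(1000, 2000)]
    report = cross_method_overlap(dict(a=list(regs), b=list(regs)))
    hits = report.pairwise[("a", "b")]
    full_spans = {h[2] for h in hits}
    assert ("1", 5, 50) in full_spans and ("1", 1000, 2000) in full_spans


def test_pairwise_overlap_matches_all_pairs_brute_force(rng):
    for _ in range(60):
        def rand_regions(method):
            out = []
            for _ in range(int(rng.integers(0, 8))):
                a = int(rng.integers(0, 5000))
                b = a + int(rng.integers(0, 800))
                out.append(_region(a, b, chrom=str(rng.integers(1, 3)), method=method))
            return out

        by_method = dict(m1=rand_regions("m1"), m2=rand_regions("m2"))
        report = cross_method_overlap(by_method)
        got = {
            (ra.chrom, ra.start_bp, ra.end_bp, rb.start_bp, rb.end_bp)
            for ra, rb, _ in report.pairwise[("m1", "m2")]
        }
        want = set()
        for ra in by_method["m1"]:
            for rb in by_method["m2"]:
                if ra.chrom == rb.chrom and ra.start_bp <= rb.end_bp and rb.start_bp <= ra.end_bp:
                    want.add((ra.chrom, ra.start_bp, ra.end_bp, rb.start_bp, rb.end_bp))
        assert got == want


def test_bed_and_gff3_gene_reading(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("1\t99\t200\tBMP15\t0\t+\n2\t0\t50\tGDF9\t0\t-\n")
    genes = read_bed_genes(str(bed))
    assert genes[0].start_bp == 100 and genes[0].end_bp == 200  # 1-based inclusive
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "1\tsrc\tgene\t100\t200\t.\t+\t.\tID=gene1;Name=BMP15\n"
        "2\tsrc\tgene\t10\t50\t.\t-\t.\tID=gene2;Name=GDF9\n"
    )
    genes2 = read_gff3_genes(str(gff))
    assert {g.name for g in genes2} == {"BMP15", "GDF9"}
    assert genes2[0].start_bp == 100 and genes2[0].end_bp == 200


def test_regions_table_includes_gene_columns():
    table = regions_table([_region(10, 20)], [_gene(12, 18, name="inside")])
    assert table.loc[0, "genes_full"] == "inside"
    assert table.loc[0, "n_significant"] == 1
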