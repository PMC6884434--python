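"""End-to-end orchestration: simulate → QC → three scans → regions → report.

One master seed fans out to per-stage child seeds (hash of stage name), so
each stage is independently reproducible and a rerun of the same manifest
reproduces every deterministic output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .ehh import scan_xpehh
from .flk import scan_flk
from .fst import scan_fst
from .panels import GenotypePanel, HaplotypePanel
from .qc import QCThresholds, apply_qc
from .regions import (
    DEFAULT_MAX_GAP_BP,
    cross_method_overlap,
    merge_significant,
    regions_table,
    write_regions_bed,
)
from .sim import SimConfig, SweepSpec, SweepTruth, implant_sweep, simulate_neutral_panel

log = logging.getLogger("sweepscan")


@dataclass
class RunConfig:
    """Every knob of one pipeline run; defaults are the scan's canonical set
    (5-SNP smoothing window, mean+3SD FST threshold, K=10 clusters with 20 EM
    fits, P<0.001 for the haplotype tests, EHH integration cutoff 0.05)."""

    sim: SimConfig | None = None
    sweeps: list[SweepSpec] = field(default_factory=list)
    input_prefix: str | None = None
    input_dialect: str = "vcf"
    groups_path: str | None = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    contrast: tuple[str, str] | None = None
    window_snps: int = 5
    sd_mult: float = 3.0
    K: int = 10
    n_fit: int = 20
    alpha: float = 0.001
    ehh_cutoff: float = 0.05
    max_gap_bp: int = DEFAULT_MAX_GAP_BP
    out_dir: str = "sweepscan_out"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"]["maf_range"] = list(self.sim.maf_range)
        if self.contrast is not None:
            d["contrast"] = list(self.contrast)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim"):
            sim = dict(d["sim"])
            sim["maf_range"] = tuple(sim.get("maf_range", (0.05, 0.5)))
            d["sim"] = SimConfig(**sim)
        if d.get("sweeps"):
            d["sweeps"] = [
                s if isinstance(s, SweepSpec) else SweepSpec(**s) for s in d["sweeps"]
            ]
        if d.get("qc") and not isinstance(d["qc"], QCThresholds):
            d["qc"] = QCThresholds(**d["qc"])
        if d.get("contrast"):
            d["contrast"] = tuple(d["contrast"])
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _subset_haplotypes(hpanel: HaplotypePanel, panel_after_qc: GenotypePanel) -> HaplotypePanel:
    """Restrict a haplotype panel to the samples/SNPs that survived QC."""
    keep_samples = hpanel.samples["sample_id"].isin(panel_after_qc.samples["sample_id"])
    keep_snps = hpanel.variants["snp_id"].isin(panel_after_qc.variants["snp_id"]).to_numpy()
    rows = np.repeat(keep_samples.to_numpy(), 2)
    return HaplotypePanel(
        hpanel.haps[rows][:, keep_snps],
        hpanel.variants.loc[keep_snps].reset_index(drop=True),
        hpanel.samples.loc[keep_samples.to_numpy()].reset_index(drop=True),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write all outputs plus a manifest, return the bundle."""
    os.makedirs(config.out_dir, exist_ok=True)
    t0 = time.time()
    stages: dict[str, str] = {}
    truth = SweepTruth()

    def _out(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        stages[name] = path
        return path

    if config.sim is not None:
        sim_cfg = replace(config.sim, seed=config.sim.seed or config.seed)
        result = simulate_neutral_panel(sim_cfg)
        hpanel = result.haplotypes
        for i, spec in enumerate(config.sweeps):
            hpanel, realized = implant_sweep(hpanel, spec, seed=sim_cfg.seed + i)
            truth.sweeps.append(realized)
        gpanel = hpanel.to_genotypes()
        sio.write_vcf(hpanel, _out("panel.vcf"))
        sio.write_groups(gpanel.samples, _out("groups.tsv"))
        truth.to_frame().to_csv(_out("sweep_truth.tsv"), sep="\t", index=False)
        log.info("simulate: %d samples x %d SNPs", gpanel.n_samples, gpanel.n_snps)
    else:
        if config.input_prefix is None:
            raise ValueError("run_pipeline needs either a sim config or an input prefix")
        if config.groups_path is not None and not os.path.exists(config.groups_path):
            raise FileNotFoundError(f"groups file not found: {config.groups_path}")
        gpanel, hpanel = sio.read_panel(
            config.input_prefix, config.input_dialect, config.groups_path
        )
        if hpanel is None:
            raise ValueError(
                "haplotype-based scans need phased input (phased VCF or simulator)"
            )

    gpanel_qc, qc_report = apply_qc(gpanel, config.qc)
    qc_report.to_frame().to_csv(_out("qc_report.tsv"), sep="\t", index=False)
    hpanel_qc = _subset_haplotypes(hpanel, gpanel_qc)
    log.info(
        "qc: %d samples and %d SNPs available for analysis",
        gpanel_qc.n_samples, gpanel_qc.n_snps,
    )

    contrast = config.contrast
    if contrast is None:
        gs = gpanel_qc.groups()
        if len(gs) != 2:
            raise ValueError(f"need exactly two groups, found {gs}")
        contrast = (gs[0], gs[1])

    fst_track = scan_fst(gpanel_qc, contrast, config.window_snps, config.sd_mult)
    fst_track.table.to_csv(_out("fst.tsv"), sep="\t", index=False)
    log.info("scan-fst: %d outliers (threshold %.4g)",
             int(fst_track.table["significant"].sum()), fst_track.threshold)

    flk_track = scan_flk(
        hpanel_qc, contrast, K=config.K, n_fit=config.n_fit,
        alpha=config.alpha, seed=config.seed,
    )
    flk_track.table.to_csv(_out("flk.tsv"), sep="\t", index=False)
    log.info("scan-flk: theta=%.4g, %d significant",
             flk_track.theta, int(flk_track.table["significant"].sum()))

    xpehh_track = scan_xpehh(
        hpanel_qc, contrast, cutoff=config.ehh_cutoff, alpha=config.alpha
    )
    xpehh_track.table.to_csv(_out("xpehh.tsv"), sep="\t", index=False)
    log.info("scan-xpehh: %d significant", int(xpehh_track.table["significant"].sum()))

    regions_by_method = {
        "fst": merge_significant(fst_track.table, "fst", config.max_gap_bp),
        "hapflk": merge_significant(flk_track.table, "hapflk", config.max_gap_bp),
        "xpehh": merge_significant(xpehh_track.table, "xpehh", config.max_gap_bp),
    }
    all_regions = [r for rs in regions_by_method.values() for r in rs]
    regions_table(all_regions).to_csv(_out("regions.tsv"), sep="\t", index=False)
    write_regions_bed(all_regions, _out("regions.bed"))
    overlap = cross_method_overlap(regions_by_method)

    manifest = dict(
        config=config.to_dict(),
        outputs={name: _sha256(path) for name, path in stages.items()},
        seed=config.seed,
        max_gap_bp=config.max_gap_bp,
        wall_time_s=round(time.time() - t0, 3),
    )
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return dict(
        genotypes=gpanel_qc,
        haplotypes=hpanel_qc,
        qc_report=qc_report,
        fst=fst_track,
        flk=flk_track,
        xpehh=xpehh_track,
        regions=regions_by_method,
        overlap=overlap,
        truth=truth,
        manifest=manifest,
    )


# ------------------------------------------------------------- power harness

@dataclass
class MethodPower:
    detection_rate: float
    detection_se: float
    localization_errors_bp: list[float]
    false_positive_fraction: float  # mean fraction of significant SNPs on nulls

    def quantiles(self, qs=(0.5, 0.9)) -> dict:
        if not self.localization_errors_bp:
            return {q: float("nan") for q in qs}
        arr = np.asarray(self.localization_errors_bp, dtype=float)
        return {q: float(np.quantile(arr, q)) for q in qs}


@dataclass
class PowerReport:
    methods: dict[str, MethodPower]
    replicates: int

    def to_dict(self) -> dict:
        return {
            name: dict(
                detection_rate=m.detection_rate,
                detection_se=m.detection_se,
                localization_median_bp=m.quantiles()[0.5],
                localization_q90_bp=m.quantiles()[0.9],
                false_positive_fraction=m.false_positive_fraction,
            )
            for name, m in self.methods.items()
        }


def _top_snp_pos(table: pd.DataFrame, stat_col: str, absolute: bool = False):
    vals = table[stat_col].to_numpy(dtype=float)
    if absolute:
        vals = np.abs(vals)
    vals = np.where(np.isfinite(vals), vals, -np.inf)
    return int(table["pos"].iloc[int(np.argmax(vals))]), str(
        table["chrom"].iloc[int(np.argmax(vals))]
    )


def scan_replicate(
    sim: SimConfig,
    sweep: SweepSpec | None,
    seed: int,
    K: int = 10,
    n_fit: int = 20,
    alpha: float = 0.001,
    window_snps: int = 5,
    sd_mult: float = 3.0,
    ehh_cutoff: float = 0.05,
    max_iter: int = 100,
):
    """One simulated genome through all three scans (no file IO)."""
    cfg = replace(sim, seed=seed)
    result = simulate_neutral_panel(cfg)
    hpanel = result.haplotypes
    realized = None
    if sweep is not None:
        hpanel, realized = implant_sweep(hpanel, sweep, seed=seed)
    gpanel = hpanel.to_genotypes()
    fst_track = scan_fst(gpanel, window_snps=window_snps, sd_mult=sd_mult)
    flk_track = scan_flk(hpanel, K=K, n_fit=n_fit, alpha=alpha, seed=seed, max_iter=max_iter)
    xpehh_track = scan_xpehh(hpanel, cutoff=ehh_cutoff, alpha=alpha)
    return dict(fst=fst_track, hapflk=flk_track, xpehh=xpehh_track, truth=realized)


def power_experiment(
    sim: SimConfig,
    sweep: SweepSpec | None,
    replicates: int,
    tolerance_bp: int = 250_000,
    seed: int = 0,
    K: int = 10,
    n_fit: int = 20,
    alpha: float = 0.001,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    max_iter: int = 100,
) -> PowerReport:
    """Detection/localization rates over simulated replicates.

    Detection = the method produced a significant region whose span,
    extended by ``tolerance_bp``, covers the implanted focal SNP.  With
    ``sweep=None`` the genomes are neutral and the per-genome significant-SNP
    fraction estimates the family false-positive rate instead.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    stat_cols = dict(fst=("smoothed_fst", False), hapflk=("hapflk_std", False),
                     xpehh=("xpehh_std", True))
    detections = {m: [] for m in stat_cols}
    loc_errors = {m: [] for m in stat_cols}
    fp_fracs = {m: [] for m in stat_cols}
    for rep in range(replicates):
        rep_seed = (seed * 100003 + rep) % (2**31 - 1)
        tracks = scan_replicate(sim, sweep, rep_seed, K=K, n_fit=n_fit, alpha=alpha,
                                max_iter=max_iter)
        truth = tracks["truth"]
        for method, (col, absolute) in stat_cols.items():
            table = tracks[method].table if method != "hapflk" else tracks["hapflk"].table
            if truth is None:
                fp_fracs[method].append(float(table["significant"].mean()))
                continue
            regs = merge_significant(table, method, max_gap_bp)
            hit = any(
                r.chrom == truth.spec.chromosome
                and r.start_bp - tolerance_bp <= truth.focal_pos <= r.end_bp + tolerance_bp
                for r in regs
            )
            detections[method].append(hit)
            top_pos, top_chrom = _top_snp_pos(table, col, absolute)
            err = (
                abs(top_pos - truth.focal_pos)
                if top_chrom == truth.spec.chromosome
                else float("inf")
            )
            loc_errors[method].append(err)
    methods = {}
    for m in stat_cols:
        if sweep is not None:
            rate = float(np.mean(detections[m]))
            se = float(np.sqrt(max(rate * (1 - rate), 1e-12) / replicates))
            fp = float("nan")
        else:
            rate, se = float("nan"), float("nan")
            fp = float(np.mean(fp_fracs[m]))
        methods[m] = MethodPower(rate, se, loc_errors[m], fp)
    return PowerReport(methods, replicates)
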