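"""Simulator: determinism, drift calibration, sweep implantation, QC injection."""

import numpy as np
import pytest

from sweepscan.fst import snp_fst
from sweepscan.panels import MISSING
from sweepscan.qc import apply_qc
from sweepscan.sim import (
    SimConfig,
    SweepSpec,
    implant_sweep,
    inject_qc_violations,
    simulate_neutral_panel,
)


def small_config(**kw):
    base = dict(
        n_samples_a=16, n_samples_b=8, n_chromosomes=2, snps_per_chromosome=150,
        chrom_length_bp=1_500_000, seed=7,
    )
    base.update(kw)
    return SimConfig(**base)


def test_same_seed_gives_bitwise_identical_panels():
    a = simulate_neutral_panel(small_config())
    b = simulate_neutral_panel(small_config())
    assert np.array_equal(a.haplotypes.haps, b.haplotypes.haps)
    assert a.genotypes.equals(b.genotypes)
    c = simulate_neutral_panel(small_config(seed=8))
    assert not np.array_equal(a.haplotypes.haps, c.haplotypes.haps)


def test_haplotypes_collapse_to_genotypes():
    res = simulate_neutral_panel(small_config())
    assert res.haplotypes.to_genotypes().equals(res.genotypes)


def test_positions_sorted_unique_within_chromosome():
    res = simulate_neutral_panel(small_config())
    for _, sub in res.genotypes.variants.groupby("chrom"):
        assert (np.diff(sub["pos"].to_numpy()) > 0).all()


def test_degenerate_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(n_samples_a=1)
    with pytest.raises(ValueError):
        SimConfig(snps_per_chromosome=0)
    with pytest.raises(ValueError):
        SimConfig(background_fst=1.0)


def _mean_sample_fst(sim_result, config):
    g = sim_result.genotypes
    n_a = config.n_samples_a
    p_a = g.calls[:n_a].mean(axis=0) / 2.0
    p_b = g.calls[n_a:].mean(axis=0) / 2.0
    return float(np.mean(snp_fst(p_a, p_b)))


def _oracle_mean_fst(config, n_snps, reps, seed):
    """Monte-Carlo oracle: the drift + binomial-sampling model simulated
    directly at the frequency level, bypassing the haplotype machinery."""
    rng = np.random.default_rng(seed)
    m_a, m_b = 2 * config.n_samples_a, 2 * config.n_samples_b
    F = config.background_fst
    means = []
    for _ in range(reps):
        maf = rng.uniform(*config.maf_range, size=n_snps)
        p = np.where(rng.random(n_snps) < 0.5, 1 - maf, maf)
        if F > 0:
            s = (1 - F) / F
            pa = rng.beta(p * s, (1 - p) * s)
            pb = rng.beta(p * s, (1 - p) * s)
        else:
            pa = pb = p
        pha = rng.binomial(m_a, pa) / m_a
        phb = rng.binomial(m_b, pb) / m_b
        means.append(np.mean(snp_fst(pha, phb)))
    return float(np.mean(means)), float(np.std(means, ddof=1) / np.sqrt(reps))


@pytest.mark.parametrize("background_fst", [0.0, 0.02])
def test_drift_calibration_against_frequency_level_oracle(background_fst):
    """Mean per-SNP FST from full panels matches a direct Monte-Carlo
    simulation of the same drift + sampling model, within 3 combined SEs."""
    reps = 5
    cfg = small_config(
        n_samples_a=64, n_samples_b=20, n_chromosomes=1,
        snps_per_chromosome=10_000, chrom_length_bp=50_000_000,
        background_fst=background_fst,
    )
    means = []
    for r in range(reps):
        res = simulate_neutral_panel(small_config(
            n_samples_a=64, n_samples_b=20, n_chromosomes=1,
            snps_per_chromosome=10_000, chrom_length_bp=50_000_000,
            background_fst=background_fst, seed=100 + r,
        ))
        means.append(_mean_sample_fst(res, cfg))
    obs = float(np.mean(means))
    obs_se = float(np.std(means, ddof=1) / np.sqrt(reps))
    exp, exp_se = _oracle_mean_fst(cfg, 10_000, reps, seed=999)
    assert abs(obs - exp) < 3 * np.sqrt(obs_se**2 + exp_se**2)
    if background_fst == 0.0:
        assert obs <= 0.01  # sampling noise only
    else:
        assert 0.01 <= obs <= 0.03


def test_sweep_focal_frequencies_hit_request():
    res = simulate_neutral_panel(small_config())
    spec = SweepSpec(chromosome="1", position_bp=750_000, freq_in_target=0.9,
                     freq_in_other=0.1, haplotype_block_bp=200_000)
    swept, truth = implant_sweep(res.haplotypes, spec, seed=3)
    n_t = 2 * 16
    n_o = 2 * 8
    assert abs(truth.realized_freq_target - 0.9) <= 1.0 / n_t
    assert abs(truth.realized_freq_other - 0.1) <= 1.0 / n_o
    focal = swept.variants.index[swept.variants["snp_id"] == truth.snp_id][0]
    groups = swept.hap_groups()
    assert swept.haps[groups == "prolific", focal].mean() == pytest.approx(
        truth.realized_freq_target
    )


def test_full_carrier_block_makes_carriers_identical():
    res = simulate_neutral_panel(small_config())
    spec = SweepSpec(chromosome="1", position_bp=750_000, freq_in_target=0.75,
                     freq_in_other=0.1, haplotype_block_bp=400_000,
                     block_carrier_fraction=1.0)
    swept, truth = implant_sweep(res.haplotypes, spec, seed=3)
    v = swept.variants
    in_block = ((v["chrom"] == "1") & v["pos"].between(truth.block_start, truth.block_end)).to_numpy()
    groups = swept.hap_groups()
    focal = v.index[v["snp_id"] == truth.snp_id][0]
    carriers = (groups == "prolific") & (swept.haps[:, focal] == 1)
    block = swept.haps[np.ix_(np.flatnonzero(carriers), np.flatnonzero(in_block))]
    assert (block == block[0]).all()
    # homozygosity bound at the block edge: at least the carrier-pair share
    k = carriers.sum()
    n = (groups == "prolific").sum()
    assert k * (k - 1) / (n * (n - 1)) > 0.4


def test_zero_carrier_fraction_leaves_block_unchanged():
    res = simulate_neutral_panel(small_config())
    spec = SweepSpec(chromosome="1", position_bp=750_000, block_carrier_fraction=0.0)
    swept, truth = implant_sweep(res.haplotypes, spec, seed=3)
    focal = swept.variants.index[swept.variants["snp_id"] == truth.snp_id][0]
    mask = np.ones(swept.n_snps, dtype=bool)
    mask[focal] = False
    assert np.array_equal(swept.haps[:, mask], res.haplotypes.haps[:, mask])


def test_monomorphic_both_groups_rejected():
    res = simulate_neutral_panel(small_config())
    spec = SweepSpec(chromosome="1", position_bp=750_000, freq_in_target=1.0,
                     freq_in_other=1.0)
    with pytest.raises(ValueError, match="monomorphic"):
        implant_sweep(res.haplotypes, spec, seed=3)


def test_sweep_outside_chromosome_rejected():
    res = simulate_neutral_panel(small_config())
    with pytest.raises(ValueError, match="outside"):
        implant_sweep(res.haplotypes, SweepSpec(chromosome="1", position_bp=10_000_000))


def test_injected_violations_recovered_by_qc():
    res = simulate_neutral_panel(small_config(
        n_samples_a=60, n_samples_b=24, snps_per_chromosome=200,
        maf_range=(0.15, 0.5),
    ))
    dirty, manifest = inject_qc_violations(
        res.genotypes, n_low_callrate=3, n_low_maf=7, n_hwe_fail=2,
        n_bad_samples=2, seed=5,
    )
    clean, report = apply_qc(dirty)
    assert sorted(report.removed_samples_missingness) == manifest.bad_samples
    assert sorted(report.removed_snps_call_rate) == manifest.low_callrate_snps
    assert sorted(report.removed_snps_maf) == manifest.low_maf_snps
    assert sorted(report.removed_snps_hwe) == manifest.hwe_fail_snps


def test_zero_injections_leave_clean_panel_passing():
    res = simulate_neutral_panel(small_config(
        n_samples_a=60, n_samples_b=24, maf_range=(0.15, 0.5),
    ))
    dirty, manifest = inject_qc_violations(res.genotypes, seed=5)
    assert np.array_equal(dirty.calls, res.genotypes.calls)
    _, report = apply_qc(dirty)
    assert report.n_samples_removed == 0
    assert report.n_snps_removed == 0


def test_violation_requests_beyond_panel_rejected():
    res = simulate_neutral_panel(small_config())
    with pytest.raises(ValueError):
        inject_qc_violations(res.genotypes, n_low_maf=10_000)
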