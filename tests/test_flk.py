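"""Reynolds distance, kinship, FLK closed form, cluster EM, hapFLK."""

import numpy as np
import pytest

from sweepscan.cluster import fit_cluster_model
from sweepscan.flk import (
    flk_stat,
    hapflk_stat,
    kinship_from_distance,
    reynolds_distance,
    sampling_corrected_kinship,
    scan_flk,
    standardize_hapflk,
)
from sweepscan.panels import GenotypePanel, HaplotypePanel
from sweepscan.sim import SimConfig, simulate_neutral_panel
from tests.conftest import make_samples, make_variants


def reynolds_oracle(calls_a, calls_b):
    """Per-locus hand evaluation of the bias-corrected coancestry estimator."""
    num = den = 0.0
    for j in range(calls_a.shape[1]):
        m1 = 2 * calls_a.shape[0]
        m2 = 2 * calls_b.shape[0]
        p1 = calls_a[:, j].sum() / m1
        p2 = calls_b[:, j].sum() / m2
        q1, q2 = 1 - p1, 1 - p2
        num += (p1 - p2) ** 2 - p1 * q1 / (m1 - 1) - p2 * q2 / (m2 - 1)
        den += 1 - p1 * p2 - q1 * q2
    return float(np.clip(num / den, 0.0, 1.0 - 1e-12))


def _panel_from_calls(calls_a, calls_b):
    calls = np.vstack([calls_a, calls_b]).astype(np.int8)
    return GenotypePanel(
        calls, make_variants(calls.shape[1]), make_samples(len(calls_a), len(calls_b))
    )


def test_reynolds_matches_per_locus_oracle(rng):
    for _ in range(20):
        n_loci = int(rng.integers(1, 6))
        calls_a = rng.integers(0, 3, size=(5, n_loci))
        calls_b = rng.integers(0, 3, size=(4, n_loci))
        panel = _panel_from_calls(calls_a, calls_b)
        try:
            got = reynolds_distance(panel)
        except ValueError:
            assert reynolds_oracle(calls_a, calls_b) <= 0 or np.isnan(
                reynolds_oracle(calls_a, calls_b)
            )
            continue
        assert got == pytest.approx(reynolds_oracle(calls_a, calls_b), abs=1e-12)


def test_reynolds_fixed_difference_saturates():
    calls_a = np.full((6, 4), 2)
    calls_b = np.full((5, 4), 0)
    assert reynolds_distance(_panel_from_calls(calls_a, calls_b)) > 0.999


def test_reynolds_null_is_unbiased(rng):
    thetas = []
    for rep in range(10):
        p = rng.uniform(0.1, 0.9, size=2000)
        calls_a = rng.binomial(2, p, size=(30, 2000))
        calls_b = rng.binomial(2, p, size=(20, 2000))
        thetas.append(reynolds_distance(_panel_from_calls(calls_a, calls_b)))
    se = np.std(thetas, ddof=1) / np.sqrt(len(thetas))
    assert abs(np.mean(thetas)) < max(3 * se, 1e-3)


def test_reynolds_tracks_simulator_background():
    res = simulate_neutral_panel(
        SimConfig(n_chromosomes=1, snps_per_chromosome=10_000,
                  chrom_length_bp=50_000_000, background_fst=0.02, seed=42)
    )
    theta = reynolds_distance(res.genotypes)
    assert 0.01 <= theta <= 0.03


def test_kinship_midpoint_split():
    F = kinship_from_distance(0.04)
    assert np.allclose(F, np.diag([0.02, 0.02]))
    assert np.allclose(kinship_from_distance(0.0), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        kinship_from_distance(1.0)


def test_sampling_correction_adds_binomial_term():
    F = sampling_corrected_kinship(np.diag([0.02, 0.02]), [128, 40])
    assert F[0, 0] == pytest.approx(0.02 + 0.98 / 128)
    assert F[1, 1] == pytest.approx(0.02 + 0.98 / 40)


def test_flk_closed_form_under_symmetric_kinship():
    f = 0.02
    F = np.diag([f, f])
    grid = np.linspace(0.01, 0.99, 99)
    for p_a in grid:
        for p_b in grid:
            p0 = (p_a + p_b) / 2
            want = (p_a - p_b) ** 2 / (2 * f * p0 * (1 - p0))
            got, _ = flk_stat(p_a, p_b, F)
            assert got == pytest.approx(want, abs=1e-10)


def test_flk_reference_points():
    F = np.diag([0.02, 0.02])
    t, p = flk_stat(0.3, 0.3, F)
    assert t == pytest.approx(0.0) and p == pytest.approx(1.0)
    t, _ = flk_stat(0.7, 0.3, F)
    assert t == pytest.approx(16.0, abs=1e-10)
    t, p = flk_stat(0.0, 0.0, F)  # degenerate ancestral frequency
    assert np.isnan(t) and np.isnan(p)


def _two_string_panel(n_snps=30, copies=8):
    rng = np.random.default_rng(0)
    s1 = rng.integers(0, 2, n_snps).astype(np.uint8)
    s2 = 1 - s1
    haps = np.vstack([np.tile(s1, (copies, 1)), np.tile(s2, (copies, 1))])
    return HaplotypePanel(
        haps, make_variants(n_snps), make_samples(copies // 2, copies // 2)
    )


def test_em_single_cluster_is_degenerate(rng):
    panel = _two_string_panel()
    runs = fit_cluster_model(panel, K=1, n_fit=1, seed=0)
    freqs = runs[0].group_freqs
    assert np.allclose(freqs[:, 0, :], 1.0)


def test_em_separates_two_distinct_strings():
    panel = _two_string_panel()
    runs = fit_cluster_model(panel, K=2, n_fit=20, seed=1)
    separated = 0
    for run in runs:
        # each group is a pure string: posterior mass concentrates on one cluster
        conc = run.group_freqs.max(axis=1)  # (n_groups, n_snps)
        if (conc > 0.99).all():
            separated += 1
    assert separated >= 18


def test_em_loglik_monotone_every_run():
    res = simulate_neutral_panel(
        SimConfig(n_samples_a=10, n_samples_b=6, n_chromosomes=1,
                  snps_per_chromosome=120, chrom_length_bp=600_000, seed=2)
    )
    runs = fit_cluster_model(res.haplotypes, K=4, n_fit=5, seed=2)
    for run in runs:
        for hist in run.loglik_histories:
            diffs = np.diff(hist)
            assert (diffs >= -1e-6 * np.abs(hist[:-1])).all()


def test_em_k_above_distinct_haplotypes_warns():
    panel = _two_string_panel()
    with pytest.warns(UserWarning, match="distinct"):
        fit_cluster_model(panel, K=5, n_fit=1, seed=0)


def test_hapflk_nonnegative_and_relabeling_invariant(rng):
    res = simulate_neutral_panel(
        SimConfig(n_samples_a=10, n_samples_b=6, n_chromosomes=1,
                  snps_per_chromosome=80, chrom_length_bp=400_000, seed=3)
    )
    runs = fit_cluster_model(res.haplotypes, K=3, n_fit=2, seed=3)
    F = sampling_corrected_kinship(np.diag([0.01, 0.01]), [20, 12])
    stat = hapflk_stat(runs, F)
    assert (stat >= 0).all()
    perm = rng.permutation(3)
    for run in runs:
        run.group_freqs = run.group_freqs[:, perm, :]
    assert np.allclose(hapflk_stat(runs, F), stat)


def test_hapflk_zero_when_groups_share_haplotypes():
    rng = np.random.default_rng(5)
    block = rng.integers(0, 2, size=(12, 25)).astype(np.uint8)
    haps = np.vstack([block, block])
    panel = HaplotypePanel(haps, make_variants(25), make_samples(6, 6))
    runs = fit_cluster_model(panel, K=3, n_fit=2, seed=5)
    F = sampling_corrected_kinship(np.diag([0.01, 0.01]), [12, 12])
    stat = hapflk_stat(runs, F)
    assert np.max(np.abs(stat)) < 1e-8


def test_hapflk_invariant_under_sample_duplication():
    panel = _two_string_panel(copies=4)
    doubled = HaplotypePanel(
        np.vstack([panel.haps[: 4], panel.haps[:4], panel.haps[4:], panel.haps[4:]]),
        panel.variants.copy(),
        make_samples(4, 4),
    )
    runs_1 = fit_cluster_model(panel, K=2, n_fit=1, seed=7)
    runs_2 = fit_cluster_model(doubled, K=2, n_fit=1, seed=7)
    assert np.allclose(
        np.sort(runs_1[0].group_freqs, axis=1),
        np.sort(runs_2[0].group_freqs, axis=1),
        atol=1e-3,
    )


def test_standardize_hapflk_reference_points(rng):
    from scipy.stats import norm

    raw = rng.normal(size=1000)
    z, p, sig = standardize_hapflk(raw)
    assert z.mean() == pytest.approx(0.0, abs=1e-9)
    assert norm.sf(3.0902) == pytest.approx(0.001, rel=1e-3)
    with pytest.raises(ValueError):
        standardize_hapflk(np.full(10, 2.0))


def test_scan_flk_outputs_are_coherent():
    res = simulate_neutral_panel(
        SimConfig(n_samples_a=12, n_samples_b=8, n_chromosomes=2,
                  snps_per_chromosome=60, chrom_length_bp=300_000, seed=9)
    )
    track = scan_flk(res.haplotypes, K=3, n_fit=2, seed=9)
    t = track.table
    assert len(t) == res.haplotypes.n_snps
    ok = np.isfinite(t["flk"])
    assert (t["flk"][ok] >= 0).all()
    assert ((t["flk_p"][ok] > 0) & (t["flk_p"][ok] <= 1)).all()
    assert (t["hapflk"] >= 0).all()
    assert t["hapflk_std"].mean() == pytest.approx(0.0, abs=1e-9)
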