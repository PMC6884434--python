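"""fastPHASE-style haplotype-cluster model fitted by EM.

Each haplotype is modelled as a hidden Markov chain over K local clusters.
Cluster k emits the alternate allele at SNP j with probability theta[k, j];
between adjacent SNPs the chain either stays put or, with a per-interval
switch probability r[j], jumps to a cluster drawn from global weights pi.
Chains restart at chromosome boundaries.  The model is fitted by
Baum–Welch EM with seeded random restarts; convergence is declared when the
relative log-likelihood improvement drops below a tolerance (default 1e-4)
or after a hard iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
import pandas as pd
from numba import njit

from .panels import HaplotypePanel
from .sim import child_rng

_THETA_MIN = 1e-4
_R_MIN = 1e-5


@njit(cache=True)
def _em_chrom(haps, theta, pi, r, max_iter, tol):  # pragma: no cover - via fit
    n_hap, n_snp = haps.shape
    K = theta.shape[0]
    f = np.empty((n_snp, K))
    c = np.empty(n_snp)
    b = np.empty(K)
    eb = np.empty(K)
    ll_hist = np.empty(max_iter)
    n_it = 0
    ll_prev = -np.inf
    for it in range(max_iter):
        th_num = np.zeros((K, n_snp))
        th_den = np.zeros((K, n_snp))
        pi_num = np.zeros(K)
        jump = np.zeros(max(n_snp - 1, 1))
        ll = 0.0
        for h in range(n_hap):
            # ---- forward (scaled)
            s = 0.0
            for k in range(K):
                e = theta[k, 0] if haps[h, 0] == 1 else 1.0 - theta[k, 0]
                f[0, k] = pi[k] * e
                s += f[0, k]
            c[0] = s
            for k in range(K):
                f[0, k] /= s
            ll += np.log(s)
            for j in range(1, n_snp):
                rr = r[j - 1]
                s = 0.0
                for k in range(K):
                    e = theta[k, j] if haps[h, j] == 1 else 1.0 - theta[k, j]
                    v = ((1.0 - rr) * f[j - 1, k] + rr * pi[k]) * e
                    f[j, k] = v
                    s += v
                c[j] = s
                for k in range(K):
                    f[j, k] /= s
                ll += np.log(s)
            # ---- backward with sufficient-statistic accumulation
            for k in range(K):
                b[k] = 1.0
                g = f[n_snp - 1, k]
                th_den[k, n_snp - 1] += g
                if haps[h, n_snp - 1] == 1:
                    th_num[k, n_snp - 1] += g
            for j in range(n_snp - 2, -1, -1):
                rr = r[j]
                sum_pieb = 0.0
                for k in range(K):
                    e = theta[k, j + 1] if haps[h, j + 1] == 1 else 1.0 - theta[k, j + 1]
                    eb[k] = e * b[k]
                    sum_pieb += pi[k] * eb[k]
                inv_c = 1.0 / c[j + 1]
                jump[j] += rr * sum_pieb * inv_c
                for k in range(K):
                    pi_num[k] += rr * pi[k] * eb[k] * inv_c
                    b[k] = ((1.0 - rr) * eb[k] + rr * sum_pieb) * inv_c
                for k in range(K):
                    g = f[j, k] * b[k]
                    th_den[k, j] += g
                    if haps[h, j] == 1:
                        th_num[k, j] += g
            for k in range(K):
                pi_num[k] += f[0, k] * b[k]
        ll_hist[it] = ll
        n_it = it + 1
        if it > 0 and (ll - ll_prev) < tol * abs(ll_prev):
            break
        ll_prev = ll
        # ---- M-step
        for k in range(K):
            for j in range(n_snp):
                if th_den[k, j] > 1e-12:
                    v = th_num[k, j] / th_den[k, j]
                    if v < _THETA_MIN:
                        v = _THETA_MIN
                    elif v > 1.0 - _THETA_MIN:
                        v = 1.0 - _THETA_MIN
                    theta[k, j] = v
        for j in range(n_snp - 1):
            v = jump[j] / n_hap
            if v < _R_MIN:
                v = _R_MIN
            elif v > 1.0 - _R_MIN:
                v = 1.0 - _R_MIN
            r[j] = v
        s = 0.0
        for k in range(K):
            if pi_num[k] < 1e-9:
                pi_num[k] = 1e-9
            s += pi_num[k]
        for k in range(K):
            pi[k] = pi_num[k] / s
    return ll_hist[:n_it]


@njit(cache=True)
def _posteriors_chrom(haps, theta, pi, r, group_codes, n_groups):  # pragma: no cover
    n_hap, n_snp = haps.shape
    K = theta.shape[0]
    f = np.empty((n_snp, K))
    c = np.empty(n_snp)
    b = np.empty(K)
    eb = np.empty(K)
    acc = np.zeros((n_groups, K, n_snp))
    counts = np.zeros(n_groups)
    for h in range(n_hap):
        g_idx = group_codes[h]
        counts[g_idx] += 1.0
        s = 0.0
        for k in range(K):
            e = theta[k, 0] if haps[h, 0] == 1 else 1.0 - theta[k, 0]
            f[0, k] = pi[k] * e
            s += f[0, k]
        c[0] = s
        for k in range(K):
            f[0, k] /= s
        for j in range(1, n_snp):
            rr = r[j - 1]
            s = 0.0
            for k in range(K):
                e = theta[k, j] if haps[h, j] == 1 else 1.0 - theta[k, j]
                v = ((1.0 - rr) * f[j - 1, k] + rr * pi[k]) * e
                f[j, k] = v
                s += v
            c[j] = s
            for k in range(K):
                f[j, k] /= s
        for k in range(K):
            b[k] = 1.0
            acc[g_idx, k, n_snp - 1] += f[n_snp - 1, k]
        for j in range(n_snp - 2, -1, -1):
            rr = r[j]
            sum_pieb = 0.0
            for k in range(K):
                e = theta[k, j + 1] if haps[h, j + 1] == 1 else 1.0 - theta[k, j + 1]
                eb[k] = e * b[k]
                sum_pieb += pi[k] * eb[k]
            inv_c = 1.0 / c[j + 1]
            for k in range(K):
                b[k] = ((1.0 - rr) * eb[k] + rr * sum_pieb) * inv_c
            for k in range(K):
                acc[g_idx, k, j] += f[j, k] * b[k]
    for g_idx in range(n_groups):
        if counts[g_idx] > 0:
            for k in range(K):
                for j in range(n_snp):
                    acc[g_idx, k, j] /= counts[g_idx]
    return acc


@dataclass
class ClusterModel:
    """One EM run of the haplotype-cluster model over the whole genome."""

    K: int
    seed: int
    theta: np.ndarray  # (K, n_snps) per-cluster alternate-allele frequency
    switch: np.ndarray  # (n_snps,) jump probability into each SNP (1 at chrom starts)
    pi_by_chrom: list  # cluster weights per chromosome
    loglik_histories: list  # per chromosome, non-decreasing within a run
    group_freqs: np.ndarray  # (n_groups, K, n_snps) posterior cluster frequencies
    groups: list  # group labels, order matches group_freqs rows

    @property
    def loglik(self) -> float:
        return float(sum(h[-1] for h in self.loglik_histories))


def fit_cluster_model(
    panel: HaplotypePanel,
    K: int = 10,
    n_fit: int = 20,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> list[ClusterModel]:
    """Fit ``n_fit`` seeded EM restarts of the K-cluster LD model.

    Every run is retained (downstream statistics average over runs).  K
    larger than the number of distinct haplotypes is allowed (clusters may
    stay empty); a warning is emitted.
    """
    if K < 1 or n_fit < 1:
        raise ValueError("K and n_fit must be >= 1")
    groups = list(pd.unique(panel.samples["group"]))
    group_of = {g: i for i, g in enumerate(groups)}
    group_codes = np.array([group_of[g] for g in panel.hap_groups()], dtype=np.int64)

    n_distinct = len({tuple(row) for row in panel.haps})
    if K > n_distinct:
        warn(f"K={K} exceeds the {n_distinct} distinct haplotypes; clusters may stay empty",
             stacklevel=2)

    blocks = panel.chromosome_blocks()
    runs = []
    for run in range(n_fit):
        rng = child_rng(seed, "em", run)
        theta_full = np.empty((K, panel.n_snps))
        switch_full = np.empty(panel.n_snps)
        pis, hists = [], []
        freqs = np.empty((len(groups), K, panel.n_snps))
        for chrom, cols in blocks:
            haps = np.ascontiguousarray(panel.haps[:, cols], dtype=np.uint8)
            p = haps.mean(axis=0)
            theta = np.clip(
                p[None, :] + rng.normal(0.0, 0.2, size=(K, cols.size)), 0.05, 0.95
            )
            pi = np.full(K, 1.0 / K) + rng.uniform(0, 0.01, K)
            pi /= pi.sum()
            r = np.full(max(cols.size - 1, 1), 0.05)
            hist = _em_chrom(haps, theta, pi, r, max_iter, tol)
            hists.append(hist)
            pis.append(pi)
            theta_full[:, cols] = theta
            switch_full[cols[0]] = 1.0
            if cols.size > 1:
                switch_full[cols[1:]] = r[: cols.size - 1]
            freqs[:, :, cols] = _posteriors_chrom(
                haps, theta, pi, r, group_codes, len(groups)
            )
        runs.append(
            ClusterModel(K, seed, theta_full, switch_full, pis, hists, freqs, groups)
        )
    return runs
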