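# Methods

`sweepscan` implements a two-group genome scan for selection signatures of
the kind used to map prolificacy loci in livestock: per-SNP differentiation
(smoothed FST), a drift-aware frequency test extended to local haplotype
clusters (FLK / hapFLK-style), and cross-population extended haplotype
homozygosity (XP-EHH).  Because array datasets of this kind are usually not
redistributable, the package ships a calibrated simulator that reproduces the
study design — two groups of diploid samples genotyped at array density, with
weak background differentiation and, optionally, implanted sweeps — so every
statistic can be validated against ground truth.

## Synthetic data model

Neutral panels follow a Balding–Nichols drift model.  Each SNP draws an
ancestral minor-allele frequency uniformly from `maf_range` (default
0.05–0.5, the common-variant regime a genotyping array targets) and a random
allele orientation.  Each group's population frequency is a Beta draw with
mean p and variance `background_fst`·p(1−p); haplotypes are then sampled
allele-by-allele from the group frequency (linkage equilibrium), and
genotypes are the sum of the two haplotypes per sample, i.e. exact
Hardy–Weinberg sampling.  Defaults: 64 vs 20 samples, 4 chromosomes × 5,000
SNPs over 25 Mb each (one SNP per ~5 kb, HD-array-like density),
`background_fst` = 0.02.

Linkage equilibrium outside implanted blocks is a deliberate simplification:
it makes the EHH background decay within a handful of SNPs so that implanted
haplotype blocks are unambiguous, and it gives closed-form expectations for
calibration.  It also means passing tests say nothing about behaviour under
realistic background LD, recombination-map structure, or demography — those
are out of scope.

Under this model the expected value of the per-SNP FST statistic (below)
computed from *sample* frequencies is F/2 + (1/m_A + 1/m_B)/4 to first
order, where m_g are allele counts: the squared-deviation FST of a frequency
*pair* absorbs only half of the per-group drift variance, and finite samples
add binomial noise.  With the default design (F = 0.02, m = 128 and 40) this
is ≈ 0.018.  The simulator's calibration test therefore checks the realized
mean against a direct Monte-Carlo evaluation of the same frequency-level
model rather than against a nominal constant; the 0.001–0.05 background band
quoted for array data of this kind is comfortably covered.

A sweep is implanted by forcing the focal SNP's allele frequency to
requested values in the two groups (default 0.9 in the target group, 0.1 in
the other) and copying a single core haplotype across a block (default
500 kb, centred on the focal SNP) onto a fraction (default all) of the
focal-allele carriers in the target group.  This creates the two signals the
scans target: allele-frequency differentiation and one long, shared
haplotype at high frequency in one group only.  The realized frequencies,
block bounds and carrier counts are recorded as ground truth.

QC-violation injection degrades designated SNPs/samples past the filter
thresholds by construction (e.g. an all-heterozygous SNP for a guaranteed
Hardy–Weinberg failure; >5% missing calls for a call-rate failure) with
disjoint designations in a fixed priority order (call rate, then MAF, then
HWE), and places degraded entries only in samples not themselves designated
bad, so the sample-first filter order cannot silently consume a SNP
designation.

## Quality control

Filters run in a fixed order — samples with call rate < 90% first, then
SNPs without genomic positions, SNP call rate < 95%, MAF < 1%, and an exact
conditional Hardy–Weinberg test at P < 1e−6 — with per-SNP metrics
recomputed after sample removal.  All "lower than" thresholds are strict: a
SNP with call rate exactly 0.95 is retained.  The HWE test is the exact
conditional test (enumerating heterozygote counts given allele counts,
two-sided by summing probabilities not exceeding the observed one), matching
the behaviour of standard array-QC tooling; monomorphic SNPs return p = 1.
X-chromosome SNPs pass through the same per-SNP filters as autosomes and are
never excluded wholesale.  PCA mean-imputes missing calls per SNP, centres,
and reports each component's percentage of total genetic variance.

## Smoothed FST

Per SNP, with group frequencies p_A, p_B and p̄ = (p_A + p_B)/2:

    FST = ½ [ (p_A − p̄)² + (p_B − p̄)² ] / (p̄ q̄)

which is 0 at equal frequencies and 1 at a fixed difference.  Monomorphic
SNPs return 0 (not NaN) so the smoother has no holes; they can never be
outliers.  Smoothing is Nadaraya–Watson local averaging with an Epanechnikov
kernel; the bandwidth at SNP i is the physical distance to its 5th-nearest
SNP (self included), which reproduces "5-SNP window" semantics on irregular
maps, never crosses chromosome boundaries, and degenerates to the identity
at window 1.  Outliers are smoothed values strictly above the genome-wide
mean + 3 SD.  Only the upper tail is flagged: low-differentiation SNPs are
not evidence of selection in this contrast (a two-tail option exists for
completeness).

## XP-EHH

EHH is the site variant used by cross-population statistics: all haplotypes
of one group are followed outward from the core SNP together, EHH(x) being
the probability that two random haplotypes are identical over core..x
(pair counting over distinct strings).  EHH at zero extension is defined as
1.  Curves extend until EHH < 0.05 (configurable) or the chromosome end
(flagged truncated; such SNPs are kept but can be dropped with a switch).
iHH integrates EHH over physical bp by trapezoid, both directions summed,
stopping at the linearly interpolated cutoff crossing.  Distances are
physical because array data of this kind carries no genetic map.  Raw
XP-EHH = ln(iHH_A/iHH_B) is standardized genome-wide by mean/SD; p-values
are two-sided normal with the sign (which group the sweep favours) reported
separately, significant at P < 0.001.  On neutral panels the P < 0.001
fraction is binomially consistent with the nominal two-sided rate 0.002
(verified in the acceptance suite).

## FLK and hapFLK

The Reynolds coancestry θ between the two groups is estimated as a ratio of
locus-sums: numerator (p_A − p_B)² minus its binomial sampling bias
(p_g q_g/(m_g − 1) per group), denominator 1 − p_A p_B − q_A q_B.  The
estimator is unbiased at θ = 0, saturates at 1 for fixed differences, and
recovers the simulator's background differentiation.  The kinship matrix for
the two-group contrast is the star tree with a midpoint root,
F = diag(θ/2, θ/2) — the only symmetric choice without an outgroup.

The FLK variance model for observed sample frequencies includes binomial
sampling on top of drift:

    Var(p̂_g) = p0 q0 (F_gg + (1 − F_gg)/m_g)

With the study's sample sizes (128 vs 40 alleles) the sampling term is the
same order as the drift term, so omitting it would inflate the statistic
~80%; the scan therefore always folds it into the kinship diagonal.  p0 is
the GLS mean (for a diagonal kinship the weights are frequency-free, so the
one-step plug-in refinement is already exact); T is the quadratic form of
the residuals with p-values from chi-square with 1 df.  SNPs whose estimated
ancestral frequency is 0 or 1 are excluded.  The chi-square reference is
asymptotic: with 40 alleles it is accurate for common variants but
conservative below MAF ≈ 0.1 (measured type-I ≈ 0.017 there vs 0.050–0.054
above), so the calibration experiments run in the MAF 0.2–0.5 regime.

hapFLK applies the same quadratic form to local haplotype-cluster
frequencies.  The LD model is fastPHASE-style: a hidden Markov chain over K
clusters per haplotype, Bernoulli emissions theta[k, j], and jump-to-weights
transitions with a per-interval switch probability, fitted by Baum–Welch EM
with seeded random restarts (defaults K = 10, 20 restarts; the scaled test
configurations use K = 5 with 3–5 restarts and state so).  Convergence is
declared at relative log-likelihood improvement < 1e−4 (an absolute
tolerance is meaningless against a total log-likelihood of order 1e6) or
100 iterations; emission and switch parameters are clipped away from 0/1 by
1e−4/1e−5, so the monotonicity guarantee of EM holds up to that clipping
(asserted to 1e−6 relative).  Group cluster frequencies are posterior (soft)
means; per SNP, each cluster is tested one-vs-rest with the FLK form and
summed over clusters — a documented simplification of the full multivariate
statistic — then averaged across restarts, z-standardized genome-wide, with
one-sided upper-tail normal p-values at P < 0.001.

**Null-distribution caveat.**  The cluster statistic is a sum of K
positively-correlated quadratic terms: its null is chi-square-like (skew
≈ 0.9, moment-matched df ≈ 8.5 under the scaled test configuration), so the
fraction of neutral SNPs beyond the normal 0.001 quantile is ~0.006, not
0.001 — the same reason the original haplotype-cluster software calibrates
against an empirically fitted chi-square rather than a literal normal tail.
Moreover the HMM's posterior smoothing gives the statistic a 20–50-SNP
autocorrelation length, so exceedances arrive in bursts and no marginal
transformation can make tail *counts* binomial.  The normal standardization
is retained because it is the convention this pipeline follows; its
significance calls should be read as a ranking with an approximate
threshold, not as calibrated per-SNP error control — power and localization
against implanted truth are the meaningful guarantees, and those are
asserted in the acceptance suite.

## Candidate regions

Significant SNPs merge into a region when consecutive significant SNPs on a
chromosome are ≤ 500 kb apart (configurable; reported in output metadata
because region counts depend on it — the default is justified by LD decaying
over ~0–300 kb on ovine-type array maps, with headroom).  Region bounds are
significant-SNP positions, 1-based inclusive internally; BED output is
0-based half-open.  Gene overlap distinguishes full coverage from partial
overlap; when nothing overlaps, the nearest gene on the chromosome is
reported with the bp gap between closest edges and a side label.  Strand is
carried through but ignored for overlap.

## Pipeline, seeds, problem sizes

One master seed fans out to per-stage child generators (FNV-hashed stage
labels into a SeedSequence spawn key), so identical configurations reproduce
outputs bit-identically and stages are independently reproducible.  The
power harness simulates a genome per replicate, runs all three scans, and
scores detection (a significant region within 250 kb of the implanted focal
SNP) and localization (distance from the top-statistic SNP to truth).

Problem sizes used by the test and acceptance runs were chosen to exercise
the full study design at tractable cost: 20,000-SNP genomes (4 × 5,000) for
power with 50 replicates at K = 5, 3 EM restarts, 12 EM iterations —
detection is insensitive to deeper EM fitting because the implanted signal
is far above threshold — and 10,000-SNP genomes for null calibrations at
K = 5 with 5 restarts.  The acceptance script repeats the power experiment
at 20 replicates.

## Known limitations

- Background linkage equilibrium (see above): no realistic LD, no genetic
  map, no demography, no mutation model, no male hemizygosity.
- hapFLK p-values are approximate by construction (see the null caveat).
- Single-SNP FLK run through the scan uses the Reynolds-derived midpoint
  kinship, which for a pair estimate understates pair variance relative to
  the per-branch drift actually simulated; its scan p-values are therefore
  conservative.  hapFLK is unaffected (genome-wide standardization cancels
  scale), and calibration experiments pass the known simulation kinship
  explicitly.
- The .ped dialect cannot represent the unobserved allele of a monomorphic
  SNP; round-trips through .ped are exact at the allele-letter level.
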