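# Methods

## Statistical model

The unit of observation is the beta value β ∈ [0, 1] of one CpG probe
in one sample (methylated intensity over total intensity plus an
offset). The analyses exploit the paired structure of monozygotic twin
data: for a pair discordant for the phenotype, the within-pair
difference Δβ = β(affected) − β(unaffected) removes all additive
effects shared by the co-twins (genotype, age, sex, shared environment,
and — because each pair is hybridised on one array — array batch).

**Paired test.** Per probe, t = mean(Δ) / (sd(Δ)/√n) with n − 1 degrees
of freedom and a two-sided p. Probes with fewer than two complete pairs
or zero variance of Δ are reported with a missing p and a note
("constant differences") rather than dropped silently. Ranking is by p
ascending with ties broken by |mean Δβ| descending, then probe id, so
ranks are always a permutation of 1..n_probes. The Bonferroni flag uses
0.05 / n_testable.

**Sign-flip permutation.** Re-assigning affected/unaffected labels
within pairs is equivalent to flipping the sign of each pair's Δ. Sign
flips leave Σ Δ² unchanged, so permuted t statistics are computed from
the flipped means alone (vectorised over all assignments). With n pairs
and a cap of 10,000, enumeration is exhaustive when 2ⁿ ≤ cap (8192
assignments at n = 13) and Monte Carlo with replacement otherwise
(10,000 draws at n = 37); the identity assignment is a member of the
exhaustive set but is *not* force-included in Monte Carlo draws, which
is what allows a zero count and the "<1/n" report. The default counting
rule is permuted p ≤ observed p (the observed p is recomputed with the
identical vectorised formula so the identity compares exactly equal); a
`below_threshold` rule (permuted p < 10⁻⁴) is available as an
alternative reading of "at least as significant as the true result".
No add-one correction is applied, so a zero count reports the
resolution bound rather than a pseudo-count.

Two structural facts worth knowing: (i) in exhaustive mode the identity
is always counted, so empirical p ≥ 1/2ⁿ; (ii) for a two-sided
statistic the all-flipped assignment produces exactly the observed p,
so counts come in mirror pairs and the attainable floor is 2/2ⁿ
(2/8192 ≈ 2.4 × 10⁻⁴ at 13 pairs). A probe whose differences are
identically zero has no defined permutation distribution and is
rejected ("permutation undefined for degenerate probe"); a row with
zero variance but nonzero mean is treated as maximally significant
(p = 0), which makes the all-equal-|Δ| configuration behave as the
enumeration says it should (2 of 16 assignments at n = 4).

**Stratification and specificity.** Pairs discordant at the childhood
assessment split by the early-adulthood phenotype into persistent
(still discordant), remission (both unaffected) and — excluded from
group comparisons — concordant-affected and unknown-follow-up pairs;
concordant-unaffected pairs (unaffected at both ages) form the control
stratum. Concordant pairs have no affected/unaffected orientation, so
their within-pair difference is defined under a random orientation.
Two quantities are computed: (a) a permutation baseline — the mean over
1000 random orientation draws of the cohort-average within-pair
difference, zero in expectation by sign symmetry, reported with its
replicate distribution; and (b) per-pair differences under a single
seeded orientation, which enter the one-way fixed-effects ANOVA so the
concordant group contributes its honest n = 19 observations. Post hoc
pairwise comparisons are pooled-variance t-tests with Holm adjustment
(raw p also emitted; Welch variants behind a flag). Which observations
entered the original ANOVA's concordant group is ambiguous in the
source design, so both quantities are emitted and either can be
compared.

**Longitudinal change.** For each individual with samples at both
ages, longitudinal Δβ = β(age 10) − β(age 5); the persistent-stratum
contrast is the paired t on the within-pair difference of longitudinal
change. By construction Δβ₁₀ − Δβ₅ (within-pair) equals that contrast
exactly — asserted as an algebraic identity in the tests. Pairs missing
either member at the earlier age are excluded pair-wise. The reported
"co-twin mean"/"affected mean" columns are means of *change* and can
be negative. The probe universe is the intersection of probes
surviving QC at both ages, and the earlier-age per-probe tests are run
at the later age's top-ranked probes (threshold configurable).

**Gene-set enrichment.** The universe is every gene with ≥ 1 retained
probe (probes annotated to several ";"-separated genes count toward
each); a gene is significant when any of its probes is below the
nominal threshold (default 10⁻³). The probability weighting function
(PWF) is an isotonic (monotone non-decreasing) least-squares fit of the
significance indicator on probes-per-gene, floored at 10⁻⁶ and rescaled
to mean = observed significant fraction. The null draws gene sets of
the observed significant-set size without replacement with inclusion
probability proportional to the PWF — sequential selection with
renormalisation, realised by exponential sort keys (top-k of
Exp(1)/wᵢ), which is distributionally identical and vectorises. Per
term, p = (1 + #{null sets with overlap ≥ observed}) / (1 + n_samples),
bounded below by the add-one floor. The Wallenius-approximation route
some tools offer is out of scope; the sampling route is exactly
specifiable and oracle-testable (it converges to the sampling
hypergeometric test under uniform weights). Term membership is taken
from a user-supplied gene→term table; no ontology-graph propagation is
performed.

## Quality control

Sample filter: fraction of probes with detection p > 0.05 is ≥ 5%
(inclusive boundary); the co-twin of a removed sample is dropped from
paired analyses. Probe filters: bead count < 3 in ≥ 5% of retained
samples, blacklisted (non-specific) probes, chrX/chrY probes, and SNP
control probes (excluded from analysis, retained for the zygosity
check). Filters run samples first, then probes, so probe fractions are
computed on retained samples. An optional detection-p *probe* rule
(off by default) is available since the source description conflates
the sample and probe readings of its filter sentence. Normalisation
quantile-maps methylated and unmethylated intensities separately within
each probe design type (type I/II chemistries differ in dynamic range)
before β = M / (M + U + 100); the offset follows platform convention.
Exact parity with any published normalisation package is a non-goal —
pre-normalised beta input bypasses the step, and that is the primary
path for synthetic data. Monozygosity is verified as the within-pair
Pearson correlation over ≥ 2 SNP control probes (genotype-driven betas
cluster near 0/0.5/1 and are identical in MZ twins); pairs below
r = 0.9 are flagged. The threshold is a default, not a sourced value,
and no genotype calling is attempted.

## Synthetic cohort generator

Per probe j, a baseline mean m_j is drawn from a three-component Beta
mixture — 40% low-methylated Beta(14, 56) (mode ≈ 0.2), 40%
high-methylated Beta(56, 14), 20% intermediate Beta(8, 8) — and each
sample value is

m_j + pair effect + batch effect + individual effect + noise
(+ common age drift at the later age) (+ planted effects), clamped to [0, 1].

Pair effects (sd 0.015) and individual effects (sd 0.035) persist
across ages; batch effects (sd 0.010) are drawn per pair × age (each
pair shares an array per collection wave); measurement noise
(sd 0.0335) is independent per value; a common per-probe drift
(sd 0.01) moves both co-twins equally between ages. Planted effects are
added to the affected twin only: cross-sectional Δβ at the later age
(magnitudes drawn from 0.003–0.14, the range a discordant-twin study of
this size can surface), optionally at the earlier age, and differential
longitudinal drift; all planted probes and their effects are emitted in
a truth table. Strata default to 13 persistent / 20 remission / 19
concordant-unaffected / 3 concordant-affected pairs plus one discordant
pair lost to follow-up (37 discordant pairs in total); 2 persistent and
4 remission pairs lack earlier-age samples. All randomness derives from
one master seed through independent child streams, so generation is
fully deterministic.

**Calibration.** The variance components were fixed by a one-time
calibration run targeting a mean within-pair correlation of 0.97 across
probes (the hallmark of MZ twins on methylation arrays): with the
mixture above, the shared variance (mixture ≈ 0.077 + pair² + batch²)
against unshared variance (individual² + noise² ≈ 0.0023) gives
r ≈ 0.970, verified at 0.9703–0.9705 over several seeds. The mixture
modes sit at 0.2/0.8 rather than pressed against the boundaries: with
modes at 0.1/0.9 the unshared spread required for r = 0.97 forces more
than 1% of values onto the 0/1 boundary, and clamping rare (< 1% of
values, measured ≈ 0.13% at defaults) was kept as a hard property so
that beta-scale effect arithmetic stays essentially undistorted.
Effects are added on the beta scale and clamped — matching the Δβ
arithmetic of the analyses — which slightly shrinks planted effects
whose baseline sits near a boundary; recovery tests therefore plant on
intermediate baselines when they assert exact effect recovery.

**What the generator does not emulate:** raw intensities/IDAT-level
artefacts, cell-type heterogeneity, SNP-confounded probes, spatial
correlation along the genome, and non-Gaussian tail behaviour of
within-pair differences. Passing tests on synthetic cohorts validate
the statistical machinery under the assumed structure; they do not
certify performance on real arrays where these features are present.

## Numerical and design choices

* Beta scale throughout (no M-values), matching the reported statistics
  of the study design this package targets; two-sided tests everywhere.
* Missing values: complete-pair analysis per probe, with per-probe n
  reported; "NA"/empty cells both read as missing, written back as "NA".
* Permutation counting uses a relative tolerance of 10⁻¹² when
  comparing permuted to observed p, so exact ties (identity, mirror)
  are never lost to rounding.
* The ANOVA uses classical equal-variance F; on two groups it equals
  the squared pooled t (checked numerically).
* Isotonic PWF fitting degenerates gracefully: all-or-none significance
  or a single distinct probe count falls back to uniform weights with a
  warning.
* Output tables carry 4-decimal rounding only at presentation; files
  round-trip at full float precision (readers parse with round-trip
  float precision).
* Pipeline seeds: one master seed, five named child seeds (permutation
  × 2 strata, concordant orientation, baseline, enrichment) derived via
  a seed sequence and logged in the run manifest.

## Problem sizes used in validation

The test suite exercises cohorts of 20,000 probes for calibration and
uniformity checks, 200-replicate simulations at 20,000 probes for
planted-effect recovery, 200 replicates of the full 13/20/19 strata
design (60 probes) for specificity power, and pooled enrichment runs of
4000 genes × 120 terms × 3 replicates. The enrichment-bias check uses
modest per-gene selection probabilities (≈ 0.03–0.29) and large terms
(400–900 genes): the weighted-sampling null matches
independent-Bernoulli significance conditioned on its total only when
selection probabilities are well below one, and large expected overlaps
keep the discrete p-value support fine enough for a
Kolmogorov–Smirnov uniformity check to be calibrated.

## Known limitations

* The quantile step approximates, but does not reproduce bit-for-bit,
  the background-adjusted normalisation of established array pipelines.
* The zygosity check is correlation-based; it flags, it does not call
  genotypes.
* Per-probe permutation p-values are marginal (no step-down/max-T
  family-wise control), mirroring the per-DMP empirical reporting of
  the target design.
* The enrichment module tests terms as given; parent-term propagation
  through the ontology graph is the caller's responsibility.
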