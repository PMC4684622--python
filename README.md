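# twinmeth

Paired EWAS toolkit for disease-discordant monozygotic (MZ) twin
DNA-methylation studies.

Disease-discordant MZ twins are a powerful design for epigenetic
epidemiology: co-twins are matched for genotype, age, sex and shared
environment, so within-pair differences in DNA methylation isolate
non-shared (potentially disease-related) influences. `twinmeth`
implements the statistical core of such a study on methylation-array
beta values (β = M / (M + U + offset) ∈ [0, 1]):

* **Paired differential methylation** — per CpG probe, the within-pair
  difference Δβ = β(affected) − β(unaffected co-twin) is tested with a
  paired *t*-test (df = n_pairs − 1); probes are ranked by *p* and
  flagged at the Bonferroni threshold 0.05 / n_probes.
* **Sign-flip permutation empirical p** — for top-ranked probes
  (nominal *p* < 10⁻⁴), affected/unaffected labels are re-assigned
  within pairs (equivalently, the signs of the pair differences are
  flipped); with *n* pairs all 2ⁿ assignments are enumerated when
  2ⁿ ≤ 10,000 (e.g. 8192 for 13 pairs) and sampled otherwise, and
  empirical *p* = (#assignments at least as significant) / n_assignments,
  reported as "<1/n" when the count is zero.
* **Persistence stratification** — pairs discordant in childhood split
  into a *persistent* stratum (still discordant in early adulthood) and
  a *remission* stratum; within-pair Δβ at probes of interest is
  compared across persistent / remission / concordant-unaffected groups
  by one-way ANOVA with Holm-adjusted pairwise *t*-tests, alongside a
  concordant-twin permutation baseline (mean within-pair difference
  under 1000 random twin orientations).
* **Longitudinal Δβ** — intra-individual change between two sampling
  ages, with its within-pair contrast tested by the same paired *t*.
* **Gene-set enrichment with probe-count correction** — genes covered
  by many probes get more chances to contain a significant probe; a
  monotone probability weighting function (PWF) of significance versus
  probes-per-gene, fitted by isotonic regression, drives a weighted
  resampling null with add-one-corrected per-term p-values.
* **Calibrated synthetic cohorts** — a generator that reproduces the
  statistical structure these analyses assume (bimodal beta landscape,
  within-pair correlation ≈ 0.97, strata of 13/20/19/3 pairs plus one
  pair lost to follow-up, planted effects with a truth table) for
  validation and power studies.
* **Array QC** — detection-p sample filtering, bead-count / blacklist /
  sex-chromosome probe filtering, per-design-type quantile
  normalisation, and a SNP-control-probe zygosity check.

## Worked example

```python
from twinmeth import TwinCohortConfig, generate_cohort, empirical_p_batch
from twinmeth.ewas import paired_ewas, delta_beta, discordant_pairs, \
    within_twin_correlation

cohort = generate_cohort(TwinCohortConfig(n_probes=5000, seed=7))
snp = cohort.annotation.set_index("probe_id").is_snp_control
beta = cohort.beta_age10.loc[~snp.loc[cohort.beta_age10.index].to_numpy()]
pairs = discordant_pairs(cohort.sample_sheet)

results = paired_ewas(beta, cohort.sample_sheet, pairs=pairs,
                      annotation=cohort.annotation)
print(results.head(3)[["probe_id", "cotwin_mean", "asthma_mean",
                       "mean_delta_beta", "p", "rank"]])

delta = delta_beta(beta, cohort.sample_sheet, pairs=pairs)
print(empirical_p_batch(results, delta, threshold=1e-4, cap=10_000, seed=1)
      .head(3)[["probe_id", "empirical_p", "reported"]])
```

prints (37 discordant pairs, 5000 probes, a handful of planted effects):

```
  probe_id  cotwin_mean  asthma_mean  mean_delta_beta         p  rank
cg00004475       0.6243       0.7727           0.1484 4.192e-16     1
cg00002200       0.7111       0.5884          -0.1227 5.359e-12     2
cg00000914       0.0901       0.0296          -0.0604 1.049e-09     3

  probe_id  empirical_p reported
cg00004475          0.0  <0.0001
cg00002200          0.0  <0.0001
cg00000914          0.0  <0.0001
```

The three top-ranked probes are exactly the three largest planted
effects in the cohort's truth table: the affected twins run 0.15 higher
(respectively 0.12 and 0.06 lower) in methylation fraction than their
co-twins, none of the 10,000 random label assignments is as extreme, so
the empirical *p* is reported as the resolution bound "<0.0001". On the
same cohort the mean within-pair correlation across probes is 0.9704
and the global mean-methylation paired test is null (Δ = 0.0001,
*p* = 0.48), as expected when signal is probe-specific.

The same workflow runs from the shell:

```sh
twinmeth simulate --out cohort/ --seed 7
twinmeth run --config run.yaml        # QC → DMP → permutation → strata →
                                      # specificity → longitudinal → enrichment
```

Every stage writes a TSV with header comments carrying the package
version, config hash and derived seeds; `run_manifest.json` records
parameters and input checksums, enough to reproduce a run byte for byte.

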