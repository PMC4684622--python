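"""Stratification, concordant permutation baseline and specificity ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinmeth import (TwinCohortConfig, generate_cohort, stratify_pairs,
                      concordant_baseline, specificity_anova)
from twinmeth.specificity import holm_adjust, oriented_concordant_delta
from conftest import make_paired_cohort


def _sheet_row(pair, role, s10, s18, age=10):
    return {"sample_id": f"{pair}.{role}.age{age}", "pair_id": pair,
            "role": role, "age": age, "status_age5": s10,
            "status_age10": s10, "status_age18": s18, "batch_id": "a"}


def test_stratify_study_design(design_sheet):
    strata, excluded = stratify_pairs(design_sheet)
    assert (strata == "persistent").sum() == 13
    assert (strata == "remission").sum() == 20
    assert (strata == "concordant-unaffected").sum() == 19
    assert len(excluded) == 4  # 3 concordant affected + 1 unknown at 18


def test_stratify_discordant_to_concordant_affected_excluded():
    rows = [
        _sheet_row("p1", "twin1", "affected", "affected"),
        _sheet_row("p1", "twin2", "unaffected", "affected"),
    ]
    strata, excluded = stratify_pairs(pd.DataFrame(rows))
    assert len(strata) == 0
    assert excluded == {"p1": "concordant affected at 18"}


def test_stratify_unknown_age10_rejected():
    rows = [
        _sheet_row("p1", "twin1", "unknown", "unaffected"),
        _sheet_row("p1", "twin2", "unaffected", "unaffected"),
    ]
    with pytest.raises(ValueError, match="p1"):
        stratify_pairs(pd.DataFrame(rows))


def test_all_concordant_cohort_refuses_anova():
    rows = []
    for i in range(4):
        rows += [_sheet_row(f"p{i}", "twin1", "unaffected", "unaffected"),
                 _sheet_row(f"p{i}", "twin2", "unaffected", "unaffected")]
    strata, _ = stratify_pairs(pd.DataFrame(rows))
    assert (strata == "concordant-unaffected").sum() == 4
    groups = {"persistent": pd.DataFrame(index=["cg1"]),
              "remission": pd.DataFrame(index=["cg1"]),
              "concordant": pd.DataFrame(np.zeros((1, 4)), index=["cg1"])}
    with pytest.raises(ValueError, match="two non-empty groups"):
        specificity_anova(groups)


def test_baseline_zero_expectation_and_enumeration():
    """Two pairs with fixed differences d1, d2: the per-rep cohort average
    lives on {±d1/2 ± d2/2} and the mean over reps approaches zero."""
    d1, d2 = 0.08, -0.02
    beta, sheet = make_paired_cohort([[0.5 + d1, 0.5 + d2]], [[0.5, 0.5]])
    # relabel as concordant so orientation is genuinely arbitrary
    sheet["status_age10"] = "unaffected"
    sheet["status_age18"] = "unaffected"
    baseline, reps = concordant_baseline(beta, sheet,
                                         ["pair001", "pair002"],
                                         n_reps=1000, seed=0)
    support = {round(v, 10) for v in reps[0]}
    expected = {round(s1 * d1 / 2 + s2 * d2 / 2, 10)
                for s1 in (-1, 1) for s2 in (-1, 1)}
    assert support <= expected
    se = reps[0].std(ddof=1) / np.sqrt(reps.shape[1])
    assert abs(baseline.iloc[0]) < 4 * se


def test_baseline_seeded_determinism_and_se_scaling():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.3, 0.7, (5, 6))
    beta, sheet = make_paired_cohort(vals, vals + rng.normal(0, 0.05, vals.shape))
    sheet["status_age10"] = "unaffected"
    pairs = sorted(sheet.pair_id.unique())
    b1, r1 = concordant_baseline(beta, sheet, pairs, n_reps=400, seed=3)
    b2, r2 = concordant_baseline(beta, sheet, pairs, n_reps=400, seed=3)
    assert np.array_equal(r1, r2)
    # Monte-Carlo SE of the baseline halves when reps quadruple
    ses_small, ses_big = [], []
    for seed in range(40):
        s, _ = concordant_baseline(beta, sheet, pairs, n_reps=50, seed=seed)
        b, _ = concordant_baseline(beta, sheet, pairs, n_reps=200, seed=seed)
        ses_small.append(s.iloc[0])
        ses_big.append(b.iloc[0])
    ratio = np.std(ses_small) / np.std(ses_big)
    assert 1.4 < ratio < 2.9  # sqrt(4) = 2 within sampling noise


def test_baseline_input_validation():
    beta, sheet = make_paired_cohort([[0.5, 0.5]], [[0.4, 0.4]])
    with pytest.raises(ValueError, match="n_reps"):
        concordant_baseline(beta, sheet, ["pair001", "pair002"], n_reps=0)
    with pytest.raises(ValueError, match="two concordant pairs"):
        concordant_baseline(beta, sheet, ["pair001"])


def test_anova_identical_groups_f_zero():
    g = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["cg1"])
    res = specificity_anova({"a": g, "b": g.copy(), "c": g.copy()})
    assert res.F.iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert res.p_anova.iloc[0] == pytest.approx(1.0)


def test_anova_matches_closed_form_on_jittered_groups():
    rng = np.random.default_rng(1)
    a = np.zeros(4) + rng.normal(0, 1e-3, 4)
    b = np.zeros(4) + rng.normal(0, 1e-3, 4)
    c = np.ones(4) + rng.normal(0, 1e-3, 4)
    groups = {"a": pd.DataFrame([a], index=["cg1"]),
              "b": pd.DataFrame([b], index=["cg1"]),
              "c": pd.DataFrame([c], index=["cg1"])}
    res = specificity_anova(groups)
    f_ref, p_ref = stats.f_oneway(a, b, c)
    assert res.F.iloc[0] == pytest.approx(f_ref)
    assert res.p_anova.iloc[0] == pytest.approx(p_ref)
    assert res.F.iloc[0] > 1e4
    # only contrasts involving group c are significant
    assert res.p_adj_a_vs_c.iloc[0] < 1e-6
    assert res.p_adj_b_vs_c.iloc[0] < 1e-6
    assert res.p_adj_a_vs_b.iloc[0] > 0.05


def test_two_group_f_equals_squared_pooled_t():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 7)
    b = rng.normal(0.5, 1, 9)
    res = specificity_anova({"a": pd.DataFrame([a], index=["cg1"]),
                             "b": pd.DataFrame([b], index=["cg1"])})
    t, _ = stats.ttest_ind(a, b)
    assert res.F.iloc[0] == pytest.approx(t ** 2, rel=1e-10)


def test_random_group_labels_give_uniform_anova_p():
    rng = np.random.default_rng(3)
    values = rng.normal(0, 0.05, (2000, 18))
    idx = [f"cg{i:05d}" for i in range(2000)]
    groups = {"a": pd.DataFrame(values[:, :6], index=idx),
              "b": pd.DataFrame(values[:, 6:12], index=idx),
              "c": pd.DataFrame(values[:, 12:], index=idx)}
    res = specificity_anova(groups)
    ks = stats.kstest(res.p_anova.to_numpy(), "uniform")
    assert ks.pvalue > 0.01


def test_holm_adjustment_reference():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(4)
    for _ in range(20):
        p = rng.uniform(0, 1, 3)
        ours = holm_adjust(p)
        theirs = multipletests(p, method="holm")[1]
        assert np.allclose(ours, theirs)


def test_oriented_delta_is_signed_pair_difference():
    beta, sheet = make_paired_cohort([[0.6, 0.7]], [[0.5, 0.5]])
    sheet["status_age10"] = "unaffected"
    d = oriented_concordant_delta(beta, sheet, ["pair001", "pair002"], seed=1)
    assert set(np.round(np.abs(d.to_numpy()[0]), 10)) == {0.1, 0.2}


def test_persistent_only_effect_flagged_specifically():
    """A persistent-only planted effect separates that stratum from both
    comparison groups while remission vs concordant stays null."""
    cfg = TwinCohortConfig(n_probes=40, n_snp_probes=0,
                           frac_planted_dmp=1 / 40,
                           effect_size_range=(0.1, 0.1),
                           dmp_scope="persistent",
                           frac_planted_longitudinal=0.0, seed=12)
    cohort = generate_cohort(cfg)
    from twinmeth.ewas import delta_beta
    strata, _ = stratify_pairs(cohort.sample_sheet)
    probe = cohort.truth.probe_id.iloc[0]
    groups = {
        "persistent": delta_beta(cohort.beta_age10, cohort.sample_sheet,
                                 pairs=sorted(strata.index[strata == "persistent"])),
        "remission": delta_beta(cohort.beta_age10, cohort.sample_sheet,
                                pairs=sorted(strata.index[strata == "remission"])),
        "concordant": oriented_concordant_delta(
            cohort.beta_age10, cohort.sample_sheet,
            sorted(strata.index[strata == "concordant-unaffected"]), seed=1),
    }
    res = specificity_anova(groups).set_index("probe_id").loc[probe]
    assert res.p_anova < 0.001
    assert res.p_adj_persistent_vs_remission < 0.05
    assert res.p_adj_persistent_vs_concordant < 0.05
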