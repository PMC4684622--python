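"""Sample/probe QC, quantile normalisation and the zygosity check."""

import numpy as np
import pandas as pd
import pytest

from twinmeth.preprocess import (IntensityBundle, filter_samples,
                                 filter_probes, quantile_normalize,
                                 normalize_and_beta, verify_monozygosity)
from conftest import make_paired_cohort


def _bundle(n_probes=10, n_samples=4, seed=0, **kwargs):
    rng = np.random.default_rng(seed)
    probes = [f"cg{i:05d}" for i in range(n_probes)]
    samples = [f"s{j}" for j in range(n_samples)]
    shape = (n_probes, n_samples)
    mk = lambda arr: pd.DataFrame(arr, index=probes, columns=samples)
    return IntensityBundle(
        meth=mk(kwargs.get("meth", rng.uniform(100, 1000, shape))),
        unmeth=mk(kwargs.get("unmeth", rng.uniform(100, 1000, shape))),
        detection_p=mk(kwargs.get("detection_p", np.zeros(shape))),
        beadcount=mk(kwargs.get("beadcount", np.full(shape, 10))),
        design_type=pd.Series("II", index=probes),
    )


def _annotation(bundle, **overrides):
    probes = bundle.meth.index
    ann = pd.DataFrame({
        "probe_id": probes,
        "chrom": "chr1",
        "position": np.arange(len(probes)) + 1,
        "gene": "",
        "design_type": "II",
        "island_relation": "Intergenic",
        "is_snp_control": False,
        "is_blacklisted": False,
    })
    for col, values in overrides.items():
        ann[col] = values
    return ann


def test_sample_filter_threshold_arithmetic():
    detp = np.zeros((10, 4))
    detp[0, 1] = 0.5  # sample s1 fails 1/10 probes = 10% >= 5%
    bundle = _bundle(detection_p=detp)
    kept, report = filter_samples(bundle)
    assert "s1" in report.samples_removed
    assert list(kept.meth.columns) == ["s0", "s2", "s3"]


def test_sample_filter_all_pass_when_detection_perfect():
    bundle = _bundle()
    kept, report = filter_samples(bundle)
    assert report.samples_removed == {}
    assert kept.meth.shape == bundle.meth.shape


def test_sample_filter_boundary_is_inclusive():
    """Failure fractions {0.04, 0.05, 0.06}: exactly the >= 5% ones go."""
    detp = np.zeros((100, 3))
    detp[:4, 0] = 0.9
    detp[:5, 1] = 0.9
    detp[:6, 2] = 0.9
    bundle = _bundle(n_probes=100, n_samples=3, detection_p=detp)
    kept, report = filter_samples(bundle)
    assert set(report.samples_removed) == {"s1", "s2"}
    assert list(kept.meth.columns) == ["s0"]


def test_sample_filter_drops_cotwin():
    detp = np.zeros((10, 4))
    detp[:, 0] = 0.9
    bundle = _bundle(detection_p=detp)
    sheet = pd.DataFrame({
        "sample_id": ["s0", "s1", "s2", "s3"],
        "pair_id": ["p1", "p1", "p2", "p2"],
        "role": ["twin1", "twin2"] * 2,
        "age": 10,
        "status_age5": "unaffected", "status_age10": "unaffected",
        "status_age18": "unaffected", "batch_id": "a",
    })
    kept, report = filter_samples(bundle, sheet=sheet)
    assert report.cotwins_removed == ["s1"]
    assert list(kept.meth.columns) == ["s2", "s3"]


def test_all_samples_removed_is_an_error():
    detp = np.full((10, 4), 0.9)
    with pytest.raises(ValueError, match="no samples survive"):
        filter_samples(_bundle(detection_p=detp))


def test_probe_filter_rules_and_union():
    """5 low-bead, 3 blacklisted, 2 chrY probes, one overlap -> 91 retained."""
    n = 100
    bead = np.full((n, 10), 10)
    bead[:5, 0] = 2  # probes 0-4 low bead in 1/10 samples = 10% >= 5%
    bundle = _bundle(n_probes=n, n_samples=10, beadcount=bead)
    blacklisted = np.zeros(n, dtype=bool)
    blacklisted[4:7] = True  # probe 4 overlaps the low-bead set
    chrom = np.array(["chr1"] * n, dtype=object)
    chrom[[90, 91]] = "chrY"
    ann = _annotation(bundle, is_blacklisted=blacklisted, chrom=chrom)
    kept, report = filter_probes(bundle, ann)
    assert len(report.probes_removed["lowbead"]) == 5
    assert len(report.probes_removed["blacklist"]) == 3
    assert len(report.probes_removed["sex_chromosome"]) == 2
    assert report.n_probes_retained == 91
    assert report.n_probes_removed + report.n_probes_retained == n


def test_probe_filter_removes_chrx_regardless_of_quality():
    bundle = _bundle(n_probes=5, n_samples=4)
    chrom = ["chrX", "chr2", "chr3", "chr4", "chr5"]
    ann = _annotation(bundle, chrom=chrom)
    kept, report = filter_probes(bundle, ann)
    assert report.probes_removed["sex_chromosome"] == ["cg00000"]
    assert "cg00000" not in kept.meth.index


def test_probe_filter_snp_controls_removed_from_analysis_set():
    bundle = _bundle(n_probes=6, n_samples=4)
    snp = [False, False, False, False, True, True]
    ann = _annotation(bundle, is_snp_control=snp)
    kept, report = filter_probes(bundle, ann)
    assert set(report.probes_removed["snp_control"]) == {"cg00004", "cg00005"}
    assert len(kept.meth) == 4


def test_probe_filter_orphan_probes_rejected():
    bundle = _bundle(n_probes=4, n_samples=3)
    ann = _annotation(bundle).iloc[:2]
    with pytest.raises(ValueError, match="annotation missing probes"):
        filter_probes(bundle, ann)


def test_quantile_normalization_hand_computed_toy():
    """2 samples x 4 probes: each column maps onto the mean sorted column."""
    M = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0], [4.0, 8.0]])
    U = np.array([[4.0, 8.0], [3.0, 7.0], [2.0, 6.0], [1.0, 5.0]])
    bundle = _bundle(n_probes=4, n_samples=2, meth=M, unmeth=U)
    beta = normalize_and_beta(bundle, offset=0.0)
    # reference = (3,4,5,6) for both channels; hand-computed betas:
    expected = np.array([[3 / 9, 3 / 9], [4 / 9, 4 / 9],
                         [5 / 9, 5 / 9], [6 / 9, 6 / 9]])
    assert np.allclose(beta.to_numpy(), expected)


def test_beta_symmetry_and_extremes():
    M = np.full((3, 2), 500.0)
    bundle = _bundle(n_probes=3, n_samples=2, meth=M, unmeth=M.copy())
    beta = normalize_and_beta(bundle, offset=0.0)
    assert np.allclose(beta.to_numpy(), 0.5)
    bundle2 = _bundle(n_probes=3, n_samples=2, meth=M,
                      unmeth=np.zeros((3, 2)))
    beta2 = normalize_and_beta(bundle2, offset=0.0, skip_normalization=True)
    assert np.allclose(beta2.to_numpy(), 1.0)


def test_quantile_normalization_idempotent_and_bounded():
    rng = np.random.default_rng(6)
    x = pd.DataFrame(rng.lognormal(6, 1, (50, 5)))
    once = quantile_normalize(x)
    twice = quantile_normalize(once)
    assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-9)
    bundle = _bundle(n_probes=50, n_samples=5,
                     meth=rng.lognormal(6, 1, (50, 5)),
                     unmeth=rng.lognormal(6, 1, (50, 5)))
    beta = normalize_and_beta(bundle, offset=100.0)
    v = beta.to_numpy()
    assert (v >= 0).all() and (v <= 1).all()


def test_negative_intensities_rejected():
    M = np.full((3, 2), -1.0)
    with pytest.raises(ValueError, match="negative"):
        normalize_and_beta(_bundle(n_probes=3, n_samples=2, meth=M))


def test_zygosity_identical_twins_pass():
    rng = np.random.default_rng(7)
    geno = rng.choice([0.0, 0.5, 1.0], (20, 3))
    beta, sheet = make_paired_cohort(geno, geno)
    ann = pd.DataFrame({
        "probe_id": beta.index, "chrom": "chr1",
        "position": np.arange(len(beta)) + 1, "gene": "",
        "design_type": "II", "island_relation": "Intergenic",
        "is_snp_control": True, "is_blacklisted": False,
    })
    res = verify_monozygosity(beta, ann, sheet)
    assert res.monozygotic.all()
    assert np.allclose(res.snp_r, 1.0)


def test_zygosity_unrelated_individual_flagged():
    """Independently re-drawn genotypes give r near zero -> flagged."""
    rng = np.random.default_rng(8)
    a = rng.choice([0.0, 0.5, 1.0], (65, 2))
    b = a.copy()
    b[:, 1] = rng.choice([0.0, 0.5, 1.0], 65)  # pair002 twin2 re-drawn
    beta, sheet = make_paired_cohort(a, b)
    ann = pd.DataFrame({
        "probe_id": beta.index, "chrom": "chr1",
        "position": np.arange(len(beta)) + 1, "gene": "",
        "design_type": "II", "island_relation": "Intergenic",
        "is_snp_control": True, "is_blacklisted": False,
    })
    res = verify_monozygosity(beta, ann, sheet).set_index("pair_id")
    assert bool(res.loc["pair001", "monozygotic"])
    assert not bool(res.loc["pair002", "monozygotic"])
    assert abs(res.loc["pair002", "snp_r"]) < 0.5


def test_zygosity_single_snp_probe_is_an_error():
    beta, sheet = make_paired_cohort([[0.5, 0.5]], [[0.5, 0.5]])
    ann = pd.DataFrame({
        "probe_id": beta.index, "chrom": "chr1", "position": [1],
        "gene": "", "design_type": "II", "island_relation": "Intergenic",
        "is_snp_control": True, "is_blacklisted": False,
    })
    with pytest.raises(ValueError, match="zygosity"):
        verify_monozygosity(beta, ann, sheet)


def test_filter_report_counts_conserved_on_random_runs():
    rng = np.random.default_rng(9)
    for seed in range(5):
        n = 40
        bead = np.where(rng.random((n, 8)) < 0.05, 2, 10)
        bundle = _bundle(n_probes=n, n_samples=8, seed=seed, beadcount=bead)
        black = rng.random(n) < 0.1
        chrom = np.where(rng.random(n) < 0.1, "chrX", "chr1")
        ann = _annotation(bundle, is_blacklisted=black, chrom=chrom)
        _, report = filter_probes(bundle, ann)
        assert report.n_probes_removed + report.n_probes_retained == n
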