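"""Quality control and normalisation for methylation-array intensities.

Sample filter: a sample is removed when the fraction of its probes with
detection p > 0.05 reaches the threshold (default 5%, inclusive); the
co-twin of a removed sample is also dropped from paired analyses.
Probe filters: bead count below 3 in at least 5% of retained samples,
blacklisted (non-specific) probes, sex-chromosome probes, and SNP
control probes (the latter are excluded from the analysis set but kept
for the zygosity check).  Normalisation quantile-normalises methylated
and unmethylated intensities separately within each probe design type
before forming beta = M / (M + U + offset); exact parity with any
published normalisation package is out of scope, and pre-normalised
beta input bypasses this step entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntensityBundle", "FilterReport",
    "filter_samples", "filter_probes",
    "quantile_normalize", "normalize_and_beta",
    "verify_monozygosity",
]


@dataclass
class IntensityBundle:
    """Methylated/unmethylated intensities with QC matrices.

    All matrices are probes x samples with identical indexing; the
    design type Series (values "I"/"II") is indexed by probe.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    beadcount: pd.DataFrame | None = None
    design_type: pd.Series | None = None

    def __post_init__(self) -> None:
        ref = self.meth
        for name in ("unmeth", "detection_p", "beadcount"):
            other = getattr(self, name)
            if other is None:
                continue
            if not (other.index.equals(ref.index)
                    and other.columns.equals(ref.columns)):
                raise ValueError(f"{name} matrix indexing differs from meth")
        if self.detection_p is not None:
            v = self.detection_p.to_numpy(dtype=float)
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError("detection p values must lie in [0, 1]")
        if self.beadcount is not None:
            v = self.beadcount.to_numpy(dtype=float)
            if np.nanmin(v) < 0:
                raise ValueError("bead counts must be non-negative")

    def subset(self, probes=None, samples=None) -> "IntensityBundle":
        def cut(df):
            if df is None:
                return None
            out = df
            if probes is not None:
                out = out.loc[probes]
            if samples is not None:
                out = out[samples]
            return out
        design = self.design_type
        if design is not None and probes is not None:
            design = design.loc[probes]
        return IntensityBundle(cut(self.meth), cut(self.unmeth),
                               cut(self.detection_p), cut(self.beadcount),
                               design)


@dataclass
class FilterReport:
    """Per-rule record of removed samples/probes; counts are conserved."""

    n_input_samples: int = 0
    n_input_probes: int = 0
    samples_removed: dict[str, float] = field(default_factory=dict)
    cotwins_removed: list[str] = field(default_factory=list)
    probes_removed: dict[str, list[str]] = field(default_factory=dict)
    n_probes_retained: int = 0
    n_samples_retained: int = 0

    @property
    def n_probes_removed(self) -> int:
        removed: set[str] = set()
        for probes in self.probes_removed.values():
            removed.update(probes)
        return len(removed)

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples_detection_p", len(self.samples_removed)),
                ("samples_cotwin", len(self.cotwins_removed))]
        rows += [(f"probes_{rule}", len(ids))
                 for rule, ids in self.probes_removed.items()]
        rows += [("probes_retained", self.n_probes_retained),
                 ("samples_retained", self.n_samples_retained)]
        return pd.DataFrame(rows, columns=["rule", "count"])


def filter_samples(bundle: IntensityBundle, max_fail_fraction: float = 0.05,
                   detection_threshold: float = 0.05,
                   sheet: pd.DataFrame | None = None,
                   ) -> tuple[IntensityBundle, FilterReport]:
    """Remove samples failing detection across too many probes.

    A sample fails when its fraction of probes with detection
    p > ``detection_threshold`` is >= ``max_fail_fraction`` (boundary
    inclusive).  With a sample sheet, co-twins of removed samples are
    dropped too (recorded separately in the report).
    """
    if bundle.detection_p is None:
        raise ValueError("detection-p matrix required for sample filtering")
    report = FilterReport(n_input_samples=bundle.meth.shape[1],
                          n_input_probes=bundle.meth.shape[0])
    fail_frac = (bundle.detection_p > detection_threshold).mean(axis=0)
    bad = fail_frac[fail_frac >= max_fail_fraction]
    report.samples_removed = {s: float(f) for s, f in bad.items()}
    removed = set(bad.index)
    if sheet is not None and removed:
        lut = sheet.set_index("sample_id")
        for s in list(removed):
            if s not in lut.index:
                continue
            rec = lut.loc[s]
            mate = sheet[(sheet.pair_id == rec.pair_id)
                         & (sheet.age == rec.age)
                         & (sheet.sample_id != s)]
            for m in mate.sample_id:
                if m in bundle.meth.columns and m not in removed:
                    report.cotwins_removed.append(m)
        removed.update(report.cotwins_removed)
    keep = [s for s in bundle.meth.columns if s not in removed]
    if not keep:
        raise ValueError("no samples survive QC")
    report.n_samples_retained = len(keep)
    report.n_probes_retained = bundle.meth.shape[0]
    return bundle.subset(samples=keep), report


def filter_probes(bundle: IntensityBundle, annotation: pd.DataFrame,
                  max_lowbead_fraction: float = 0.05,
                  detection_fail_fraction: float | None = None,
                  detection_threshold: float = 0.05,
                  ) -> tuple[IntensityBundle, FilterReport]:
    """Remove unreliable, blacklisted, sex-chromosome and SNP-control probes.

    * bead count < 3 in >= ``max_lowbead_fraction`` of retained samples;
    * blacklisted (non-specific) probes;
    * chrX / chrY probes;
    * SNP control probes (removed from the analysis set; the zygosity
      check reads them from the unfiltered beta matrix);
    * optionally, probes failing detection in >= ``detection_fail_fraction``
      of samples (off by default).
    """
    probes = bundle.meth.index
    ann = annotation.set_index("probe_id")
    orphans = probes.difference(ann.index)
    if len(orphans):
        raise ValueError(f"annotation missing probes: {sorted(orphans)[:10]}")
    ann = ann.loc[probes]
    report = FilterReport(n_input_samples=bundle.meth.shape[1],
                          n_input_probes=len(probes))

    removed: dict[str, list[str]] = {}
    if bundle.beadcount is not None:
        lowbead = (bundle.beadcount < 3).mean(axis=1) >= max_lowbead_fraction
        removed["lowbead"] = list(probes[lowbead])
    else:
        removed["lowbead"] = []
    removed["blacklist"] = list(probes[ann.is_blacklisted.to_numpy(dtype=bool)])
    removed["sex_chromosome"] = list(probes[ann.chrom.isin(["chrX", "chrY"])])
    removed["snp_control"] = list(probes[ann.is_snp_control.to_numpy(dtype=bool)])
    if detection_fail_fraction is not None and bundle.detection_p is not None:
        fail = ((bundle.detection_p > detection_threshold).mean(axis=1)
                >= detection_fail_fraction)
        removed["detection_p"] = list(probes[fail])
    report.probes_removed = removed

    drop: set[str] = set()
    for ids in removed.values():
        drop.update(ids)
    keep = [p for p in probes if p not in drop]
    report.n_probes_retained = len(keep)
    report.n_samples_retained = bundle.meth.shape[1]
    return bundle.subset(probes=keep), report


def quantile_normalize(x: pd.DataFrame) -> pd.DataFrame:
    """Map each sample's values onto the mean of the sorted columns.

    Ties receive the mean of the reference values they span (average
    ranks with interpolation); applying the transform twice changes
    nothing beyond numerical tolerance.
    """
    values = x.to_numpy(dtype=float)
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def normalize_and_beta(bundle: IntensityBundle, offset: float = 100.0,
                       skip_normalization: bool = False) -> pd.DataFrame:
    """Quantile-normalise intensities per design type and compute betas.

    beta = M / (M + U + offset); with offset >= 0 every output lies in
    [0, 1].  Methylated and unmethylated channels are normalised
    separately within each design type stratum; a stratum with zero
    probes is skipped with a warning.
    """
    M, U = bundle.meth, bundle.unmeth
    if (M.to_numpy() < 0).any() or (U.to_numpy() < 0).any():
        raise ValueError("negative intensities")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if not skip_normalization:
        if bundle.design_type is None:
            raise ValueError("design types required for stratified normalization")
        M = M.copy()
        U = U.copy()
        for dt in ("I", "II"):
            idx = bundle.design_type.index[bundle.design_type == dt]
            idx = M.index.intersection(idx)
            if len(idx) == 0:
                import warnings
                warnings.warn(f"no probes of design type {dt}; stratum skipped")
                continue
            M.loc[idx] = quantile_normalize(M.loc[idx])
            U.loc[idx] = quantile_normalize(U.loc[idx])
    denom = M.to_numpy() + U.to_numpy() + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, M.to_numpy() / denom, np.nan)
    out = pd.DataFrame(beta, index=M.index, columns=M.columns)
    out.index.name = "probe_id"
    return out


def verify_monozygosity(beta: pd.DataFrame, annotation: pd.DataFrame,
                        sheet: pd.DataFrame, min_r: float = 0.9,
                        age: int = 10) -> pd.DataFrame:
    """Within-pair correlation over SNP control probes flags non-identical pairs.

    Genotype-driven probes have near-identical betas in monozygotic
    twins; a pair whose correlation falls below ``min_r`` is flagged.
    Requires at least two SNP control probes (correlation is undefined
    on one point).
    """
    snp_ids = annotation.loc[annotation.is_snp_control.astype(bool), "probe_id"]
    snp_ids = beta.index.intersection(snp_ids)
    if len(snp_ids) == 0:
        raise ValueError("zygosity check impossible: no SNP control probes")
    if len(snp_ids) < 2:
        raise ValueError("zygosity check impossible: need >= 2 SNP control probes")
    sub = sheet[sheet.age == age]
    rows = []
    for pair, grp in sub.groupby("pair_id"):
        cols = grp.sort_values("role").sample_id.tolist()
        x = beta.loc[snp_ids, cols[0]].to_numpy(dtype=float)
        y = beta.loc[snp_ids, cols[1]].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r = 1.0 if np.allclose(x, y) else 0.0
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows.append({"pair_id": pair, "snp_r": r, "monozygotic": r >= min_r})
    return pd.DataFrame(rows).sort_values("pair_id").reset_index(drop=True)
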