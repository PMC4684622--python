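"""Synthetic twin-cohort methylome generator.

Generates beta-value matrices for monozygotic twin pairs at two sampling
ages, together with a sample sheet, a probe annotation table and a truth
table of planted effects.  The generator emulates the statistical
structure a discordant-twin methylation analysis assumes:

* a bimodal array-like landscape of per-probe baseline methylation
  (most CpGs are either lowly or highly methylated, with a smaller
  intermediate fraction);
* a strong shared component within a twin pair (genetic background plus
  the shared array the pair is hybridised on), so that within-pair
  correlation of beta values across probes is very high (~0.97 with the
  shipped defaults);
* individual-level deviations that persist across ages, plus independent
  per-measurement noise;
* optional planted effects: cross-sectional within-pair differences at
  age 10 and/or age 5 (added to the affected twin) and differential
  longitudinal drift between ages 5 and 10.

All effects are added on the beta scale and the result is clamped to
[0, 1]; with the default variance components clamping is rare (<1% of
values).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["TwinCohortConfig", "TwinCohort", "generate_cohort", "write_cohort"]

STRATA = ("persistent", "remission", "concordant-unaffected", "concordant-affected")

#: closed vocabulary for the CpG-island relation column
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "Intergenic")


@dataclass
class TwinCohortConfig:
    """Configuration of a synthetic twin cohort.

    Default pair counts reproduce the study design this package targets:
    13 pairs persistently discordant for the phenotype at ages 10 and 18,
    20 discordant pairs whose affected twin remits by 18, 19 concordant
    unaffected pairs, 3 discordant pairs that become concordant affected
    at 18 and 1 discordant pair lost to age-18 follow-up (37 discordant
    pairs in total at age 10).

    The variance components (``pair_sd``, ``batch_sd``, ``individual_sd``,
    ``noise_sd``) were fixed by a one-time calibration run so that the
    mean within-pair Pearson correlation of beta values across 20,000
    probes is 0.97; see docs/methods.md.
    """

    n_pairs_persistent: int = 13
    n_pairs_remission: int = 20
    n_pairs_concordant_unaffected: int = 19
    n_pairs_concordant_affected: int = 3
    #: discordant pairs lost to age-18 follow-up (37 discordant at age 10)
    n_pairs_unknown18: int = 1
    n_probes: int = 20_000
    n_snp_probes: int = 65

    # planted cross-sectional effects (age 10), |delta beta| drawn from range
    frac_planted_dmp: float = 0.001
    effect_size_range: tuple[float, float] = (0.003, 0.14)
    #: which pairs receive the cross-sectional effect
    dmp_scope: str = "all-discordant"  # or "persistent" / "remission"

    # planted differential longitudinal drift (age 5 -> 10, affected twin)
    frac_planted_longitudinal: float = 0.001
    longitudinal_effect_range: tuple[float, float] = (0.02, 0.14)

    # planted cross-sectional effects at age 5 (off by default)
    frac_planted_age5: float = 0.0
    age5_effect_range: tuple[float, float] = (0.003, 0.14)

    # variance components, beta scale (calibrated; see class docstring)
    pair_sd: float = 0.015
    batch_sd: float = 0.010
    individual_sd: float = 0.035
    noise_sd: float = 0.0335
    #: common (non-differential) per-probe drift between ages
    age_drift_sd: float = 0.01

    # bimodal baseline mixture: (low, high, intermediate)
    mixture_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)
    mixture_shapes: tuple[tuple[float, float], ...] = (
        (14.0, 56.0),   # low-methylated mode, mean 0.2
        (56.0, 14.0),   # high-methylated mode, mean 0.8
        (8.0, 8.0),     # intermediate component
    )

    #: discordant pairs without age-5 material, per stratum
    missing_age5: Mapping[str, int] = field(
        default_factory=lambda: {"persistent": 2, "remission": 4}
    )

    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_pairs_persistent,
            self.n_pairs_remission,
            self.n_pairs_concordant_unaffected,
            self.n_pairs_concordant_affected,
            self.n_pairs_unknown18,
        )
        if any(c < 0 for c in counts) or self.n_probes < 0 or self.n_snp_probes < 0:
            raise ValueError("counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("empty cohort")
        for frac in (self.frac_planted_dmp, self.frac_planted_longitudinal,
                     self.frac_planted_age5):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("planted fractions must lie in [0, 1]")
        for lo, hi in (self.effect_size_range, self.longitudinal_effect_range,
                       self.age5_effect_range):
            if not (-1.0 <= lo <= hi <= 1.0):
                raise ValueError("effect bounds must be ordered and within [-1, 1]")
        for sd in (self.pair_sd, self.batch_sd, self.individual_sd,
                   self.noise_sd, self.age_drift_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if self.dmp_scope not in ("all-discordant", "persistent", "remission"):
            raise ValueError(f"unknown dmp_scope {self.dmp_scope!r}")


@dataclass
class TwinCohort:
    """In-memory bundle produced by :func:`generate_cohort`."""

    beta_age5: pd.DataFrame
    beta_age10: pd.DataFrame
    sample_sheet: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame
    config: TwinCohortConfig


def _pair_table(cfg: TwinCohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per pair: id, stratum, which twin is affected, age-5 availability."""
    strata = (
        ["persistent"] * cfg.n_pairs_persistent
        + ["remission"] * cfg.n_pairs_remission
        + ["concordant-unaffected"] * cfg.n_pairs_concordant_unaffected
        + ["concordant-affected"] * cfg.n_pairs_concordant_affected
        + ["discordant-unknown18"] * cfg.n_pairs_unknown18
    )
    n = len(strata)
    width = max(3, len(str(n)))
    pairs = pd.DataFrame({
        "pair_id": [f"pair{i + 1:0{width}d}" for i in range(n)],
        "stratum": strata,
    })
    # which twin carries the phenotype in discordant pairs (irrelevant for
    # concordant-unaffected, where nobody is affected)
    pairs["affected_role"] = np.where(
        rng.random(n) < 0.5, "twin1", "twin2"
    )
    pairs.loc[pairs.stratum == "concordant-unaffected", "affected_role"] = ""
    # drop age-5 material for a deterministic subset of discordant pairs
    pairs["has_age5"] = True
    for stratum, k in dict(cfg.missing_age5).items():
        idx = pairs.index[pairs.stratum == stratum][:k]
        pairs.loc[idx, "has_age5"] = False
    return pairs


def _sample_sheet(pairs: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for rec in pairs.itertuples(index=False):
        for role in ("twin1", "twin2"):
            affected = role == rec.affected_role
            s18_token = None
            if rec.stratum == "persistent":
                s10, s18 = affected, affected
            elif rec.stratum == "remission":
                s10, s18 = affected, False
            elif rec.stratum == "concordant-affected":
                s10, s18 = affected, True
            elif rec.stratum == "discordant-unknown18":
                s10, s18 = affected, False
                s18_token = "unknown"
            else:  # concordant-unaffected
                s10, s18 = False, False
            tok = {True: "affected", False: "unaffected"}
            for age in (5, 10):
                if age == 5 and not rec.has_age5:
                    continue
                rows.append({
                    "sample_id": f"{rec.pair_id}.{role}.age{age}",
                    "pair_id": rec.pair_id,
                    "role": role,
                    "age": age,
                    # phenotype history: the age-5 record mirrors age 10
                    "status_age5": tok[s10],
                    "status_age10": tok[s10],
                    "status_age18": s18_token or tok[s18],
                    "batch_id": f"array_{rec.pair_id}_age{age}",
                })
    return pd.DataFrame(rows)


def _annotation(cfg: TwinCohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Probe manifest: autosomal CpG probes plus SNP control probes.

    Gene sizes (probes per gene) are drawn from a skewed distribution so
    that the probes-per-gene bias the enrichment module corrects for is
    actually present in synthetic cohorts.
    """
    n = cfg.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n)]
    gene_of_probe = np.full(n, "", dtype=object)
    pos = 0
    g = 0
    while pos < n:
        size = 1 + rng.geometric(0.25)  # mean 5 probes per gene, long tail
        gene = f"G{g + 1:05d}"
        # ~15% of probes stay intergenic (no gene annotation)
        if rng.random() < 0.15:
            pos += max(1, size // 3)
        else:
            gene_of_probe[pos:pos + size] = gene
            g += 1
            pos += size
    ann = pd.DataFrame({
        "probe_id": probe_ids,
        "chrom": [f"chr{c}" for c in rng.integers(1, 23, n)],
        "position": rng.integers(10_000, 2.4e8, n),
        "gene": gene_of_probe,
        "design_type": np.where(rng.random(n) < 0.3, "I", "II"),
        "island_relation": rng.choice(ISLAND_RELATIONS, n,
                                      p=(0.3, 0.12, 0.12, 0.08, 0.08, 0.3)),
        "is_snp_control": False,
        "is_blacklisted": False,
    })
    if cfg.n_snp_probes:
        snp = pd.DataFrame({
            "probe_id": [f"rs{i:08d}" for i in range(cfg.n_snp_probes)],
            "chrom": [f"chr{c}" for c in rng.integers(1, 23, cfg.n_snp_probes)],
            "position": rng.integers(10_000, 2.4e8, cfg.n_snp_probes),
            "gene": "",
            "design_type": "II",
            "island_relation": "Intergenic",
            "is_snp_control": True,
            "is_blacklisted": False,
        })
        ann = pd.concat([ann, snp], ignore_index=True)
    return ann


def _plant(cfg: TwinCohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Choose planted probes and effect sizes; disjoint sets per effect kind."""
    n = cfg.n_probes
    n_dmp = int(round(cfg.frac_planted_dmp * n))
    n_long = int(round(cfg.frac_planted_longitudinal * n))
    n_age5 = int(round(cfg.frac_planted_age5 * n))
    order = rng.permutation(n)
    take = iter(np.array_split(order, np.cumsum([n_dmp, n_long, n_age5]))[:3])
    idx_dmp, idx_long, idx_age5 = (np.sort(a) for a in take)

    def draw(k: int, bounds: tuple[float, float]) -> np.ndarray:
        mag = rng.uniform(bounds[0], bounds[1], k)
        sign = np.where(rng.random(k) < 0.5, -1.0, 1.0)
        return mag * sign

    rows = []
    for i, eff in zip(idx_dmp, draw(n_dmp, cfg.effect_size_range)):
        rows.append((i, eff, 0.0, 0.0, cfg.dmp_scope))
    for i, eff in zip(idx_long, draw(n_long, cfg.longitudinal_effect_range)):
        rows.append((i, 0.0, 0.0, eff, "persistent"))
    for i, eff in zip(idx_age5, draw(n_age5, cfg.age5_effect_range)):
        rows.append((i, 0.0, eff, 0.0, cfg.dmp_scope))
    truth = pd.DataFrame(
        rows,
        columns=["probe_index", "delta_beta_age10", "delta_beta_age5",
                 "longitudinal_drift", "stratum"],
    )
    return truth


def _scope_pairs(pairs: pd.DataFrame, scope: str) -> pd.Series:
    if scope == "all-discordant":
        return pairs.stratum != "concordant-unaffected"
    return pairs.stratum == scope


def generate_cohort(config: TwinCohortConfig) -> TwinCohort:
    """Generate a deterministic synthetic twin cohort.

    Returns a :class:`TwinCohort` with beta matrices at ages 5 and 10
    (probes x samples), a sample sheet, a probe annotation table and a
    truth table listing every planted effect.  All randomness derives
    from ``config.seed`` via independent child streams.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_design, rng_ann, rng_plant, rng_values, rng_snp = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    pairs = _pair_table(config, rng_design)
    sheet = _sample_sheet(pairs)
    ann = _annotation(config, rng_ann)
    truth = _plant(config, rng_plant)

    n_probes, n_pairs = config.n_probes, len(pairs)
    n_samples = 2 * n_pairs

    # bimodal baseline per probe
    comp = rng_values.choice(3, n_probes, p=config.mixture_weights)
    m = np.empty(n_probes)
    for c, (a, b) in enumerate(config.mixture_shapes):
        mask = comp == c
        m[mask] = rng_values.beta(a, b, mask.sum())

    pair_fx = rng_values.normal(0.0, config.pair_sd, (n_probes, n_pairs))
    batch_fx = rng_values.normal(0.0, config.batch_sd, (n_probes, n_pairs, 2))
    ind_fx = rng_values.normal(0.0, config.individual_sd, (n_probes, n_samples))
    drift = rng_values.normal(0.0, config.age_drift_sd, n_probes)

    pair_of_sample = np.repeat(np.arange(n_pairs), 2)  # twin1, twin2 per pair
    affected_col = np.zeros(n_samples, dtype=bool)
    for p, rec in enumerate(pairs.itertuples(index=False)):
        if rec.affected_role == "twin1":
            affected_col[2 * p] = True
        elif rec.affected_role == "twin2":
            affected_col[2 * p + 1] = True

    base = (
        m[:, None]
        + pair_fx[:, pair_of_sample]
        + ind_fx
    )

    def one_age(age_idx: int) -> np.ndarray:
        x = (
            base
            + batch_fx[:, pair_of_sample, age_idx]
            + rng_values.normal(0.0, config.noise_sd, (n_probes, n_samples))
        )
        if age_idx == 1:
            x += drift[:, None]
        return x

    beta5 = one_age(0)
    beta10 = one_age(1)

    # planted effects: added to the affected twin of in-scope pairs
    for rec in truth.itertuples(index=False):
        in_scope = _scope_pairs(pairs, rec.stratum).to_numpy()
        cols = affected_col & in_scope[pair_of_sample]
        i = int(rec.probe_index)
        if rec.delta_beta_age10:
            beta10[i, cols] += rec.delta_beta_age10
        if rec.delta_beta_age5:
            beta5[i, cols] += rec.delta_beta_age5
        if rec.longitudinal_drift:
            beta10[i, cols] += rec.longitudinal_drift

    np.clip(beta5, 0.0, 1.0, out=beta5)
    np.clip(beta10, 0.0, 1.0, out=beta10)

    probe_ids = ann.probe_id[~ann.is_snp_control].to_numpy()
    truth = truth.assign(probe_id=probe_ids[truth.probe_index]).drop(
        columns="probe_index"
    )[["probe_id", "delta_beta_age10", "delta_beta_age5",
       "longitudinal_drift", "stratum"]]

    # SNP control probes: genotype-like betas shared within a pair
    if config.n_snp_probes:
        geno = rng_snp.choice([0.0, 0.5, 1.0], (config.n_snp_probes, n_pairs))
        snp_vals = geno[:, pair_of_sample]
        def with_snp(x: np.ndarray) -> np.ndarray:
            v = snp_vals + rng_snp.normal(0.0, 0.01, snp_vals.shape)
            return np.vstack([x, np.clip(v, 0.0, 1.0)])
        beta5 = with_snp(beta5)
        beta10 = with_snp(beta10)

    all_probe_ids = ann.probe_id.to_numpy()
    cols5 = sheet.loc[sheet.age == 5, "sample_id"].to_numpy()
    cols10 = sheet.loc[sheet.age == 10, "sample_id"].to_numpy()
    # column order in the value arrays is pair-major (twin1, twin2)
    sample_order = np.array(
        [f"{pid}.{role}" for pid in pairs.pair_id for role in ("twin1", "twin2")]
    )
    col_idx5 = [np.where(sample_order == s.rsplit(".age", 1)[0])[0][0] for s in cols5]
    col_idx10 = [np.where(sample_order == s.rsplit(".age", 1)[0])[0][0] for s in cols10]

    beta_age5 = pd.DataFrame(beta5[:, col_idx5], index=all_probe_ids, columns=cols5)
    beta_age10 = pd.DataFrame(beta10[:, col_idx10], index=all_probe_ids, columns=cols10)
    beta_age5.index.name = beta_age10.index.name = "probe_id"

    return TwinCohort(beta_age5, beta_age10, sheet, ann, truth, config)


def config_digest(config: TwinCohortConfig) -> str:
    payload = repr(sorted(asdict(config).items(), key=lambda kv: kv[0]))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_cohort(cohort: TwinCohort, directory: str | Path,
                 term_map: Mapping[str, Sequence[str]] | None = None) -> dict[str, Path]:
    """Write a cohort to ``directory`` in the package interchange formats.

    Emits the two beta matrices (TSV), the sample sheet (CSV), the probe
    manifest (TSV) and the truth table (TSV); optionally a synthetic
    gene-to-term map (TSV).  Round-trips losslessly through the readers
    in :mod:`twinmeth.io`.
    """
    from . import io as tio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"generator_seed": cohort.config.seed,
            "config_sha256": config_digest(cohort.config)}
    paths = {
        "beta_age5": directory / "beta_age5.tsv",
        "beta_age10": directory / "beta_age10.tsv",
        "sample_sheet": directory / "sample_sheet.csv",
        "manifest": directory / "manifest.tsv",
        "truth": directory / "truth.tsv",
    }
    tio.write_beta_matrix(cohort.beta_age5, paths["beta_age5"], meta=meta)
    tio.write_beta_matrix(cohort.beta_age10, paths["beta_age10"], meta=meta)
    tio.write_sample_sheet(cohort.sample_sheet, paths["sample_sheet"], meta=meta)
    tio.write_manifest(cohort.annotation, paths["manifest"], meta=meta)
    tio.write_truth_table(cohort.truth, paths["truth"], meta=meta)
    if term_map is not None:
        paths["go_map"] = directory / "go_map.tsv"
        tio.write_go_map(term_map, paths["go_map"], meta=meta)
    return paths
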