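"""Umbrella workflow: chain the analysis stages on files on disk.

Stages, in order: probe QC on the beta matrices -> paired EWAS at age 10
over all discordant pairs -> permutation empirical p for its top probes
-> stratification -> paired EWAS restricted to the persistent stratum ->
permutation empirical p for its top probes -> group-specificity ANOVA
with the concordant permutation baseline -> longitudinal delta-beta
analysis -> gene-set enrichment.  Every stage writes a TSV with header
comments (package version, config hash, seeds) and the run manifest
records parameters, derived seeds and input checksums, enough to
reproduce the run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as tio
from .ewas import delta_beta, paired_ewas, global_mean_test, within_twin_correlation
from .permutation import empirical_p_batch
from .specificity import (stratify_pairs, concordant_baseline,
                          oriented_concordant_delta, specificity_anova)
from .longitudinal import (longitudinal_delta, longitudinal_paired_test,
                           cross_age_consistency)
from .enrichment import build_universe, fit_pwf, enrichment_test
from .preprocess import verify_monozygosity

log = logging.getLogger("twinmeth")

__all__ = ["RunConfig", "load_run_config", "run_pipeline"]

_PARAM_DEFAULTS = {
    "detection_p_threshold": 0.05,
    "sample_fail_fraction": 0.05,
    "lowbead_fraction": 0.05,
    "beta_offset": 100.0,
    "dmp_threshold": 1e-4,
    "permutation_cap": 10_000,
    "baseline_reps": 1000,
    "enrichment_threshold": 1e-3,
    "enrichment_samples": 10_000,
    "min_snp_r": 0.9,
    "specificity_top_k": 10,
}

_INPUT_KEYS = {"beta_age10", "beta_age5", "sample_sheet", "manifest",
               "blacklist", "go_map"}


@dataclass
class RunConfig:
    """Paths and stage parameters for :func:`run_pipeline`."""

    inputs: dict[str, str]
    output_dir: str
    seed: int = 0
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - _INPUT_KEYS
        if unknown:
            raise ValueError(f"unknown input keys {sorted(unknown)}")
        for key in ("beta_age10", "sample_sheet", "manifest"):
            if key not in self.inputs:
                raise ValueError(f"missing required input {key!r}")
        unknown = set(self.params) - set(_PARAM_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter keys {sorted(unknown)}")
        merged = dict(_PARAM_DEFAULTS)
        merged.update(self.params)
        self.params = merged


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    unknown = set(raw) - {"inputs", "output_dir", "seed", "params"}
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    return RunConfig(inputs=raw["inputs"], output_dir=raw["output_dir"],
                     seed=int(raw.get("seed", 0)),
                     params=raw.get("params") or {})


def _config_hash(config: RunConfig) -> str:
    # output_dir is excluded so reruns into a fresh directory compare equal
    payload = json.dumps({"inputs": config.inputs, "seed": config.seed,
                          "params": config.params}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _derive_seeds(master: int) -> dict[str, int]:
    names = ["permutation_all", "permutation_persistent", "orientation",
             "baseline", "enrichment"]
    state = np.random.SeedSequence(master).generate_state(len(names))
    return {name: int(s % (2 ** 31)) for name, s in zip(names, state)}


def _write(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# twinmeth {__version__}\n")
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the artifact directory.

    A stage failure raises with the stage name; outputs of completed
    stages are retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    seeds = _derive_seeds(config.seed)
    meta = {"config_sha256": _config_hash(config), "master_seed": config.seed}
    meta.update({f"seed_{k}": v for k, v in seeds.items()})

    stage = "load inputs"
    try:
        beta10 = tio.read_beta_matrix(config.inputs["beta_age10"])
        sheet = tio.read_sample_sheet(config.inputs["sample_sheet"])
        ann = tio.read_manifest(config.inputs["manifest"])
        beta5 = None
        if config.inputs.get("beta_age5"):
            beta5 = tio.read_beta_matrix(config.inputs["beta_age5"])
        if config.inputs.get("blacklist"):
            black = tio.read_blacklist(config.inputs["blacklist"])
            ann = ann.assign(is_blacklisted=ann.is_blacklisted
                             | ann.probe_id.isin(black))

        # stage 1: probe-level QC on beta input + zygosity check
        stage = "qc"
        ann_idx = ann.set_index("probe_id").loc[beta10.index]
        drop_rules = {
            "blacklist": ann_idx.index[ann_idx.is_blacklisted.astype(bool)],
            "sex_chromosome": ann_idx.index[ann_idx.chrom.isin(["chrX", "chrY"])],
            "snp_control": ann_idx.index[ann_idx.is_snp_control.astype(bool)],
        }
        drop: set[str] = set()
        for ids in drop_rules.values():
            drop.update(ids)
        keep = [p for p in beta10.index if p not in drop]
        report_rows = [(f"probes_{rule}", len(ids))
                       for rule, ids in drop_rules.items()]
        report_rows += [("probes_retained", len(keep)),
                        ("samples_retained", beta10.shape[1])]
        _write(pd.DataFrame(report_rows, columns=["rule", "count"]),
               outdir / "01_filter_report.tsv", meta)
        if ann.is_snp_control.any():
            zyg = verify_monozygosity(beta10, ann, sheet,
                                      min_r=params["min_snp_r"])
            _write(zyg, outdir / "01_zygosity.tsv", meta)
        beta10_qc = beta10.loc[keep]
        beta5_qc = beta5.loc[beta5.index.intersection(keep)] if beta5 is not None \
            else None
        ann_qc = ann[ann.probe_id.isin(keep)]

        # stage 2: paired EWAS, all discordant pairs at age 10
        stage = "dmp age10 all discordant"
        strata, excluded = stratify_pairs(sheet)
        discordant = sorted(strata.index[strata.isin(["persistent", "remission"])])
        # pairs discordant at 10 whose age-18 outcome is concordant-affected
        # or unknown still count in the age-10 analysis
        sub10 = sheet[sheet.age == 10]
        all_disc = sorted(
            pair for pair, grp in sub10.groupby("pair_id")
            if sorted(grp.status_age10).count("affected") == 1
        )
        results_all = paired_ewas(beta10_qc, sheet, age=10, pairs=all_disc,
                                  annotation=ann_qc)
        _write(results_all, outdir / "02_dmp_age10_all.tsv", meta)
        gmt = global_mean_test(beta10_qc, sheet)
        r_pairs, mean_r = within_twin_correlation(beta10_qc, sheet)

        # stage 3: empirical p, all discordant pairs
        stage = "empirical p all discordant"
        delta_all = delta_beta(beta10_qc, sheet, age=10, pairs=all_disc)
        emp_all = empirical_p_batch(results_all, delta_all,
                                    threshold=params["dmp_threshold"],
                                    cap=int(params["permutation_cap"]),
                                    seed=seeds["permutation_all"])
        _write(emp_all, outdir / "03_empirical_all.tsv", meta)

        # stage 4: stratification
        stage = "stratify"
        strata_df = strata.rename_axis("pair_id").reset_index()
        for pair, reason in excluded.items():
            strata_df = pd.concat(
                [strata_df, pd.DataFrame([{"pair_id": pair,
                                           "stratum": f"excluded: {reason}"}])],
                ignore_index=True)
        _write(strata_df.sort_values("pair_id"), outdir / "04_strata.tsv", meta)

        persistent = sorted(strata.index[strata == "persistent"])
        remission = sorted(strata.index[strata == "remission"])
        concordant = sorted(strata.index[strata == "concordant-unaffected"])

        # stage 5: paired EWAS, persistent stratum
        stage = "dmp age10 persistent"
        results_pers = paired_ewas(beta10_qc, sheet, age=10, pairs=persistent,
                                   annotation=ann_qc)
        _write(results_pers, outdir / "05_dmp_age10_persistent.tsv", meta)

        # stage 6: empirical p, persistent stratum
        stage = "empirical p persistent"
        delta_pers = delta_beta(beta10_qc, sheet, age=10, pairs=persistent)
        emp_pers = empirical_p_batch(results_pers, delta_pers,
                                     threshold=params["dmp_threshold"],
                                     cap=int(params["permutation_cap"]),
                                     seed=seeds["permutation_persistent"])
        _write(emp_pers, outdir / "06_empirical_persistent.tsv", meta)

        # probes of interest: top persistent DMPs (fallback: top-k by rank)
        top = results_pers[results_pers.p < params["dmp_threshold"]]
        if top.empty:
            k = int(params["specificity_top_k"])
            log.info("no probe below the DMP threshold; using top %d by rank", k)
            top = results_pers.nsmallest(k, "rank")
        probes_of_interest = top.probe_id.tolist()

        # stage 7: group specificity
        stage = "specificity"
        delta_rem = delta_beta(beta10_qc, sheet, age=10, pairs=remission)
        groups = {
            "persistent": delta_pers.loc[probes_of_interest],
            "remission": delta_rem.loc[probes_of_interest],
            "concordant": oriented_concordant_delta(
                beta10_qc, sheet, concordant, probes=probes_of_interest,
                seed=seeds["orientation"]),
        }
        spec = specificity_anova(groups)
        baseline, _ = concordant_baseline(
            beta10_qc, sheet, concordant, probes=probes_of_interest,
            n_reps=int(params["baseline_reps"]), seed=seeds["baseline"])
        spec["concordant_permutation_baseline"] = baseline.to_numpy()
        _write(spec, outdir / "07_specificity.tsv", meta)

        # stage 8: longitudinal analysis (needs age-5 betas)
        stage = "longitudinal"
        cross_age = None
        if beta5_qc is not None:
            ldelta = longitudinal_delta(beta5_qc, beta10_qc, sheet)
            ltest = longitudinal_paired_test(ldelta, sheet, pairs=persistent)
            ltest = ltest.merge(
                ann_qc.assign(hg19=ann_qc.chrom.str.replace("chr", "Chr",
                                                            regex=False)
                              + ":" + ann_qc.position.astype(str))
                [["probe_id", "hg19", "island_relation", "gene", "design_type"]],
                on="probe_id", how="left")
            _write(ltest, outdir / "08_longitudinal.tsv", meta)
            age5_pairs = [p for p in persistent
                          if p not in ldelta.attrs["excluded_pairs"]]
            if len(probes_of_interest) >= 3 and len(age5_pairs) >= 2:
                delta5 = delta_beta(beta5_qc, sheet, age=5, pairs=age5_pairs)
                cross_age = cross_age_consistency(
                    delta5, delta_pers, probes_of_interest)
        else:
            log.info("no age-5 betas supplied; longitudinal stage skipped")

        # stage 9: enrichment (needs gene-to-term map)
        stage = "enrichment"
        if config.inputs.get("go_map"):
            term_map = tio.read_go_map(config.inputs["go_map"])
            universe = build_universe(results_all, ann_qc,
                                      p_threshold=params["enrichment_threshold"])
            if universe.significant.any():
                pwf = fit_pwf(universe)
                enr = enrichment_test(universe, pwf, term_map,
                                      n_samples=int(params["enrichment_samples"]),
                                      seed=seeds["enrichment"])
            else:
                enr = pd.DataFrame(columns=["term", "term_size", "observed",
                                            "expected", "p"])
            _write(enr, outdir / "09_enrichment.tsv", meta)
        else:
            log.info("no gene-to-term map supplied; enrichment stage skipped")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "config_sha256": meta["config_sha256"],
            "derived_seeds": seeds,
            "input_checksums": {k: _checksum(v)
                                for k, v in config.inputs.items() if v},
            "global_mean_test": gmt,
            "mean_within_pair_r": mean_r,
            "within_pair_r": {k: float(v) for k, v in r_pairs.items()},
            "cross_age_consistency": (
                {"r": cross_age["r"], "p": cross_age["p"]} if cross_age else None),
            "excluded_pairs": excluded,
        }
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
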