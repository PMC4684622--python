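"""Readers and writers for the package interchange formats.

All tables are plain text: beta matrices, probe manifests, truth tables
and gene-to-term maps are tab-separated; the sample sheet is CSV.  Every
writer can prepend ``#``-prefixed header comments (package version,
config hash, seeds) which all readers skip.  Readers validate and reject
malformed input rather than silently coercing it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

PHENOTYPE_TOKENS = ("affected", "unaffected", "unknown")
DESIGN_TYPES = ("I", "II")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "Intergenic")
CHROMOSOMES = tuple(f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"])

SHEET_COLUMNS = ["sample_id", "pair_id", "role", "age",
                 "status_age5", "status_age10", "status_age18", "batch_id"]
MANIFEST_COLUMNS = ["probe_id", "chrom", "position", "gene", "design_type",
                    "island_relation", "is_snp_control", "is_blacklisted"]
TRUTH_COLUMNS = ["probe_id", "delta_beta_age10", "delta_beta_age5",
                 "longitudinal_drift", "stratum"]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _write_header(handle, meta: Mapping[str, object] | None) -> None:
    handle.write(f"# twinmeth {__version__}\n")
    for key, value in (meta or {}).items():
        handle.write(f"# {key}={value}\n")


# ---------------------------------------------------------------------------
# beta matrices

def read_beta_matrix(path: str | Path, tol: float = 1e-9) -> pd.DataFrame:
    """Read a probes x samples beta matrix (probe id in the first column).

    Rejects duplicate probe/sample ids, non-numeric cells and values
    outside [0, 1] beyond ``tol``; empty cells and ``NA`` are missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), comment="#", index_col=0,
                     na_values=["NA", ""], keep_default_na=False,
                     float_precision="round_trip")
    df.index.name = "probe_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            raise ValueError(
                f"non-numeric value {bad.iloc[0]!r} at probe {bad.index[0]!r}, "
                f"sample {col!r} in {path}")
    values = df.to_numpy(dtype=float)
    bad = (values < -tol) | (values > 1.0 + tol)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value {values[i, j]} out of [0, 1] at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r} in {path}")
    return df.astype(float)


def write_beta_matrix(beta: pd.DataFrame, path: str | Path,
                      meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        beta.to_csv(fh, sep=_sep(path), na_rep="NA", index_label="probe_id")


# ---------------------------------------------------------------------------
# sample sheet

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns {missing}")
    if sheet.sample_id.duplicated().any():
        dup = sheet.sample_id[sheet.sample_id.duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    for col in ("status_age5", "status_age10", "status_age18"):
        bad = ~sheet[col].isin(PHENOTYPE_TOKENS)
        if bad.any():
            raise ValueError(
                f"unknown phenotype token {sheet.loc[bad, col].iloc[0]!r} "
                f"in column {col}")
    bad_role = ~sheet.role.isin(("twin1", "twin2"))
    if bad_role.any():
        raise ValueError(f"unknown role {sheet.loc[bad_role, 'role'].iloc[0]!r}")
    for (pair, age), grp in sheet.groupby(["pair_id", "age"]):
        if len(grp) != 2 or set(grp.role) != {"twin1", "twin2"}:
            raise ValueError(
                f"pair {pair!r} must have exactly twin1 and twin2 at age {age} "
                f"(got {len(grp)} rows)")
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sheet = pd.read_csv(path, sep=_sep(path), comment="#", dtype={"age": int})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path,
                       meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        sheet.to_csv(fh, sep=_sep(path), index=False)


# ---------------------------------------------------------------------------
# probe manifest

def validate_manifest(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    if ann.probe_id.duplicated().any():
        dup = ann.probe_id[ann.probe_id.duplicated()].iloc[0]
        raise ValueError(f"duplicate probe id {dup!r} in manifest")
    bad = ~ann.design_type.isin(DESIGN_TYPES)
    if bad.any():
        raise ValueError(
            f"unknown design type {ann.loc[bad, 'design_type'].iloc[0]!r}")
    bad = ~ann.island_relation.isin(ISLAND_RELATIONS)
    if bad.any():
        raise ValueError(
            f"unknown island relation {ann.loc[bad, 'island_relation'].iloc[0]!r}")
    bad = ~ann.chrom.isin(CHROMOSOMES)
    if bad.any():
        raise ValueError(f"unknown chromosome {ann.loc[bad, 'chrom'].iloc[0]!r}")
    return ann


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    ann = pd.read_csv(
        path, sep=_sep(path), comment="#",
        dtype={"position": int, "is_snp_control": bool, "is_blacklisted": bool},
        na_values=[""], keep_default_na=False,
    )
    ann["gene"] = ann.gene.fillna("")
    return validate_manifest(ann)


def write_manifest(ann: pd.DataFrame, path: str | Path,
                   meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        ann.to_csv(fh, sep=_sep(path), index=False)


# ---------------------------------------------------------------------------
# truth table, blacklist, gene-to-term map

def read_truth_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    truth = pd.read_csv(path, sep=_sep(path), comment="#", float_precision="round_trip")
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ValueError(f"truth table missing columns {missing}")
    return truth


def write_truth_table(truth: pd.DataFrame, path: str | Path,
                      meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        truth.to_csv(fh, sep=_sep(path), index=False)


def read_blacklist(path: str | Path) -> set[str]:
    """One probe id per line; ``#`` comments allowed."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def read_go_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (gene, term id; one row per membership) -> term -> genes."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), comment="#",
                     names=["gene", "term"], header=0)
    mapping: dict[str, list[str]] = {}
    for term, grp in df.groupby("term"):
        mapping[str(term)] = sorted(set(grp.gene.astype(str)))
    return mapping


def write_go_map(term_map: Mapping[str, Sequence[str]], path: str | Path,
                 meta: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        fh.write("gene\tterm\n")
        for term in sorted(term_map):
            for gene in term_map[term]:
                fh.write(f"{gene}\t{term}\n")
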