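"""Within-pair differential methylation (paired EWAS).

The unit of analysis is the within-pair difference of beta values
(delta-beta), with the sign convention *affected twin minus unaffected
co-twin* everywhere.  Per probe, a paired t-test on the pair differences
gives a nominal two-sided p-value; probes are ranked by p and flagged at
the Bonferroni threshold 0.05 / n_tested.  Diagnostics cover overall
mean methylation (no global shift expected) and within-pair correlation
across probes (near 0.97 for identical twins on methylation arrays).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "discordant_pairs",
    "pair_columns",
    "delta_beta",
    "paired_t_per_probe",
    "paired_ewas",
    "global_mean_test",
    "within_twin_correlation",
]


def discordant_pairs(sheet: pd.DataFrame, age: int = 10) -> list[str]:
    """Pairs with exactly one affected member at ``age``."""
    sub = sheet[sheet.age == age]
    status_col = f"status_age{age}"
    return sorted(pair for pair, grp in sub.groupby("pair_id")
                  if (grp[status_col] == "affected").sum() == 1)


def pair_columns(sheet: pd.DataFrame, age: int,
                 pairs: list[str] | None = None,
                 require_discordant: bool = True,
                 ) -> tuple[list[str], list[str], list[str]]:
    """Resolve (pair ids, affected sample ids, unaffected sample ids) at ``age``.

    With ``require_discordant`` every pair must have exactly one member
    affected at that age; a violation raises and names the pair.
    """
    sub = sheet[sheet.age == age]
    status_col = f"status_age{age}" if f"status_age{age}" in sheet.columns \
        else "status_age10"
    if pairs is None:
        pairs = sorted(sub.pair_id.unique())
    aff, unaff, kept = [], [], []
    for pair in pairs:
        grp = sub[sub.pair_id == pair]
        if len(grp) != 2:
            raise ValueError(f"pair {pair!r} does not have two samples at age {age}")
        affected = grp[grp[status_col] == "affected"]
        if len(affected) != 1:
            if require_discordant:
                raise ValueError(
                    f"pair {pair!r} is not discordant at age {age}: "
                    f"{len(affected)} affected members")
            continue
        aff.append(affected.sample_id.iloc[0])
        unaff.append(grp.loc[grp.index.difference(affected.index),
                             "sample_id"].iloc[0])
        kept.append(pair)
    return kept, aff, unaff


def delta_beta(beta: pd.DataFrame, sheet: pd.DataFrame, age: int = 10,
               pairs: list[str] | None = None) -> pd.DataFrame:
    """Per-probe per-pair delta-beta matrix (affected minus unaffected).

    Missing beta values propagate as missing for that pair and probe.
    Every included pair must be discordant at ``age``; a violation
    raises and names the pair.
    """
    kept, aff, unaff = pair_columns(sheet, age, pairs)
    delta = pd.DataFrame(
        beta[aff].to_numpy() - beta[unaff].to_numpy(),
        index=beta.index, columns=kept,
    )
    delta.index.name = "probe_id"
    return delta


def _rank(p: np.ndarray, abs_delta: np.ndarray, probe_ids: np.ndarray) -> np.ndarray:
    """Rank 1..n by p ascending; ties by |delta| descending, then probe id."""
    p_key = np.where(np.isnan(p), np.inf, p)
    order = np.lexsort((probe_ids, -abs_delta, p_key))
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks


def paired_t_per_probe(delta: pd.DataFrame,
                       cotwin_mean: pd.Series | None = None,
                       affected_mean: pd.Series | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-test per probe on a delta-beta matrix.

    Probes with constant differences (zero variance) or fewer than two
    complete pairs get a missing p with an explanatory note instead of
    crashing.  Ranks are a permutation of 1..n_probes; the Bonferroni
    flag uses ``alpha`` / number of testable probes.
    """
    d = delta.to_numpy(dtype=float)
    n = (~np.isnan(d)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=1)
        sd = np.full(len(d), np.nan)
        ok_n = n >= 2
        sd[ok_n] = np.nanstd(d[ok_n], axis=1, ddof=1)
    t = np.full(len(d), np.nan)
    p = np.full(len(d), np.nan)
    note = np.full(len(d), "", dtype=object)
    note[~ok_n] = "fewer than two complete pairs"
    const = ok_n & (sd == 0)
    note[const] = "constant differences"
    testable = ok_n & (sd > 0)
    t[testable] = mean[testable] / (sd[testable] / np.sqrt(n[testable]))
    p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), n[testable] - 1)

    n_tested = int(testable.sum())
    threshold = alpha / n_tested if n_tested else np.nan
    out = pd.DataFrame({
        "probe_id": delta.index.to_numpy(),
        "n_pairs": n,
        "mean_delta_beta": mean,
        "t": t,
        "df": np.where(ok_n, n - 1, 0),
        "p": p,
        "note": note,
    })
    if cotwin_mean is not None:
        out.insert(1, "cotwin_mean", np.asarray(cotwin_mean))
    if affected_mean is not None:
        out.insert(2, "asthma_mean", np.asarray(affected_mean))
    out["rank"] = _rank(p, np.abs(np.where(np.isnan(mean), 0.0, mean)),
                        out.probe_id.to_numpy())
    out["bonferroni_significant"] = out.p < threshold
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def paired_ewas(beta: pd.DataFrame, sheet: pd.DataFrame, age: int = 10,
                pairs: list[str] | None = None,
                annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full per-probe paired analysis with group means and annotation join."""
    kept, aff, unaff = pair_columns(sheet, age, pairs)
    delta = pd.DataFrame(beta[aff].to_numpy() - beta[unaff].to_numpy(),
                         index=beta.index, columns=kept)
    cotwin = pd.Series(np.nanmean(beta[unaff].to_numpy(), axis=1), index=beta.index)
    affected = pd.Series(np.nanmean(beta[aff].to_numpy(), axis=1), index=beta.index)
    results = paired_t_per_probe(delta, cotwin_mean=cotwin, affected_mean=affected)
    if annotation is not None:
        ann = annotation.assign(
            hg19=annotation.chrom.str.replace("chr", "Chr", regex=False)
            + ":" + annotation.position.astype(str)
        )[["probe_id", "hg19", "island_relation", "gene", "design_type"]]
        results = results.merge(ann, on="probe_id", how="left")
    return results


def global_mean_test(beta: pd.DataFrame, sheet: pd.DataFrame,
                     age: int = 10) -> dict[str, float]:
    """Paired t-test on per-sample mean methylation across all probes.

    Detects global shifts in methylation between affected and unaffected
    twins; a null result means any signal is probe-specific.
    """
    kept, aff, unaff = pair_columns(sheet, age, require_discordant=False)
    sample_means = beta.mean(axis=0, skipna=True)
    d = sample_means[aff].to_numpy() - sample_means[unaff].to_numpy()
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) >= 2 else np.nan
    if not np.isfinite(sd) or sd == 0:
        return {"mean_difference": mean, "t": np.nan, "p": np.nan,
                "n_pairs": len(d), "note": "constant differences"}
    t = mean / (sd / np.sqrt(len(d)))
    p = float(2.0 * stats.t.sf(abs(t), len(d) - 1))
    return {"mean_difference": mean, "t": float(t), "p": p,
            "n_pairs": len(d), "note": ""}


def within_twin_correlation(beta: pd.DataFrame, sheet: pd.DataFrame,
                            age: int = 10) -> tuple[pd.Series, float]:
    """Pearson correlation across probes within each pair, plus the mean."""
    if len(beta) < 2:
        raise ValueError("within-pair correlation needs at least two probes")
    sub = sheet[sheet.age == age]
    out = {}
    for pair, grp in sub.groupby("pair_id"):
        cols = grp.sort_values("role").sample_id.tolist()
        x = beta[cols[0]].to_numpy(dtype=float)
        y = beta[cols[1]].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        out[pair] = float(stats.pearsonr(x[ok], y[ok]).statistic)
    r = pd.Series(out, name="within_pair_r").sort_index()
    return r, float(r.mean())
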