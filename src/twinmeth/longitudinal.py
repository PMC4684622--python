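"""Intra-individual methylation change between two sampling ages.

The longitudinal delta-beta of an individual is beta(age 10) minus
beta(age 5) at each probe.  Within the persistent stratum, the contrast
of interest is the within-pair difference of longitudinal change
(affected minus unaffected), tested with the same paired t machinery as
the cross-sectional analysis.  By construction the age-10 within-pair
difference minus the age-5 within-pair difference equals the within-pair
difference of longitudinal change — an algebraic identity used as a
consistency check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import paired_t_per_probe

__all__ = ["longitudinal_delta", "longitudinal_paired_test", "cross_age_consistency"]


def longitudinal_delta(beta5: pd.DataFrame, beta10: pd.DataFrame,
                       sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-individual change matrix beta(age 10) - beta(age 5).

    Individuals are matched across ages by (pair id, role); columns of
    the result are "pair.role" individual ids.  Pairs missing either
    member at age 5 are excluded pair-wise (listed in
    ``result.attrs['excluded_pairs']``).  Probes are intersected across
    the two matrices (order of the age-10 matrix).
    """
    probes = beta10.index.intersection(beta5.index)
    if len(probes) == 0:
        raise ValueError("empty probe intersection between ages")
    s5 = sheet[sheet.age == 5].set_index(["pair_id", "role"])
    s10 = sheet[sheet.age == 10].set_index(["pair_id", "role"])
    cols5, cols10, individuals = [], [], []
    excluded: list[str] = []
    for pair in sheet.pair_id.unique():
        keys = [(pair, "twin1"), (pair, "twin2")]
        if not all(k in s10.index for k in keys):
            continue
        if not all(k in s5.index for k in keys):
            excluded.append(pair)
            continue
        for key in keys:
            cols5.append(s5.loc[key, "sample_id"])
            cols10.append(s10.loc[key, "sample_id"])
            individuals.append(f"{key[0]}.{key[1]}")
    delta = pd.DataFrame(
        beta10.loc[probes, cols10].to_numpy() - beta5.loc[probes, cols5].to_numpy(),
        index=probes, columns=individuals,
    )
    delta.index.name = "probe_id"
    delta.attrs["excluded_pairs"] = excluded
    return delta


def longitudinal_paired_test(longitudinal: pd.DataFrame, sheet: pd.DataFrame,
                             pairs: list[str] | None = None) -> pd.DataFrame:
    """Paired t per probe on within-pair differences of longitudinal change.

    The reported co-twin/affected means are means of longitudinal change
    (they can be negative).  ``pairs`` restricts to a stratum; pairs not
    present in the longitudinal matrix are dropped.
    """
    s10 = sheet[sheet.age == 10]
    have = {c.rsplit(".", 1)[0] for c in longitudinal.columns}
    aff_cols, unaff_cols = [], []
    for pair in (pairs if pairs is not None else sorted(have)):
        if pair not in have:
            continue
        grp = s10[s10.pair_id == pair]
        affected = grp[grp.status_age10 == "affected"]
        if len(affected) != 1:
            raise ValueError(f"pair {pair!r} is not discordant at age 10")
        role_aff = affected.role.iloc[0]
        role_unaff = "twin2" if role_aff == "twin1" else "twin1"
        aff_cols.append(f"{pair}.{role_aff}")
        unaff_cols.append(f"{pair}.{role_unaff}")
    if len(aff_cols) < 2:
        raise ValueError("need at least two complete pairs")
    delta = pd.DataFrame(
        longitudinal[aff_cols].to_numpy() - longitudinal[unaff_cols].to_numpy(),
        index=longitudinal.index,
        columns=[c.rsplit(".", 1)[0] for c in aff_cols],
    )
    cotwin = pd.Series(np.nanmean(longitudinal[unaff_cols].to_numpy(), axis=1),
                       index=longitudinal.index)
    affected_mean = pd.Series(np.nanmean(longitudinal[aff_cols].to_numpy(), axis=1),
                              index=longitudinal.index)
    return paired_t_per_probe(delta, cotwin_mean=cotwin, affected_mean=affected_mean)


def cross_age_consistency(delta5: pd.DataFrame, delta10: pd.DataFrame,
                          probes: list[str]) -> dict[str, object]:
    """Correlation of within-pair differences across ages at selected probes.

    Pearson correlation across ``probes`` between mean within-pair
    delta-beta at age 5 and at age 10, plus the per-probe paired t-tests
    at age 5 (re-running the cross-sectional analysis at the earlier
    age, restricted to the probes of interest).
    """
    if len(probes) < 3:
        raise ValueError("cross-age consistency needs at least three probes")
    m5 = delta5.loc[probes].mean(axis=1, skipna=True)
    m10 = delta10.loc[probes].mean(axis=1, skipna=True)
    r, p = stats.pearsonr(m5.to_numpy(), m10.to_numpy())
    age5_tests = paired_t_per_probe(delta5.loc[probes])
    return {"r": float(r), "p": float(p), "age5_tests": age5_tests}
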