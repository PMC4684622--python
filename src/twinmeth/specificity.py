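"""Group specificity of within-pair methylation differences.

Compares per-pair delta-beta at probes of interest across three strata
of twin pairs — persistently discordant, remission (discordant in
childhood, concordant unaffected later) and concordant unaffected — with
a one-way fixed-effects ANOVA and post hoc pairwise t-tests (Holm
adjusted by default).  Concordant pairs have no affected/unaffected
orientation, so their "difference" is defined under a random within-pair
orientation; a permutation baseline (mean over many random orientations,
default 1000) is reported alongside, and the ANOVA uses the per-pair
values under a single seeded orientation so that the concordant group
size stays honest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["stratify_pairs", "concordant_baseline", "specificity_anova",
            "holm_adjust", "oriented_concordant_delta"]


def stratify_pairs(sheet: pd.DataFrame) -> tuple[pd.Series, dict[str, str]]:
    """Assign each pair to persistent / remission / concordant-unaffected.

    * persistent: discordant at age 10 and still discordant at 18;
    * remission: discordant at 10, both unaffected at 18;
    * concordant-unaffected: both unaffected at 10 and 18.

    Pairs discordant at 10 but concordant affected at 18, and pairs with
    an unknown age-18 phenotype, are excluded; the returned dict maps
    excluded pair ids to the reason.
    """
    sub = sheet[sheet.age == 10]
    strata: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for pair, grp in sub.groupby("pair_id"):
        if len(grp) != 2:
            raise ValueError(f"pair {pair!r} does not have two age-10 samples")
        s10 = sorted(grp.status_age10)
        s18 = sorted(grp.status_age18)
        if "unknown" in s10:
            raise ValueError(f"pair {pair!r} has unknown age-10 phenotype")
        n10 = s10.count("affected")
        if "unknown" in s18:
            excluded[pair] = "age-18 phenotype unknown"
            continue
        n18 = s18.count("affected")
        if n10 == 1 and n18 == 1:
            strata[pair] = "persistent"
        elif n10 == 1 and n18 == 0:
            strata[pair] = "remission"
        elif n10 == 0 and n18 == 0:
            strata[pair] = "concordant-unaffected"
        elif n10 == 1 and n18 == 2:
            excluded[pair] = "concordant affected at 18"
        else:
            excluded[pair] = "concordant affected"
    return pd.Series(strata, name="stratum").sort_index(), excluded


def _twin_columns(sheet: pd.DataFrame, pairs: list[str], age: int = 10,
                  ) -> tuple[list[str], list[str]]:
    sub = sheet[sheet.age == age]
    c1, c2 = [], []
    for pair in pairs:
        grp = sub[sub.pair_id == pair].set_index("role")
        c1.append(grp.loc["twin1", "sample_id"])
        c2.append(grp.loc["twin2", "sample_id"])
    return c1, c2


def concordant_baseline(beta: pd.DataFrame, sheet: pd.DataFrame,
                        pairs: list[str], probes: list[str] | None = None,
                        n_reps: int = 1000, seed: int | None = 0,
                        ) -> tuple[pd.Series, np.ndarray]:
    """Permutation-averaged within-pair difference for concordant pairs.

    Each replicate assigns every pair a random orientation (twin 1 minus
    twin 2 or the reverse), averages the within-pair difference across
    pairs per probe, and the baseline is the mean over replicates.  By
    sign symmetry the expectation is zero; the replicate averages are
    returned so callers can form Monte-Carlo intervals.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(pairs) < 2:
        raise ValueError("need at least two concordant pairs")
    c1, c2 = _twin_columns(sheet, pairs)
    block = beta if probes is None else beta.loc[probes]
    d = block[c1].to_numpy() - block[c2].to_numpy()  # probes x pairs
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_reps, len(pairs))).astype(float) * 2 - 1
    rep_avgs = d @ signs.T / len(pairs)  # probes x reps
    baseline = pd.Series(rep_avgs.mean(axis=1), index=block.index,
                         name="baseline_delta_beta")
    return baseline, rep_avgs


def oriented_concordant_delta(beta: pd.DataFrame, sheet: pd.DataFrame,
                              pairs: list[str],
                              probes: list[str] | None = None,
                              seed: int | None = 0) -> pd.DataFrame:
    """Per-pair within-pair difference under one seeded random orientation."""
    c1, c2 = _twin_columns(sheet, pairs)
    block = beta if probes is None else beta.loc[probes]
    d = block[c1].to_numpy() - block[c2].to_numpy()
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=len(pairs)).astype(float) * 2 - 1
    return pd.DataFrame(d * signs, index=block.index, columns=pairs)


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment along the last axis."""
    p = np.asarray(p, dtype=float)
    m = p.shape[-1]
    order = np.argsort(p, axis=-1)
    mult = (m - np.arange(m)).astype(float)
    sorted_p = np.take_along_axis(p, order, axis=-1) * mult
    sorted_p = np.maximum.accumulate(sorted_p, axis=-1)
    adj = np.empty_like(p)
    np.put_along_axis(adj, order, np.clip(sorted_p, None, 1.0), axis=-1)
    return adj


def specificity_anova(groups: dict[str, pd.DataFrame],
                      adjust: str = "holm",
                      welch: bool = False) -> pd.DataFrame:
    """One-way ANOVA plus post hoc pairwise t-tests per probe.

    ``groups`` maps a stratum name to a probes x pairs delta-beta frame;
    all frames must share the probe index.  Classical (equal-variance)
    ANOVA and pooled-variance t-tests by default, Welch variants behind
    ``welch=True``.  Pairwise p-values are reported raw and adjusted.
    """
    names = [k for k, v in groups.items() if v.shape[1] > 0]
    if len(names) < 2:
        raise ValueError("ANOVA needs at least two non-empty groups")
    for name in names:
        if groups[name].shape[1] < 2:
            raise ValueError(f"group {name!r} has fewer than two pairs")
    index = groups[names[0]].index
    arrays = [groups[k].loc[index].to_numpy().T for k in names]  # pairs x probes

    F, p_anova = stats.f_oneway(*arrays, axis=0)  # classical fixed-effects F

    out = pd.DataFrame({"probe_id": index.to_numpy()})
    for name, arr in zip(names, arrays):
        out[f"mean_{name}"] = arr.mean(axis=0)
    out["F"] = F
    out["p_anova"] = p_anova

    raw = []
    labels = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            t_res = stats.ttest_ind(arrays[i], arrays[j], axis=0,
                                    equal_var=not welch)
            raw.append(np.atleast_1d(t_res.pvalue))
            labels.append(f"{names[i]}_vs_{names[j]}")
    raw_mat = np.column_stack(raw)
    adj_mat = holm_adjust(raw_mat) if adjust == "holm" else raw_mat
    for k, lab in enumerate(labels):
        out[f"p_{lab}"] = raw_mat[:, k]
        out[f"p_adj_{lab}"] = adj_mat[:, k]
    zero_var = np.all([a.std(axis=0, ddof=1) == 0 for a in arrays], axis=0)
    out["note"] = np.where(zero_var, "untestable: zero variance in all groups", "")
    return out
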