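import numpy as np
import pandas as pd
import pytest

from twinmeth import TwinCohortConfig, generate_cohort

try:
    from hypothesis import settings
    settings.register_profile("suite", max_examples=25, deadline=None,
                              derandomize=True)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted effects (full study design)."""
    cfg = TwinCohortConfig(n_probes=500, frac_planted_dmp=0.0,
                           frac_planted_longitudinal=0.0, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def design_sheet(null_cohort):
    return null_cohort.sample_sheet


def make_paired_cohort(affected_rows, unaffected_rows, probe_ids=None,
                       age=10):
    """Hand-built beta matrix + sheet: one column per twin, constant rows.

    ``affected_rows`` / ``unaffected_rows`` are (n_probes, n_pairs)
    arrays (or lists of per-probe per-pair values).
    """
    aff = np.atleast_2d(np.asarray(affected_rows, dtype=float))
    unaff = np.atleast_2d(np.asarray(unaffected_rows, dtype=float))
    n_probes, n_pairs = aff.shape
    if probe_ids is None:
        probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    cols, rows, data = [], [], {}
    for p in range(n_pairs):
        pair = f"pair{p + 1:03d}"
        a_id = f"{pair}.twin1.age{age}"
        u_id = f"{pair}.twin2.age{age}"
        data[a_id] = aff[:, p]
        data[u_id] = unaff[:, p]
        for role, sid, status in (("twin1", a_id, "affected"),
                                  ("twin2", u_id, "unaffected")):
            rows.append({
                "sample_id": sid, "pair_id": pair, "role": role, "age": age,
                "status_age5": status, "status_age10": status,
                "status_age18": status, "batch_id": f"array_{pair}",
            })
    beta = pd.DataFrame(data, index=probe_ids)
    beta.index.name = "probe_id"
    return beta, pd.DataFrame(rows)
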