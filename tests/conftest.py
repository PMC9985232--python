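import numpy as np
import pandas as pd
import pytest

import twinewas as tw


@pytest.fixture(scope="session")
def null_sim():
    """Small null cohort shared across read-only tests."""
    sc = tw.SimScenario(name="null", n_pairs=100, n_cpgs=500, seed=1)
    return tw.simulate_twin_cohort(sc)


@pytest.fixture(scope="session")
def null_cohort(null_sim):
    return tw.derive_bp(null_sim.cohort, "SBP")


@pytest.fixture()
def tiny_cohort():
    """Four hand-built pairs with controlled readings."""
    rows = []
    readings = {
        "p1": ((120, 124, 122), (118, 122, 120)),
        "p2": ((140, 140, 140), (120, 120, 120)),
        "p3": ((130, 130, 130), (129, 131, 130)),
        "p4": ((131, 131, 131), (129, 129, 129)),
    }
    for pid, (r1, r2) in readings.items():
        for t, r in ((1, r1), (2, r2)):
            rows.append({
                "individual_id": f"{pid}_t{t}", "pair_id": pid, "twin_index": t,
                "sex": "F", "age_years": 50.0,
                "sbp1": r[0], "sbp2": r[1], "sbp3": r[2],
                "dbp1": r[0] - 50, "dbp2": r[1] - 50, "dbp3": r[2] - 50,
            })
    return tw.TwinCohort(pd.DataFrame(rows))


def make_matrix(beta_rows, ids, positions=None, chrom="chr1"):
    """Build a CpgMatrix from a list of per-CpG beta vectors."""
    beta = np.asarray(beta_rows, dtype=float)
    if positions is None:
        positions = 1000 + 100 * np.arange(len(beta))
    idx = pd.MultiIndex.from_arrays(
        [np.repeat(chrom, len(beta)), np.asarray(positions, dtype=np.int64)],
        names=["chrom", "pos"])
    return tw.CpgMatrix(pd.DataFrame(beta, index=idx, columns=ids))
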