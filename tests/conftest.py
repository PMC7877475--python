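import numpy as np
import pandas as pd
import pytest

from spineclust.records import CohortTable


def build_cohort(spines, branches, animals):
    """Assemble a CohortTable from plain row dicts (test helper)."""
    return CohortTable(
        animals=pd.DataFrame(animals),
        branches=pd.DataFrame(branches),
        spines=pd.DataFrame(spines),
    )


def spine(spine_id, branch_id, pos, pattern):
    t0, t1, t2 = pattern
    return {
        "spine_id": spine_id,
        "branch_id": branch_id,
        "position_um": float(pos),
        "present_t0": bool(t0),
        "present_t1": bool(t1),
        "present_t2": bool(t2),
    }


@pytest.fixture
def tiny_cohort():
    """Two animals (one per genotype), one branch each, hand-placed spines."""
    animals = [
        {"animal_id": "W1", "genotype": "WT", "condition": "trained", "rotarod_mean_s": 80.0},
        {"animal_id": "D1", "genotype": "DUP", "condition": "trained", "rotarod_mean_s": 95.0},
    ]
    branches = [
        {"branch_id": "W1b1", "animal_id": "W1", "length_um": 100.0},
        {"branch_id": "D1b1", "animal_id": "D1", "length_um": 80.0},
    ]
    spines = [
        spine("s1", "W1b1", 5.0, (1, 1, 1)),   # baseline, survives
        spine("s2", "W1b1", 20.0, (1, 0, 0)),  # baseline, eliminated interval 1
        spine("s3", "W1b1", 40.0, (0, 1, 1)),  # formed, stabilized
        spine("s4", "W1b1", 44.0, (0, 1, 0)),  # formed, not stabilized
        spine("s5", "D1b1", 10.0, (1, 1, 0)),  # baseline, eliminated interval 2
        spine("s6", "D1b1", 30.0, (0, 1, 1)),  # formed, stabilized
        spine("s7", "D1b1", 33.0, (0, 1, 1)),  # formed, stabilized (clustered pair)
        spine("s8", "D1b1", 70.0, (0, 0, 1)),  # late formation (interval 2)
    ]
    return build_cohort(spines, branches, animals)


@pytest.fixture(scope="session")
def calibrated_presets():
    """WT and DUP presets calibrated against the printed group statistics.

    Session-scoped: calibration simulates large cohorts and is shared by
    every test that needs the study-condition presets.
    """
    from spineclust import synthetic

    wt, _ = synthetic.calibrate_preset(
        synthetic.wt_initial_preset(), synthetic.WT_CALIBRATION, seed=7
    )
    dup, _ = synthetic.calibrate_preset(
        synthetic.dup_initial_preset(), synthetic.DUP_CALIBRATION, seed=8
    )
    return {"WT": wt, "DUP": dup}


def nn_bruteforce(positions, query_idx, ref_idx):
    """O(n²) nearest-neighbor oracle on one branch."""
    out = []
    for i in query_idx:
        best = np.inf
        for j in ref_idx:
            if i == j:
                continue
            best = min(best, abs(positions[i] - positions[j]))
        out.append(best if np.isfinite(best) else np.nan)
    return out
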