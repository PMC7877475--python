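"""Per-animal and per-group spine dynamics: formation, stabilization and
elimination densities, baseline density, and the 4-day turnover rate.

All densities pool counts within an animal (total count across the animal's
branches divided by total analyzed length) — the animal, not the branch, is
the statistical unit throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .records import CohortTable

log = logging.getLogger(__name__)

#: per-animal metrics computed by :func:`animal_dynamics`
METRICS = (
    "formed_per_100um",
    "stabilized_per_100um",
    "elim1_per_100um",
    "elim2_per_100um",
    "elim1_fraction",
    "elim2_fraction",
    "baseline_per_um",
    "turnover_per_100um",
)


@dataclass(frozen=True)
class AnimalDynamics:
    """Spine-dynamics densities for one animal.

    Densities are per 100 μm of analyzed dendrite except ``baseline_per_um``
    (spines per μm).  ``turnover_per_100um`` is
    (formed + eliminated in interval 1) / (2 × total length) × 100, the
    4-day turnover rate.  ``elim*_fraction`` are the same eliminations as a
    fraction of baseline spines (the density is the primary metric).
    """

    animal_id: str
    total_length_um: float
    n_baseline: int
    n_formed: int
    n_stabilized: int
    n_elim1: int
    n_elim2: int
    formed_per_100um: float
    stabilized_per_100um: float
    elim1_per_100um: float
    elim2_per_100um: float
    elim1_fraction: float
    elim2_fraction: float
    baseline_per_um: float
    turnover_per_100um: float


def _animal_counts(fates: pd.DataFrame, cohort: CohortTable) -> pd.DataFrame:
    branch_to_animal = cohort.branches.set_index("branch_id")["animal_id"]
    f = fates.copy()
    f["animal_id"] = branch_to_animal.reindex(f["branch_id"]).to_numpy()
    return f


def animal_dynamics(fates: pd.DataFrame, cohort: CohortTable, animal_id: str) -> AnimalDynamics:
    """Compute the dynamics densities for one animal.

    Raises ``ValueError`` if the animal has no analyzed dendritic length.
    """
    branches = cohort.branches_of(animal_id)
    total_length = float(branches["length_um"].sum())
    if total_length <= 0:
        raise ValueError(f"animal {animal_id!r} has zero analyzed dendritic length")

    on_animal = fates["branch_id"].isin(set(branches["branch_id"]))
    f = fates[on_animal]
    n_baseline = int(f["is_baseline"].sum())
    n_formed = int(f["is_formed"].sum())
    n_stab = int(f["is_stabilized"].sum())
    n_e1 = int(f["eliminated_interval1"].sum())
    n_e2 = int(f["eliminated_interval2"].sum())

    per100 = 100.0 / total_length
    return AnimalDynamics(
        animal_id=animal_id,
        total_length_um=total_length,
        n_baseline=n_baseline,
        n_formed=n_formed,
        n_stabilized=n_stab,
        n_elim1=n_e1,
        n_elim2=n_e2,
        formed_per_100um=n_formed * per100,
        stabilized_per_100um=n_stab * per100,
        elim1_per_100um=n_e1 * per100,
        elim2_per_100um=n_e2 * per100,
        elim1_fraction=n_e1 / n_baseline if n_baseline else 0.0,
        elim2_fraction=n_e2 / n_baseline if n_baseline else 0.0,
        baseline_per_um=n_baseline / total_length,
        turnover_per_100um=(n_formed + n_e1) / (2.0 * total_length) * 100.0,
    )


def turnover_rate(fates: pd.DataFrame, cohort: CohortTable, animal_id: str) -> float:
    """4-day turnover rate: (formed + eliminated interval 1) / (2·L) × 100."""
    return animal_dynamics(fates, cohort, animal_id).turnover_per_100um


def cohort_dynamics(fates: pd.DataFrame, cohort: CohortTable) -> pd.DataFrame:
    """Per-animal dynamics table (one row per animal, plus metadata)."""
    rows = [asdict(animal_dynamics(fates, cohort, a)) for a in cohort.animals["animal_id"]]
    table = pd.DataFrame(rows)
    return table.merge(
        cohort.animals[["animal_id", "genotype", "condition"]], on="animal_id"
    )


def sem(values) -> float:
    """Standard error of the mean; 0 by convention for n = 1 (flagged)."""
    v = np.asarray(values, dtype=float)
    if v.size == 1:
        log.warning("SEM requested for a single observation; returning 0 by convention")
        return 0.0
    return float(np.std(v, ddof=1) / np.sqrt(v.size))


def group_summary(dynamics: pd.DataFrame, group_keys=("genotype",), metrics=METRICS) -> pd.DataFrame:
    """Mean ± SEM of each metric across animals, per group.

    ``dynamics`` is the output of :func:`cohort_dynamics` (or any per-animal
    table carrying the grouping columns).  Animals are the unit: the SEM is
    the between-animal SEM.  Raises on an empty table.
    """
    if len(dynamics) == 0:
        raise ValueError("no animals to summarize")
    group_keys = list(group_keys)
    rows = []
    for keys, sub in dynamics.groupby(group_keys, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_keys, keys))
        row["n_animals"] = len(sub)
        for m in metrics:
            vals = sub[m].dropna().to_numpy(float)
            row[f"{m}_mean"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"{m}_sem"] = sem(vals) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
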