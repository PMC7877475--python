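"""Nearest-neighbor spine clustering statistics.

Distances are 1-D arc-length differences along a branch; spines on
different branches are never neighbors.  A newly formed spine is
*clustered* when its nearest neighbor in the chosen reference set lies
strictly closer than the cluster-distance threshold (default 9 μm), and
*isolated* otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import sem
from .records import CohortTable

DEFAULT_THRESHOLD_UM = 9.0
DEFAULT_BIN_WIDTH_UM = 5.0
#: number of spines an animal must have formed in clusters to contribute to
#: the percent-stabilized metric (small counts make the percentage unstable)
MIN_CLUSTERED_FOR_PERCENT = 4


class SpineSet(enum.Enum):
    """Spine subsets used as nearest-neighbor query or reference sets."""

    FORMED_ALL = "formed_all"
    FORMED_STABILIZED = "formed_stabilized"
    FORMED_NONSTABILIZED = "formed_nonstabilized"
    BASELINE = "baseline"


def select_spines(fates: pd.DataFrame, selector: SpineSet) -> pd.Series:
    """Boolean mask over the fate table rows for the given spine set."""
    if selector is SpineSet.FORMED_ALL:
        return fates["is_formed"]
    if selector is SpineSet.FORMED_STABILIZED:
        return fates["is_stabilized"]
    if selector is SpineSet.FORMED_NONSTABILIZED:
        return fates["is_formed"] & ~fates["is_stabilized"]
    if selector is SpineSet.BASELINE:
        return fates["is_baseline"]
    raise ValueError(f"unknown spine set {selector!r}")


def nn_distances(
    cohort: CohortTable,
    fates: pd.DataFrame,
    query_selector: SpineSet,
    reference_selector: SpineSet,
) -> pd.DataFrame:
    """Distance from each query spine to its nearest same-branch reference.

    Returns one row per query spine with ``nn_distance_um`` = NaN when the
    reference set on that branch (minus the spine itself) is empty.  A spine
    in both sets is never its own neighbor.
    """
    pos = cohort.spines.set_index("spine_id")["position_um"]
    q = fates[select_spines(fates, query_selector)]
    r = fates[select_spines(fates, reference_selector)]

    ref_by_branch: dict[str, pd.DataFrame] = {
        b: sub for b, sub in r.groupby("branch_id")
    }
    out_ids, out_branch, out_d = [], [], []
    for branch_id, qsub in q.groupby("branch_id"):
        ref = ref_by_branch.get(branch_id)
        qpos = pos.reindex(qsub["spine_id"]).to_numpy(float)
        if ref is None:
            d = np.full(len(qsub), np.nan)
        else:
            rpos = pos.reindex(ref["spine_id"]).to_numpy(float)
            diff = np.abs(qpos[:, None] - rpos[None, :])
            # exclude self-pairs (same spine id)
            same = qsub["spine_id"].to_numpy()[:, None] == ref["spine_id"].to_numpy()[None, :]
            diff[same] = np.inf
            d = diff.min(axis=1)
            d[~np.isfinite(d)] = np.nan
        out_ids.extend(qsub["spine_id"])
        out_branch.extend([branch_id] * len(qsub))
        out_d.extend(d)
    return pd.DataFrame(
        {
            "spine_id": out_ids,
            "branch_id": out_branch,
            "nn_distance_um": out_d,
            "query_selector": query_selector.value,
            "reference_selector": reference_selector.value,
        }
    )


def distance_histogram(
    nn_table: pd.DataFrame,
    cohort: CohortTable,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    max_distance_um: float = 65.0,
) -> pd.DataFrame:
    """Per-animal binned nearest-neighbor densities (spines per 1000 μm).

    Bins are half-open ``[k·w, (k+1)·w)``; each animal's bin value is the
    count of its query spines in the bin divided by the animal's total
    analyzed length, per 1000 μm.  Distances at or beyond
    ``max_distance_um``, and spines without an eligible neighbor, are not
    binned.  Returns one row per (animal, bin).
    """
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, max_distance_um + bin_width_um / 2, bin_width_um)
    branch_to_animal = cohort.branches.set_index("branch_id")["animal_id"]
    lengths = cohort.branches.groupby("animal_id")["length_um"].sum()

    t = nn_table.dropna(subset=["nn_distance_um"]).copy()
    t["animal_id"] = branch_to_animal.reindex(t["branch_id"]).to_numpy()

    rows = []
    for animal_id in cohort.animals["animal_id"]:
        d = t.loc[t["animal_id"] == animal_id, "nn_distance_um"].to_numpy(float)
        counts, _ = np.histogram(d, bins=edges)
        dens = counts / lengths[animal_id] * 1000.0
        for k in range(len(counts)):
            rows.append(
                {
                    "animal_id": animal_id,
                    "bin_left_um": edges[k],
                    "bin_right_um": edges[k + 1],
                    "count": int(counts[k]),
                    "density_per_1000um": float(dens[k]),
                }
            )
    return pd.DataFrame(rows)


def histogram_summary(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Cross-animal mean ± SEM for each distance bin."""
    rows = []
    for (lo, hi), sub in per_animal.groupby(["bin_left_um", "bin_right_um"], sort=True):
        vals = sub["density_per_1000um"].to_numpy(float)
        rows.append(
            {
                "bin_left_um": lo,
                "bin_right_um": hi,
                "mean_per_1000um": float(np.mean(vals)),
                "sem_per_1000um": sem(vals),
                "n_animals": len(vals),
            }
        )
    return pd.DataFrame(rows)


def classify_clustered(
    nn_table: pd.DataFrame,
    threshold_um: float = DEFAULT_THRESHOLD_UM,
    inclusive: bool = False,
) -> pd.DataFrame:
    """Label each query spine clustered (NN distance < threshold) or isolated.

    The comparison is strict by default (``d < t``); spines with no eligible
    neighbor are isolated.  ``inclusive=True`` switches to ``d <= t``.
    """
    if threshold_um <= 0:
        raise ValueError("threshold must be positive")
    d = nn_table["nn_distance_um"]
    clustered = (d <= threshold_um) if inclusive else (d < threshold_um)
    out = nn_table[["spine_id", "branch_id", "reference_selector"]].copy()
    out["clustered"] = clustered.fillna(False).to_numpy(bool)
    out["threshold_um"] = threshold_um
    return out


@dataclass(frozen=True)
class SweepCurve:
    """Genotype difference of clustered stabilized density vs threshold."""

    thresholds_um: np.ndarray
    difference_per_100um: np.ndarray  # mean(DUP) - mean(WT)
    summed_sem: np.ndarray  # SEM_DUP + SEM_WT


def clustered_dynamics(
    fates: pd.DataFrame,
    labels: pd.DataFrame,
    cohort: CohortTable,
    min_clustered_for_percent: int = MIN_CLUSTERED_FOR_PERCENT,
) -> pd.DataFrame:
    """Per-animal clustered/isolated formation and stabilization metrics.

    ``labels`` must be cluster labels computed on the formed-spine query
    set.  Densities are per 100 μm.  The clustered percent-stabilized
    metric is NaN for animals that formed fewer than
    ``min_clustered_for_percent`` clustered spines; the isolated one is NaN
    only when no isolated spine formed.
    """
    clustered_ids = set(labels.loc[labels["clustered"], "spine_id"])
    branch_to_animal = cohort.branches.set_index("branch_id")["animal_id"]
    lengths = cohort.branches.groupby("animal_id")["length_um"].sum()

    f = fates[fates["is_formed"]].copy()
    f["animal_id"] = branch_to_animal.reindex(f["branch_id"]).to_numpy()
    f["clustered"] = f["spine_id"].isin(clustered_ids)

    rows = []
    for animal_id in cohort.animals["animal_id"]:
        sub = f[f["animal_id"] == animal_id]
        L = float(lengths[animal_id])
        n_cf = int(sub["clustered"].sum())
        n_if = int((~sub["clustered"]).sum())
        n_cs = int((sub["clustered"] & sub["is_stabilized"]).sum())
        n_is = int((~sub["clustered"] & sub["is_stabilized"]).sum())
        rows.append(
            {
                "animal_id": animal_id,
                "clustered_formed_per_100um": n_cf / L * 100,
                "isolated_formed_per_100um": n_if / L * 100,
                "clustered_stabilized_per_100um": n_cs / L * 100,
                "isolated_stabilized_per_100um": n_is / L * 100,
                "n_clustered_formed": n_cf,
                "n_isolated_formed": n_if,
                "percent_stabilized_clustered": (
                    100.0 * n_cs / n_cf if n_cf >= min_clustered_for_percent else np.nan
                ),
                "percent_stabilized_isolated": (
                    100.0 * n_is / n_if if n_if > 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).merge(
        cohort.animals[["animal_id", "genotype", "condition"]], on="animal_id"
    )


def threshold_sweep(
    wt_densities_by_threshold,
    dup_densities_by_threshold,
    thresholds_um,
) -> SweepCurve:
    """Between-genotype clustered-stabilized-density difference per threshold.

    Inputs are, per threshold, the per-animal clustered stabilized densities
    for each genotype.  The curve value is mean(DUP) − mean(WT); the error
    is the summed SEM of the two genotypes.
    """
    thresholds = np.asarray(thresholds_um, dtype=float)
    if len(thresholds) == 0 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing and nonempty")
    if len(wt_densities_by_threshold) != len(thresholds) or len(
        dup_densities_by_threshold
    ) != len(thresholds):
        raise ValueError("one density vector required per threshold")
    diffs, errs = [], []
    for wt, dup in zip(wt_densities_by_threshold, dup_densities_by_threshold):
        wt = np.asarray(wt, float)
        dup = np.asarray(dup, float)
        if wt.size == 0 or dup.size == 0:
            raise ValueError("empty genotype group in threshold sweep")
        diffs.append(float(np.mean(dup) - np.mean(wt)))
        errs.append(sem(dup) + sem(wt))
    return SweepCurve(thresholds, np.asarray(diffs), np.asarray(errs))


def sweep_from_cohort(
    cohort: CohortTable,
    fates: pd.DataFrame,
    thresholds_um,
    reference_selector: SpineSet = SpineSet.FORMED_ALL,
) -> SweepCurve:
    """Convenience: run the threshold sweep on a two-genotype cohort."""
    nn = nn_distances(cohort, fates, SpineSet.FORMED_ALL, reference_selector)
    genotype = cohort.animals.set_index("animal_id")["genotype"]
    wt_cols, dup_cols = [], []
    for t in np.asarray(thresholds_um, float):
        labels = classify_clustered(nn, threshold_um=t)
        cd = clustered_dynamics(fates, labels, cohort)
        gt = genotype.reindex(cd["animal_id"]).to_numpy()
        wt_cols.append(cd.loc[gt == "WT", "clustered_stabilized_per_100um"].to_numpy())
        dup_cols.append(cd.loc[gt == "DUP", "clustered_stabilized_per_100um"].to_numpy())
    return threshold_sweep(wt_cols, dup_cols, thresholds_um)
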