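"""Random-placement Monte-Carlo null model for spine locations.

The null hypothesis is that spines are located uniformly at random along
the analyzed dendrites, with no spatial interaction beyond a hard minimum
interspine spacing of 0.1 μm.  Each simulated animal is matched to a real
(or synthetic) animal's branch count, branch lengths (or their mean/SD),
baseline and formed spine counts, and stabilization rate.  Replicating the
simulation many times yields per-distance-bin 95% envelopes of the
nearest-neighbor histogram against which observed clustering is judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clustering
from .records import CohortTable, classify_fates
from .clustering import SpineSet

DEFAULT_MIN_SPACING_UM = 0.1
MIN_BRANCH_LENGTH_UM = 10.0
RETRY_CAP = 10_000


@dataclass(frozen=True)
class NullSpec:
    """Per-animal parameters of the random-placement null.

    When ``branch_lengths_um`` is provided the measured lengths are reused
    in every replicate; otherwise lengths are redrawn from a normal
    distribution truncated at 10 μm with the given mean and SD.
    ``stabilization_rate`` is the observed stabilized/formed fraction;
    under the null each formed spine stabilizes independently with this
    probability (or exactly ``round(rate·n)`` spines stabilize when
    ``fixed_count_stabilization`` is set).
    """

    animal_id: str
    n_branches: int
    branch_length_mean_um: float
    branch_length_sd_um: float
    n_baseline: int
    n_formed: int
    stabilization_rate: float
    min_spacing_um: float = DEFAULT_MIN_SPACING_UM
    branch_lengths_um: tuple = None
    fixed_count_stabilization: bool = False

    def __post_init__(self):
        if not 0 <= self.stabilization_rate <= 1:
            raise ValueError("stabilization_rate must lie in [0, 1]")
        if self.n_branches <= 0:
            raise ValueError("need at least one branch")
        if min(self.n_baseline, self.n_formed) < 0:
            raise ValueError("spine counts must be nonnegative")


class SpacingInfeasibleError(RuntimeError):
    """Rejection resampling could not satisfy the minimum spacing."""


def truncated_normal_lengths(rng, n, mean, sd, lower=MIN_BRANCH_LENGTH_UM):
    """Draw branch lengths from N(mean, sd) truncated below at ``lower``."""
    if sd <= 0:
        return np.full(n, max(mean, lower), dtype=float)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 8)
        draw = draw[draw >= lower]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def place_spines_with_spacing(rng, lengths, n_spines, min_spacing, animal_id="?"):
    """Place ``n_spines`` uniformly on the pooled branches with rejection.

    Placement is uniform over the pooled dendritic length (each branch
    weighted by its length).  Any spine closer than ``min_spacing`` to
    another spine on the same branch is redrawn until the spacing holds,
    up to a retry cap.

    Returns ``(branch_index, position_um)`` arrays.
    """
    lengths = np.asarray(lengths, float)
    cum = np.cumsum(lengths)
    total = cum[-1]
    if n_spines == 0:
        return np.empty(0, int), np.empty(0)

    u = rng.uniform(0.0, total, size=n_spines)
    redraws = 0
    while True:
        branch = np.searchsorted(cum, u, side="right")
        pos = u - (cum[branch] - lengths[branch])
        order = np.lexsort((pos, branch))
        sb, sp = branch[order], pos[order]
        close = (np.diff(sp) < min_spacing) & (np.diff(sb) == 0)
        if not close.any():
            return branch, pos
        # redraw the later spine of each offending adjacent pair
        bad = order[1:][close]
        redraws += bad.size
        if redraws > RETRY_CAP:
            raise SpacingInfeasibleError(
                f"could not satisfy min spacing {min_spacing} μm for animal "
                f"{animal_id} ({n_spines} spines on {total:.0f} μm)"
            )
        u[bad] = rng.uniform(0.0, total, size=bad.size)


def _simulate_arrays(spec: NullSpec, rng):
    """Fast core of :func:`simulate_null_animal`: plain numpy arrays."""
    if spec.branch_lengths_um is not None:
        lengths = np.asarray(spec.branch_lengths_um, float)
    else:
        lengths = truncated_normal_lengths(
            rng, spec.n_branches, spec.branch_length_mean_um, spec.branch_length_sd_um
        )
    n_total = spec.n_baseline + spec.n_formed
    branch, pos = place_spines_with_spacing(
        rng, lengths, n_total, spec.min_spacing_um, spec.animal_id
    )
    is_baseline = np.zeros(n_total, bool)
    is_baseline[: spec.n_baseline] = True
    is_formed = ~is_baseline
    is_stab = np.zeros(n_total, bool)
    if spec.n_formed:
        if spec.fixed_count_stabilization:
            k = int(round(spec.stabilization_rate * spec.n_formed))
            pick = rng.choice(spec.n_formed, size=k, replace=False)
            stab = np.zeros(spec.n_formed, bool)
            stab[pick] = True
        else:
            stab = rng.random(spec.n_formed) < spec.stabilization_rate
        is_stab[is_formed] = stab
    return lengths, branch, pos, is_baseline, is_formed, is_stab


def simulate_null_animal(spec: NullSpec, rng) -> pd.DataFrame:
    """One random-placement realization of an animal's spines.

    Returns a table with columns ``branch``, ``length_um``, ``position_um``,
    ``is_baseline``, ``is_formed``, ``is_stabilized``.
    """
    lengths, branch, pos, is_baseline, is_formed, is_stab = _simulate_arrays(spec, rng)
    return pd.DataFrame(
        {
            "branch": branch,
            "length_um": lengths[branch],
            "position_um": pos,
            "is_baseline": is_baseline,
            "is_formed": is_formed,
            "is_stabilized": is_stab,
        }
    )


def specs_from_cohort(cohort: CohortTable, fates=None, reuse_lengths: bool = True):
    """Extract one :class:`NullSpec` per animal from an observed cohort."""
    if fates is None:
        fates = classify_fates(cohort)
    branch_to_animal = cohort.branches.set_index("branch_id")["animal_id"]
    f = fates.copy()
    f["animal_id"] = branch_to_animal.reindex(f["branch_id"]).to_numpy()
    specs = []
    for animal_id in cohort.animals["animal_id"]:
        branches = cohort.branches_of(animal_id)
        sub = f[f["animal_id"] == animal_id]
        n_formed = int(sub["is_formed"].sum())
        n_stab = int(sub["is_stabilized"].sum())
        lengths = branches["length_um"].to_numpy(float)
        specs.append(
            NullSpec(
                animal_id=animal_id,
                n_branches=len(branches),
                branch_length_mean_um=float(lengths.mean()),
                branch_length_sd_um=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
                n_baseline=int(sub["is_baseline"].sum()),
                n_formed=n_formed,
                stabilization_rate=n_stab / n_formed if n_formed else 0.0,
                branch_lengths_um=tuple(lengths) if reuse_lengths else None,
            )
        )
    return specs


def nn_distances_1d(branch, pos, query_mask, ref_mask):
    """NN distance per query point, same-branch references only, self excluded.

    Array analogue of :func:`spineclust.clustering.nn_distances` for
    simulated animals; returns NaN where no eligible reference exists.
    """
    out = np.full(int(query_mask.sum()), np.nan)
    qpos_all = pos[query_mask]
    qbr_all = branch[query_mask]
    qidx_all = np.flatnonzero(query_mask)
    ridx_all = np.flatnonzero(ref_mask)
    for b in np.unique(qbr_all):
        qsel = qbr_all == b
        rsel = branch[ref_mask] == b
        if not rsel.any():
            continue
        qp = qpos_all[qsel]
        rp = pos[ref_mask][rsel]
        diff = np.abs(qp[:, None] - rp[None, :])
        diff[qidx_all[qsel][:, None] == ridx_all[rsel][None, :]] = np.inf
        d = diff.min(axis=1)
        d[~np.isfinite(d)] = np.nan
        out[qsel] = d
    return out


def _mask_for(selector: SpineSet, is_baseline, is_formed, is_stab) -> np.ndarray:
    if selector is SpineSet.FORMED_ALL:
        return is_formed
    if selector is SpineSet.FORMED_STABILIZED:
        return is_stab
    if selector is SpineSet.FORMED_NONSTABILIZED:
        return is_formed & ~is_stab
    if selector is SpineSet.BASELINE:
        return is_baseline
    raise ValueError(selector)


@dataclass
class NullEnvelope:
    """Per-bin null mean and 95% interval of the NN-distance histogram."""

    bin_edges_um: np.ndarray
    mean: np.ndarray
    lower: np.ndarray  # 2.5% quantile across replicates
    upper: np.ndarray  # 97.5% quantile
    n_replicates: int
    seed: int
    replicate_bins: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_um": self.bin_edges_um[:-1],
                "bin_right_um": self.bin_edges_um[1:],
                "null_mean": self.mean,
                "null_lower95": self.lower,
                "null_upper95": self.upper,
            }
        )


def null_envelope(
    cohort: CohortTable,
    fates=None,
    query_selector: SpineSet = SpineSet.FORMED_STABILIZED,
    reference_selector: SpineSet = SpineSet.FORMED_ALL,
    n_reps: int = 1000,
    seed: int = 0,
    bin_width_um: float = clustering.DEFAULT_BIN_WIDTH_UM,
    max_distance_um: float = 65.0,
    reuse_lengths: bool = True,
) -> NullEnvelope:
    """95% envelope of the per-bin cross-animal mean NN density under the null.

    For each replicate every animal is re-simulated under its matched
    :class:`NullSpec`; per-animal histograms (spines per 1000 μm per bin)
    are averaged across animals exactly as for observed data, and the
    envelope is the per-bin 2.5/97.5 percentile across replicates.
    Deterministic for a fixed ``seed``.
    """
    specs = specs_from_cohort(cohort, fates, reuse_lengths=reuse_lengths)
    return envelope_from_specs(
        specs,
        query_selector,
        reference_selector,
        n_reps=n_reps,
        seed=seed,
        bin_width_um=bin_width_um,
        max_distance_um=max_distance_um,
    )


def envelope_from_specs(
    specs,
    query_selector: SpineSet = SpineSet.FORMED_STABILIZED,
    reference_selector: SpineSet = SpineSet.FORMED_ALL,
    n_reps: int = 1000,
    seed: int = 0,
    bin_width_um: float = clustering.DEFAULT_BIN_WIDTH_UM,
    max_distance_um: float = 65.0,
) -> NullEnvelope:
    """As :func:`null_envelope`, from explicit per-animal specs."""
    if n_reps < 100:
        warnings.warn("fewer than 100 replicates: envelope will be unstable")
    edges = np.arange(0.0, max_distance_um + bin_width_um / 2, bin_width_um)
    child_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    reps = np.empty((n_reps, len(edges) - 1))
    for r in range(n_reps):
        rng = np.random.default_rng(child_seeds[r])
        acc = np.zeros(len(edges) - 1)
        for spec in specs:
            lengths, branch, pos, is_b, is_f, is_s = _simulate_arrays(spec, rng)
            qm = _mask_for(query_selector, is_b, is_f, is_s)
            rm = _mask_for(reference_selector, is_b, is_f, is_s)
            d = nn_distances_1d(branch, pos, qm, rm)
            d = d[np.isfinite(d)]
            acc += np.histogram(d, bins=edges)[0] / lengths.sum() * 1000.0
        reps[r] = acc / len(specs)
    return NullEnvelope(
        bin_edges_um=edges,
        mean=reps.mean(axis=0),
        lower=np.quantile(reps, 0.025, axis=0),
        upper=np.quantile(reps, 0.975, axis=0),
        n_replicates=n_reps,
        seed=seed,
        replicate_bins=reps,
    )


def empirical_pvalue(observed_stat: float, null_stats) -> float:
    """Upper-tail Monte-Carlo p-value with the add-one rule.

    ``p = (1 + #{null ≥ observed}) / (1 + n)`` — never exactly zero.
    """
    null_stats = np.asarray(null_stats, float)
    if null_stats.size == 0:
        raise ValueError("empty null sample")
    return float((1 + np.sum(null_stats >= observed_stat)) / (1 + null_stats.size))
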