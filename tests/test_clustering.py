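import numpy as np
import pandas as pd
import pytest

from spineclust.clustering import (
    SpineSet,
    classify_clustered,
    clustered_dynamics,
    distance_histogram,
    nn_distances,
    sweep_from_cohort,
    threshold_sweep,
)
from spineclust.records import classify_fates

from conftest import build_cohort, nn_bruteforce, spine


def formed_cohort(positions, lengths=None, stabilized=None):
    """One animal; formed spines at given positions, one list per branch."""
    lengths = lengths or [100.0] * len(positions)
    branches = [
        {"branch_id": f"B{k}", "animal_id": "A1", "length_um": lengths[k]}
        for k in range(len(positions))
    ]
    spines = []
    for k, branch_positions in enumerate(positions):
        for i, p in enumerate(branch_positions):
            stab = True if stabilized is None else stabilized[k][i]
            spines.append(spine(f"B{k}s{i}", f"B{k}", p, (0, 1, 1 if stab else 0)))
    return build_cohort(
        spines, branches, [{"animal_id": "A1", "genotype": "WT", "condition": "trained"}]
    )


class TestNNDistances:
    def test_three_spines_on_a_branch(self):
        cohort = formed_cohort([[0.0, 4.0, 20.0]])
        fates = classify_fates(cohort)
        nn = nn_distances(cohort, fates, SpineSet.FORMED_ALL, SpineSet.FORMED_ALL)
        got = nn.set_index("spine_id")["nn_distance_um"]
        assert got["B0s0"] == 4.0 and got["B0s1"] == 4.0 and got["B0s2"] == 16.0

    def test_lone_spine_has_no_neighbor(self):
        cohort = formed_cohort([[10.0]])
        nn = nn_distances(
            cohort, classify_fates(cohort), SpineSet.FORMED_ALL, SpineSet.FORMED_ALL
        )
        assert np.isnan(nn["nn_distance_um"]).all()

    def test_branches_are_never_neighbors(self):
        cohort = formed_cohort([[10.0], [10.5]])
        nn = nn_distances(
            cohort, classify_fates(cohort), SpineSet.FORMED_ALL, SpineSet.FORMED_ALL
        )
        assert np.isnan(nn["nn_distance_um"]).all()

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = rng.integers(2, 21)
            pos = np.round(rng.uniform(0, 80, size=n), 3)
            while len(set(pos)) < n:
                pos = np.round(rng.uniform(0, 80, size=n), 3)
            stab = rng.random(n) < 0.5
            cohort = formed_cohort([list(pos)], stabilized=[list(stab)])
            fates = classify_fates(cohort)
            nn = nn_distances(cohort, fates, SpineSet.FORMED_STABILIZED, SpineSet.FORMED_ALL)
            expected = nn_bruteforce(pos, np.flatnonzero(stab), range(n))
            got = nn.set_index("spine_id")["nn_distance_um"]
            for i, e in zip(np.flatnonzero(stab), expected):
                g = got[f"B0s{i}"]
                assert (np.isnan(e) and np.isnan(g)) or g == pytest.approx(e)


class TestHistogram:
    def test_bin_densities_per_1000um(self):
        cohort = formed_cohort([[0.0, 1.0, 500.0, 506.0]], lengths=[1000.0])
        fates = classify_fates(cohort)
        nn = nn_distances(cohort, fates, SpineSet.FORMED_ALL, SpineSet.FORMED_ALL)
        hist = distance_histogram(nn, cohort, bin_width_um=5)
        by_bin = hist.set_index("bin_left_um")["density_per_1000um"]
        assert by_bin[0.0] == pytest.approx(2.0)  # the 1-μm pair
        assert by_bin[5.0] == pytest.approx(2.0)  # the 6-μm pair

    def test_empty_distance_table_gives_zero_histogram(self):
        cohort = formed_cohort([[10.0]])
        nn = nn_distances(
            cohort, classify_fates(cohort), SpineSet.FORMED_ALL, SpineSet.FORMED_ALL
        )
        hist = distance_histogram(nn, cohort)
        assert (hist["density_per_1000um"] == 0).all()

    def test_bin_counts_sum_to_finite_distances(self):
        rng = np.random.default_rng(9)
        pos = np.round(rng.uniform(0, 60, size=15), 2)
        cohort = formed_cohort([list(set(pos))], lengths=[100.0])
        fates = classify_fates(cohort)
        nn = nn_distances(cohort, fates, SpineSet.FORMED_ALL, SpineSet.FORMED_ALL)
        hist = distance_histogram(nn, cohort, bin_width_um=5, max_distance_um=100)
        assert hist["count"].sum() == nn["nn_distance_um"].notna().sum()


class TestClusterClassification:
    def test_strict_threshold_boundary(self):
        nn = pd.DataFrame(
            {
                "spine_id": ["a", "b", "c"],
                "branch_id": ["B"] * 3,
                "nn_distance_um": [8.9, 9.0, np.nan],
                "reference_selector": "formed_all",
            }
        )
        labels = classify_clustered(nn, threshold_um=9.0)
        got = labels.set_index("spine_id")["clustered"]
        assert bool(got["a"]) and not got["b"] and not got["c"]

    def test_clustered_set_grows_with_threshold(self):
        rng = np.random.default_rng(2)
        nn = pd.DataFrame(
            {
                "spine_id": [str(i) for i in range(50)],
                "branch_id": ["B"] * 50,
                "nn_distance_um": rng.uniform(0, 20, 50),
                "reference_selector": "formed_all",
            }
        )
        small = set(classify_clustered(nn, 5.0).query("clustered")["spine_id"])
        large = set(classify_clustered(nn, 12.0).query("clustered")["spine_id"])
        assert small <= large

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_clustered(pd.DataFrame({"nn_distance_um": []}), threshold_um=0)


class TestClusteredDynamics:
    def test_fully_stabilized_pair_is_100_percent(self):
        cohort = formed_cohort([[10.0, 12.0, 40.0, 43.0]])
        fates = classify_fates(cohort)
        nn = nn_distances(cohort, fates, SpineSet.FORMED_ALL, SpineSet.FORMED_ALL)
        labels = classify_clustered(nn, 9.0)
        cd = clustered_dynamics(fates, labels, cohort).iloc[0]
        assert cd["n_clustered_formed"] == 4
        assert cd["percent_stabilized_clustered"] == pytest.approx(100.0)

    def test_animals_below_four_clustered_excluded_from_percentage(self):
        cohort = formed_cohort([[10.0, 12.0, 14.0, 60.0]])  # 3 clustered + 1 isolated
        fates = classify_fates(cohort)
        nn = nn_distances(cohort, fates, SpineSet.FORMED_ALL, SpineSet.FORMED_ALL)
        labels = classify_clustered(nn, 9.0)
        cd = clustered_dynamics(fates, labels, cohort).iloc[0]
        assert cd["n_clustered_formed"] == 3
        assert np.isnan(cd["percent_stabilized_clustered"])
        # densities are still reported for excluded animals
        assert cd["clustered_formed_per_100um"] == pytest.approx(3.0)


class TestThresholdSweep:
    def test_identical_groups_give_zero_difference(self):
        thresholds = [3.0, 6.0, 9.0]
        dens = [[1.0, 2.0], [1.5, 2.5], [2.0, 3.0]]
        curve = threshold_sweep(dens, dens, thresholds)
        assert np.allclose(curve.difference_per_100um, 0.0)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            threshold_sweep([[1.0]], [[1.0]], [9.0, 5.0])

    def test_clustered_density_nondecreasing_in_threshold(self, calibrated_presets):
        from spineclust import synthetic
        from spineclust.records import combine_cohorts

        wt, _ = synthetic.generate_cohort(calibrated_presets["WT"], seed=31)
        dup, _ = synthetic.generate_cohort(calibrated_presets["DUP"], seed=32)
        cohort = combine_cohorts(wt, dup)
        fates = classify_fates(cohort)
        thresholds = np.arange(2.0, 16.0, 2.0)
        per_group = {}
        for g, sub_ids in cohort.animals.groupby("genotype")["animal_id"]:
            sub = cohort.subset_animals(sub_ids)
            sub_fates = classify_fates(sub)
            means = []
            for t in thresholds:
                nn = nn_distances(sub, sub_fates, SpineSet.FORMED_ALL, SpineSet.FORMED_ALL)
                labels = classify_clustered(nn, t)
                cd = clustered_dynamics(sub_fates, labels, sub)
                means.append(cd["clustered_stabilized_per_100um"].mean())
            per_group[g] = means
            assert np.all(np.diff(means) >= -1e-12)
        curve = sweep_from_cohort(cohort, fates, thresholds)
        expected_diff = np.array(per_group["DUP"]) - np.array(per_group["WT"])
        assert np.allclose(curve.difference_per_100um, expected_diff)
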