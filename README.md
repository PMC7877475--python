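# spineclust

Quantitative analysis of longitudinal dendritic-spine dynamics and
nearest-neighbor spine clustering, built for three-session *in vivo*
two-photon imaging studies of cortical pyramidal neurons — in particular
the comparison of wild-type (WT) and MECP2-duplication (DUP) mice, a
syndromic-autism model in which newly formed spines are excessively
stabilized in clusters along the dendrite.

## What it computes

Spine annotations are three delimited tables (animals, branches, spines):
each spine has an arc-length position on its terminal branch and a boolean
presence triple over imaging days D1 / D5 / D9. From these the package
derives:

* **Spine fates** — *baseline* (present at D1), *formed* (absent D1,
  present D5), *stabilized* (formed and still present at D9),
  *eliminated* in interval 1 (D1→D5) or 2 (D5→D9).
* **Per-animal dynamics** — formation, stabilization and elimination
  densities per 100 μm of analyzed dendrite, baseline density per μm, and
  the 4-day turnover rate
  (*formed* + *eliminated*) / (2 × total dendritic length).
* **Clustering statistics** — 1-D nearest-neighbor distances between
  configurable spine sets on the same branch, 5-μm-binned histograms
  (spines per 1000 μm), clustered/isolated classification at a cluster
  distance threshold (default 9 μm, strict `d < t`), and the
  threshold-sweep curve used to choose that threshold.
* **Random-placement null model** — spines placed uniformly on matched
  branches with a 0.1 μm minimum spacing, replicated (default 1000×) to
  give per-bin 95% envelopes of the nearest-neighbor histogram and
  Monte-Carlo p-values.
* **Inferential statistics** — Mann–Whitney U, Fisher exact, two-way
  (genotype × training) ANOVA with Tukey HSD, Pearson correlation, and
  BCa bootstrap 95% intervals for group mean differences (5000 resamples).
* **Synthetic cohorts** — because the study's raw annotations were not
  deposited, a generative model with a clustered-pair formation mechanism
  stands in for the data; `calibrate_preset` tunes it until the pipeline's
  own measurements reproduce the published group statistics.

## Worked example

```python
from spineclust import (
    synthetic, classify_fates, cohort_dynamics, group_summary,
    nn_distances, distance_histogram, SpineSet, null_envelope,
)
from spineclust.records import combine_cohorts

wt, _ = synthetic.calibrate_preset(
    synthetic.initial_preset("WT"), synthetic.calibration_table("WT"), seed=7)
dup, _ = synthetic.calibrate_preset(
    synthetic.initial_preset("DUP"), synthetic.calibration_table("DUP"), seed=8)
cohort = combine_cohorts(
    synthetic.generate_cohort(wt, seed=1)[0],
    synthetic.generate_cohort(dup, seed=1)[0])

fates = classify_fates(cohort)
summary = group_summary(cohort_dynamics(fates, cohort))
print(summary[["genotype", "formed_per_100um_mean", "formed_per_100um_sem",
               "stabilized_per_100um_mean", "stabilized_per_100um_sem"]])
```

prints (one simulated cohort pair, seed 1):

```
  genotype  formed_per_100um_mean  formed_per_100um_sem  stabilized_per_100um_mean  stabilized_per_100um_sem
0      DUP               4.452086              0.228431                   1.749521                  0.142645
1       WT               2.758695              0.196550                   0.856160                  0.101681
```

— in this cohort DUP animals form ~4.5 and stabilize ~1.7 spines per
100 μm against ~2.8 and ~0.9 in WT (single-cohort values scatter around
the calibrated means of 4.1/1.5 and 2.8/0.8), the roughly twofold
stabilization excess the
clustering analysis then localizes to spines with a newly formed
neighbor within a few micrometers:

```python
nn = nn_distances(cohort, fates, SpineSet.FORMED_STABILIZED, SpineSet.FORMED_ALL)
hist = distance_histogram(nn, cohort)          # per-animal, per-5-μm bin
env = null_envelope(cohort, fates, n_reps=1000, seed=2)  # random-placement 95% band
```

The observed [0,5) bin for DUP animals sits far above the null envelope;
WT does not.

The same stages are exposed on the command line:

```bash
spineclust simulate --preset DUP --calibrate --seed 1 --out dup_cohort/
spineclust dynamics --cohort dup_cohort/ --out dynamics.csv
spineclust cluster  --cohort dup_cohort/ --threshold 9 --out cluster_out/
spineclust null     --cohort dup_cohort/ --reps 1000 --seed 2 --out envelope.csv
spineclust run      --config run.yaml
```

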