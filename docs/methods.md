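# Methods

## Data model and fate classification

A cohort consists of animals (genotype WT or DUP, trained or untrained),
terminal dendritic branches (analyzed length in μm), and spines (arc-length
position from the proximal end of the branch, presence at imaging days
D1/D5/D9). Positions are real-valued, 0-based arc length; occluded
sub-segments are not represented explicitly — `length_um` is the analyzed
length, and all densities are per analyzed length. A spine, once absent, is
never matched again under the same identifier, so valid presence patterns
are exactly the contiguous runs; `(present, absent, present)` is rejected at
validation.

Fates follow mechanically from the pattern: baseline ⇔ present at D1;
formed ⇔ absent at D1 and present at D5; stabilized ⇔ formed and present at
D9; eliminated in interval 1 ⇔ baseline and absent at D5; in interval 2 ⇔
baseline, present at D5, absent at D9. A spine first seen at D9 is a second-
interval formation (`late_formed`) and is excluded from every formation and
stabilization metric, because the formed cohort is defined at D5; for
cohorts without late formations every spine is exactly one of
baseline/formed. Duplicate positions on a branch are rejected rather than
jittered — the minimum credible interspine distance is 0.1 μm, which the
synthetic generator and null model both enforce.

## Dynamics metrics

All densities pool counts within an animal (total count / total analyzed
length); the animal is the statistical unit everywhere, and group summaries
report the between-animal mean ± SEM (SEM of a single animal is defined as
0 and flagged). The turnover rate over the first 4-day interval is
(formed + eliminated₁) / (2 × total length), reported per 100 μm. Because
no numbers are printed for the elimination panels, eliminations are
exported both as densities per 100 μm (primary) and as fractions of
baseline spines.

## Nearest-neighbor clustering

Distances are 1-D arc-length differences between spines on the *same*
branch; branches are independent. Query and reference sets are
configurable (all formed, formed-stabilized, formed-non-stabilized,
baseline) because different analyses use different pairs: the stabilized-
vs-all-formed histogram, and the formed-vs-formed classification behind the
clustered/isolated split. A spine is never its own neighbor; a query with
no eligible reference on its branch has an undefined (NaN) distance and is
classified isolated.

Histogram bins are half-open `[k·w, (k+1)·w)` with `w = 5 μm` by default;
per-animal bin values are counts divided by the animal's total analyzed
length, per 1000 μm, then averaged across animals. The clustered/isolated
rule is strict (`d < 9 μm` by default, configurable and exposed as an
inclusive-threshold flag) — the threshold itself is taken as configuration,
chosen where the between-genotype difference in clustered stabilized
density plateaus in the threshold sweep; the sweep reports
mean(DUP) − mean(WT) with the summed SEM of the two genotypes as its error
bar. Animals that formed fewer than four clustered spines are excluded from
the percent-stabilized-among-clustered metric only (the percentage is
unstable at small counts); their densities still count.

## Random-placement null model

The null hypothesis is complete spatial randomness in 1-D: for each animal,
its branch count, branch lengths, baseline and formed spine counts, and
observed stabilization rate are held fixed, and positions are redrawn
uniformly over the pooled branches (branch picked proportional to length)
subject to a hard 0.1 μm minimum spacing enforced by rejection resampling
(resampling is capped at 10⁴ redraws, then an error names the animal;
the cap is a numerical guard, not a model feature). When measured branch
lengths are available they are reused in every replicate; otherwise lengths
are drawn from a normal distribution with the matched mean and SD,
truncated below at 10 μm — the minimal assumption honoring the two stated
moments (a lognormal would also fit; truncated normal was chosen for
symmetry with the generator). Stabilization under the null is i.i.d.
Bernoulli at the animal's observed rate by default; a fixed-count variant
(exactly `round(rate·n)` stabilized) is available by flag.

Each replicate recomputes per-animal histograms exactly as for observed
data and averages across animals; the envelope is the per-bin 2.5/97.5
percentile over replicates (default 1000; fewer than 100 warns). The
Monte-Carlo p-value is upper-tail with the add-one rule,
p = (1 + #{null ≥ observed}) / (1 + n), so it is never zero. Validation:
with the spacing taken to zero the simulator's nearest-neighbor CDF matches
the homogeneous-Poisson closed form 1 − e^(−2λd) to within ±0.01 at 2·10⁴
points, and for data generated under the null the observed first-bin
statistic falls inside its own 95% envelope in ≈95% of trials.

## Synthetic cohort generator

The generator emulates the study's two-genotype cohort: 16 WT animals with
134 branches and 14 DUP animals with 109 branches (distributed as evenly as
possible), branch lengths truncated-normal (median 78/80 μm, SD 36/34 μm,
floor 10 μm), baseline spines Poisson-placed at ≈0.2 (WT) / 0.23 (DUP)
spines per μm, and baseline eliminations drawn per spine (defaults WT
10%/7%, DUP 13%/9% for the two intervals — free parameters chosen to give
mutants a higher turnover rate and a non-significant elimination trend,
since no elimination numbers are printed).

Formed spines arise by a two-component mechanism: with probability
`pi_cluster` a spine belongs to a generated *pair* (anchor uniform, partner
at a random spacing below the 9 μm threshold, direction random, re-drawn if
it would leave the branch or violate spacing; a partner that cannot be
placed degrades the pair to a singleton, logged); otherwise it is a uniform
singleton. Pairs are the minimal clustered-formation mechanism (clusters
are described as pairs or triplets; a triplet extension would hang off the
same machinery). Pair spacing is a two-band mixture — uniform on
(0.5, 5) μm with weight `pair_short_weight`, else uniform on (5, 8.5) μm —
so that the model can allocate clustered stabilization between the first
histogram bin and the 5–9 μm band independently. Pair members stabilize
with probability `s_clustered`, singletons with `s_isolated`. Between-
animal variability arises from finite sampling only (no random effects), so
synthetic between-animal SEMs can understate the real ones; calibration and
acceptance therefore compare means, not SEMs.

For trained animals a rotarod mean time is generated as a linear function
of the animal's generated-pair stabilized density plus Gaussian noise
(defaults 60 s + 30 s·(spines/100 μm), σ = 15 s), giving the positive
performance–clustering correlation used to exercise the Pearson test.

### Calibration

`calibrate_preset` tunes (`lambda_form`, `baseline_density`, `pi_cluster`,
`s_clustered`, `s_isolated`, `pair_short_weight`) until the pipeline's own
measurements on a large merged cohort (640 animals at the preset's
branches-per-animal ratio) match the five published group statistics —
formation, stabilization and baseline densities, the [0,5) μm
stabilized-neighbor bin, and the percent of clustered spines stabilizing —
each within one printed SEM (the loop's internal stopping rule is stricter,
0.35 SEM, to leave headroom for evaluation noise). A sixth condition, not
an audited target, sets the isolated stabilized density equal in the two
genotypes (0.45 spines/100 μm): no number is printed for it, but isolated
stabilization is reported as similar between genotypes, and the condition
pins down the otherwise-free split of clustered stabilization across the
[0,5) and [5,9) bands.

Updates are method-of-moments: rates move multiplicatively toward their
targets; the mixture parameters are re-solved each iteration from the
moment equations using incidental-clustering probabilities (the chance a
*singleton* acquires a formed neighbor within 5 or 9 μm, and the same for
pair members) measured from the generator's ground-truth labels. Because
those moment equations are approximate — edge effects, the per-animal ratio
estimator, the <4-clustered exclusion — the solve targets carry a residual
correction: after the first applied solve, each iteration shifts its
pseudo-targets by the remaining target-minus-measured error, making the
true target the loop's fixed point. A preset already within tolerance is
returned unchanged. Non-convergence after 10 iterations raises, carrying
the audit table.

## Inferential statistics

Mann–Whitney U is exact (full enumeration) for combined samples of ≤12
without ties and uses the tie-corrected normal approximation otherwise;
all-identical pooled values return p = 1 with a warning. Fisher's exact
test is two-sided by summation of hypergeometric probabilities; the sample
odds ratio is the headline statistic with the conditional MLE alongside.
The two-way genotype × training ANOVA uses Type III sums of squares with
sum-to-zero contrasts (Type II by flag); an empty cell drops the
interaction with a warning; Tukey HSD runs over the four cell means.
Pearson's r uses the t transform with n − 2 df. These are thin wrappers
over scipy/statsmodels; the test suite checks them against independent
enumeration and least-squares-projection oracles.

The BCa bootstrap interval for a difference of group means is implemented
directly (5000 resamples by default, groups resampled independently): bias
correction z₀ from the fraction of bootstrap estimates below the point
estimate, acceleration from the jackknife skewness of the leave-one-out
differences over both samples. Degenerate zero-variance inputs collapse
the interval to the point estimate with a warning. Coverage is verified by
simulation (~95% for normal samples at n = 14).

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; replicate and per-stage
streams are spawned from a master `SeedSequence`, so envelopes, generated
cohorts, calibration and bootstrap intervals are bit-reproducible. The
shipped verification uses problem sizes chosen to keep the full suite
inexpensive on one CPU: 20 replicate cohorts per genotype for the printed-
statistic reproduction, 640-animal calibration evaluations, 500 × 200-
replicate envelope-coverage trials on a 5-animal null cohort, and 100
cohort pairs for the clustered-vs-isolated contrast.

## Known limitations

* The generator has no within-animal branch heterogeneity or between-animal
  rate variability; real SEMs are larger than synthetic ones.
* Elimination fractions and the rotarod model are qualitative stand-ins —
  no quantitative targets exist for them.
* Distances are arc-length along the branch; if the original measurements
  were projected straight-line distances, histograms would shift slightly
  at long distances (nearest neighbors are barely affected).
* The null model places spines independently of baseline spine positions;
  nulls conditioning on baseline positions, inhomogeneous placement, and
  cross-branch clustering are out of scope.
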