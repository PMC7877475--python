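"""Inferential statistics for group comparisons of spine metrics.

Wraps the standard tests used for between-genotype comparisons —
Mann–Whitney U, Fisher exact, two-way (genotype × training) ANOVA with
Tukey-corrected pairwise comparisons, Pearson correlation — and implements
the bias-corrected-and-accelerated (BCa) bootstrap interval for a
difference of group means (5000 resamples by default), the estimation
statistic used alongside the p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_N_BOOT = 5000


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: tuple = None
    exact: bool = False
    direction: int = 0  # sign of (first group - second group) effect
    extra: dict = None


@dataclass(frozen=True)
class EstimationResult:
    """Difference of group means with a BCa bootstrap 95% interval."""

    difference: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration for combined samples of at most 12 observations
    without ties; normal approximation with tie correction (and continuity
    correction) otherwise.  Identical pooled values give p = 1 with a
    warning rather than an undefined statistic.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; p set to 1")
        return TestResult("mann_whitney_U", float(x.size * y.size / 2), 1.0, exact=True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        "mann_whitney_U",
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        exact=(method == "exact"),
        direction=int(np.sign(np.mean(x) - np.mean(y))),
    )


def fisher_exact(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the 2×2 table [[a, b], [c, d]].

    p sums hypergeometric probabilities of tables no more likely than the
    observed one.  The sample odds ratio ad/bc is reported as the
    statistic; the conditional MLE odds ratio is in ``extra``.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any() or table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("cells must be nonnegative with positive margins")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    sample_or = np.inf if b * c == 0 else (a * d) / (b * c)
    cond_or = float(sps.contingency.odds_ratio(table, kind="conditional").statistic)
    return TestResult(
        "fisher_exact_odds_ratio",
        float(sample_or),
        float(min(p, 1.0)),
        exact=True,
        direction=int(np.sign(a * d - b * c)),
        extra={"conditional_odds_ratio": cond_or},
    )


def two_way_anova(values, factor_genotype, factor_training, typ: int = 3):
    """Two-way ANOVA on an (un)balanced genotype × training layout.

    Type III sums of squares with sum-to-zero contrasts by default
    (``typ=2`` switches to Type II).  Returns a dict of
    :class:`TestResult` per effect plus a Tukey HSD table over the four
    cell means.  An empty cell drops the interaction with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(
        {
            "y": np.asarray(values, float),
            "genotype": np.asarray(factor_genotype, dtype=object),
            "training": np.asarray(factor_training, dtype=object),
        }
    )
    for fac in ("genotype", "training"):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac} needs at least two levels")
    cells = df.groupby(["genotype", "training"]).size()
    full_cells = df["genotype"].nunique() * df["training"].nunique()
    has_all_cells = len(cells) == full_cells
    if not has_all_cells:
        warnings.warn("empty cell: interaction term dropped")
        formula = "y ~ C(genotype, Sum) + C(training, Sum)"
    else:
        formula = "y ~ C(genotype, Sum) * C(training, Sum)"
    model = smf.ols(formula, data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    tab = sm.stats.anova_lm(model, typ=typ)

    def _row(label, key):
        if key not in tab.index:
            return None
        r = tab.loc[key]
        return TestResult(
            f"anova_F_{label}",
            float(r["F"]),
            float(min(r["PR(>F)"], 1.0)),
            df=(int(r["df"]), int(model.df_resid)),
        )

    results = {
        "genotype": _row("genotype", "C(genotype, Sum)"),
        "training": _row("training", "C(training, Sum)"),
        "interaction": _row(
            "interaction", "C(genotype, Sum):C(training, Sum)"
        ),
    }
    cell_label = df["genotype"].astype(str) + "/" + df["training"].astype(str)
    tukey = None
    if cell_label.nunique() >= 2 and all(cell_label.value_counts() >= 2):
        hsd = pairwise_tukeyhsd(df["y"].to_numpy(), cell_label.to_numpy())
        tukey = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    return results, tukey


def pearson_test(x, y) -> TestResult:
    """Pearson correlation with two-sided p from the t transform (n−2 df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return TestResult(
        "pearson_r",
        r,
        float(min(res.pvalue, 1.0)),
        df=(x.size - 2,),
        direction=int(np.sign(r)),
        extra={"r2": r * r},
    )


def _bca_interval(boot, theta_hat, jack, alpha=0.05):
    """BCa endpoints from a bootstrap distribution and jackknife values."""
    boot = np.asarray(boot, float)
    if np.allclose(boot, boot[0]) or np.allclose(jack, np.mean(jack)):
        return theta_hat, theta_hat
    # bias correction: normal quantile of the sub-estimate fraction
    frac = np.clip(np.mean(boot < theta_hat), 1e-9, 1 - 1e-9)
    z0 = sps.norm.ppf(frac)
    # acceleration from jackknife skewness
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    z = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi)


def bca_bootstrap_diff(x, y, n_boot: int = DEFAULT_N_BOOT, seed: int = 0) -> EstimationResult:
    """BCa 95% bootstrap interval for mean(x) − mean(y).

    Resamples each group independently; the acceleration constant comes
    from the leave-one-out jackknife of the difference over both samples.
    Deterministic for a fixed seed.  Zero-variance samples collapse the
    interval to the point estimate with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two observations")
    theta = float(np.mean(x) - np.mean(y))
    if np.std(x) == 0 and np.std(y) == 0:
        warnings.warn("degenerate zero-variance samples; interval collapses")
        return EstimationResult(theta, theta, theta, n_boot, seed)
    rng = np.random.default_rng(seed)
    bx = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    by = rng.choice(y, size=(n_boot, y.size), replace=True).mean(axis=1)
    boot = bx - by
    # jackknife over the concatenated samples
    jack = np.empty(x.size + y.size)
    sx, sy = x.sum(), y.sum()
    for i in range(x.size):
        jack[i] = (sx - x[i]) / (x.size - 1) - np.mean(y)
    for j in range(y.size):
        jack[x.size + j] = np.mean(x) - (sy - y[j]) / (y.size - 1)
    lo, hi = _bca_interval(boot, theta, jack)
    return EstimationResult(theta, lo, hi, n_boot, seed)


def genotype_fisher_table(fates, labels, cohort, among: str = "stabilized"):
    """2×2 genotype × {clustered, isolated} counts for the Fisher test.

    ``among='stabilized'`` counts stabilized spines split by cluster label
    (the clustering contrast); ``among='formed'`` counts all formed spines.
    Returns ((a, b), (c, d)) ordered (DUP, WT) × (clustered, isolated).
    """
    branch_to_animal = cohort.branches.set_index("branch_id")["animal_id"]
    genotype = cohort.animals.set_index("animal_id")["genotype"]
    clustered_ids = set(labels.loc[labels["clustered"], "spine_id"])
    mask = fates["is_stabilized"] if among == "stabilized" else fates["is_formed"]
    f = fates[mask].copy()
    f["genotype"] = genotype.reindex(
        branch_to_animal.reindex(f["branch_id"]).to_numpy()
    ).to_numpy()
    f["clustered"] = f["spine_id"].isin(clustered_ids)
    a = int(((f["genotype"] == "DUP") & f["clustered"]).sum())
    b = int(((f["genotype"] == "DUP") & ~f["clustered"]).sum())
    c = int(((f["genotype"] == "WT") & f["clustered"]).sum())
    d = int(((f["genotype"] == "WT") & ~f["clustered"]).sum())
    return (a, b), (c, d)
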