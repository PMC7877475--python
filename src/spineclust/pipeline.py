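"""End-to-end orchestration: simulate/load → fates → dynamics → clustering →
null envelope → inferential statistics, with a machine-readable manifest.

Every stage draws its randomness from an independent stream spawned from
the single master seed, so a run is reproducible bit-for-bit from its
manifest.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clustering, dynamics, nullmodel, stats, synthetic
from .clustering import SpineSet
from .records import CohortTable, classify_fates, combine_cohorts, read_cohort_dir, write_cohort


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``cohort_dir`` (a directory with spines/branches/animals tables)
    or ``presets`` (genotype preset names, e.g. ``["WT", "DUP"]``, cohorts
    simulated and merged) must be given.
    """

    out_dir: str
    cohort_dir: str = None
    presets: list = None
    calibrate: bool = True
    threshold_um: float = clustering.DEFAULT_THRESHOLD_UM
    bin_width_um: float = clustering.DEFAULT_BIN_WIDTH_UM
    max_distance_um: float = 65.0
    reference_selector: str = "formed_all"
    null_reps: int = 1000
    n_boot: int = stats.DEFAULT_N_BOOT
    sweep_thresholds_um: tuple = tuple(float(t) for t in range(2, 21, 1))
    seed: int = 0

    def validate(self) -> None:
        if self.cohort_dir is None and not self.presets:
            raise ValueError("config needs either cohort_dir or presets")
        if self.threshold_um <= 0:
            raise ValueError("threshold_um must be positive")
        if self.bin_width_um <= 0:
            raise ValueError("bin_width_um must be positive")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a nonnegative integer")
        SpineSet(self.reference_selector)  # raises on unknown value

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _stage_seeds(master_seed: int, names) -> dict:
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def _obtain_cohort(config: RunConfig, seeds: dict) -> CohortTable:
    if config.cohort_dir is not None:
        return read_cohort_dir(config.cohort_dir)
    cohorts = []
    for i, name in enumerate(config.presets):
        preset = synthetic.initial_preset(name)
        if config.calibrate:
            preset, _ = synthetic.calibrate_preset(
                preset, synthetic.calibration_table(name), seed=seeds["calibrate"] + i
            )
        cohort, _ = synthetic.generate_cohort(preset, seed=seeds["simulate"] + i)
        cohorts.append(cohort)
    return combine_cohorts(*cohorts)


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle to ``out_dir``.

    Returns a dict of the output paths.  On any stage failure, partial
    outputs are removed before the error propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["calibrate", "simulate", "null", "bootstrap"])
    ref = SpineSet(config.reference_selector)
    written = {}
    try:
        cohort = _obtain_cohort(config, seeds)
        written.update(write_cohort(cohort, out / "cohort"))
        fates = classify_fates(cohort)

        dyn = dynamics.cohort_dynamics(fates, cohort)
        dyn.to_csv(out / "animal_dynamics.csv", index=False)
        summary = dynamics.group_summary(dyn)
        summary.to_csv(out / "group_summary.csv", index=False)

        nn_stab = clustering.nn_distances(cohort, fates, SpineSet.FORMED_STABILIZED, ref)
        hist = clustering.distance_histogram(
            nn_stab, cohort, config.bin_width_um, config.max_distance_um
        )
        hist.to_csv(out / "nn_histogram_per_animal.csv", index=False)
        clustering.histogram_summary(hist).to_csv(out / "nn_histogram_summary.csv", index=False)

        nn_formed = clustering.nn_distances(cohort, fates, SpineSet.FORMED_ALL, ref)
        labels = clustering.classify_clustered(nn_formed, config.threshold_um)
        labels.to_csv(out / "cluster_labels.csv", index=False)
        cd = clustering.clustered_dynamics(fates, labels, cohort)
        cd.to_csv(out / "clustered_dynamics.csv", index=False)

        genotypes = set(cohort.animals["genotype"])
        results_rows = []
        if genotypes == {"WT", "DUP"}:
            sweep = clustering.sweep_from_cohort(
                cohort, fates, config.sweep_thresholds_um, ref
            )
            pd.DataFrame(
                {
                    "threshold_um": sweep.thresholds_um,
                    "difference_per_100um": sweep.difference_per_100um,
                    "summed_sem": sweep.summed_sem,
                }
            ).to_csv(out / "threshold_sweep.csv", index=False)

            for metric in ("formed_per_100um", "stabilized_per_100um", "turnover_per_100um"):
                gt = dyn["genotype"].to_numpy()
                dup = dyn.loc[gt == "DUP", metric].to_numpy()
                wt = dyn.loc[gt == "WT", metric].to_numpy()
                mwu = stats.mann_whitney(dup, wt)
                est = stats.bca_bootstrap_diff(
                    dup, wt, n_boot=config.n_boot, seed=seeds["bootstrap"]
                )
                results_rows.append(
                    {
                        "metric": metric,
                        "test": "mann_whitney_U",
                        "statistic": mwu.statistic,
                        "p_value": mwu.p_value,
                        "diff_of_means": est.difference,
                        "bca_low": est.ci_low,
                        "bca_high": est.ci_high,
                    }
                )
            (ab, cd2) = stats.genotype_fisher_table(fates, labels, cohort)
            table = np.array([ab, cd2])
            if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
                fisher = stats.fisher_exact(ab[0], ab[1], cd2[0], cd2[1])
                results_rows.append(
                    {
                        "metric": "clustered_vs_isolated_stabilized",
                        "test": "fisher_exact",
                        "statistic": fisher.statistic,
                        "p_value": fisher.p_value,
                        "diff_of_means": np.nan,
                        "bca_low": np.nan,
                        "bca_high": np.nan,
                    }
                )
        pd.DataFrame(results_rows).to_csv(out / "test_results.csv", index=False)

        # one envelope per genotype, each matched to its own animals
        env_frames = []
        for g in sorted(genotypes):
            sub = cohort.subset_animals(
                cohort.animals.loc[cohort.animals["genotype"] == g, "animal_id"]
            )
            env = nullmodel.null_envelope(
                sub,
                query_selector=SpineSet.FORMED_STABILIZED,
                reference_selector=ref,
                n_reps=config.null_reps,
                seed=seeds["null"],
                bin_width_um=config.bin_width_um,
                max_distance_um=config.max_distance_um,
            )
            frame = env.to_frame()
            frame.insert(0, "genotype", g)
            env_frames.append(frame)
        pd.concat(env_frames, ignore_index=True).to_csv(out / "null_envelope.csv", index=False)

        manifest = {
            "spineclust_version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
            "stage_seeds": seeds,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception:
        shutil.rmtree(out, ignore_errors=True)
        raise
    written["out_dir"] = out
    return {"out_dir": str(out)}
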