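"""Data model, file I/O, validation, and fate classification for
longitudinal dendritic-spine annotations.

A cohort is three tables:

* ``animals`` — one row per mouse: ``animal_id``, ``genotype`` (``WT`` or
  ``DUP``), ``condition`` (``trained`` or ``untrained``), optional
  ``rotarod_mean_s``.
* ``branches`` — one row per analyzed terminal dendritic branch:
  ``branch_id``, ``animal_id``, ``length_um`` (analyzed dendritic length).
* ``spines`` — one row per spine: ``spine_id``, ``branch_id``,
  ``position_um`` (arc-length from the proximal end of the branch) and a
  boolean presence triple ``present_t0``, ``present_t1``, ``present_t2``
  over the three imaging sessions (study days D1, D5, D9).

Spine fates follow from the presence pattern: a spine present at the first
session is a *baseline* spine; a spine absent at the first session and
present at the second is a *formed* spine; a formed spine still present at
the third session is *stabilized*.  Once a spine disappears it never
reappears under the same identifier, so valid presence patterns are the
contiguous runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

GENOTYPES = ("WT", "DUP")
CONDITIONS = ("trained", "untrained")

N_TIMEPOINTS = 3
PRESENCE_COLS = ("present_t0", "present_t1", "present_t2")

SPINE_COLS = ("spine_id", "branch_id", "position_um") + PRESENCE_COLS
BRANCH_COLS = ("branch_id", "animal_id", "length_um")
ANIMAL_COLS = ("animal_id", "genotype", "condition")

#: presence patterns that form one contiguous run with >=1 session present
_VALID_PATTERNS = {
    (True, False, False),
    (True, True, False),
    (True, True, True),
    (False, True, False),
    (False, True, True),
    (False, False, True),
}


class CohortSchemaError(ValueError):
    """A cohort file is missing a required column or has a malformed value."""


class CohortIntegrityError(ValueError):
    """Cross-table references or per-record invariants are violated."""


@dataclass(frozen=True)
class CohortTable:
    """All spine, branch and animal records for one imaging cohort."""

    animals: pd.DataFrame
    branches: pd.DataFrame
    spines: pd.DataFrame

    def __post_init__(self) -> None:
        validate_cohort(self)

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def branches_of(self, animal_id: str) -> pd.DataFrame:
        return self.branches[self.branches["animal_id"] == animal_id]

    def spines_on(self, branch_id: str) -> pd.DataFrame:
        return self.spines[self.spines["branch_id"] == branch_id]

    def subset_animals(self, animal_ids) -> "CohortTable":
        """Restrict the cohort to the given animals (e.g. one genotype)."""
        ids = set(animal_ids)
        animals = self.animals[self.animals["animal_id"].isin(ids)]
        branches = self.branches[self.branches["animal_id"].isin(ids)]
        spines = self.spines[self.spines["branch_id"].isin(set(branches["branch_id"]))]
        return CohortTable(
            animals.reset_index(drop=True),
            branches.reset_index(drop=True),
            spines.reset_index(drop=True),
        )


def _require_columns(df: pd.DataFrame, cols, which: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{which} table is missing column(s): {', '.join(missing)}")


def validate_cohort(cohort: CohortTable) -> None:
    """Check every cohort invariant; raise on the first violation found."""
    animals, branches, spines = cohort.animals, cohort.branches, cohort.spines
    _require_columns(animals, ANIMAL_COLS, "animals")
    _require_columns(branches, BRANCH_COLS, "branches")
    _require_columns(spines, SPINE_COLS, "spines")

    bad_gt = set(animals["genotype"]) - set(GENOTYPES)
    if bad_gt:
        raise CohortSchemaError(f"unknown genotype value(s): {sorted(bad_gt)}")
    bad_cond = set(animals["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise CohortSchemaError(f"unknown condition value(s): {sorted(bad_cond)}")
    if animals["animal_id"].duplicated().any():
        dup = animals.loc[animals["animal_id"].duplicated(), "animal_id"].tolist()
        raise CohortIntegrityError(f"duplicate animal_id(s): {dup}")
    if branches["branch_id"].duplicated().any():
        dup = branches.loc[branches["branch_id"].duplicated(), "branch_id"].tolist()
        raise CohortIntegrityError(f"duplicate branch_id(s): {dup}")
    if spines["spine_id"].duplicated().any():
        dup = spines.loc[spines["spine_id"].duplicated(), "spine_id"].tolist()
        raise CohortIntegrityError(f"duplicate spine_id(s): {dup}")

    if (branches["length_um"] <= 0).any():
        bad = branches.loc[branches["length_um"] <= 0, "branch_id"].tolist()
        raise CohortIntegrityError(f"non-positive branch length for branch(es): {bad}")

    dangling_b = set(branches["animal_id"]) - set(animals["animal_id"])
    if dangling_b:
        raise CohortIntegrityError(
            f"branches reference unknown animal_id(s): {sorted(dangling_b)}"
        )
    dangling_s = set(spines["branch_id"]) - set(branches["branch_id"])
    if dangling_s:
        raise CohortIntegrityError(
            f"spines reference unknown branch_id(s): {sorted(dangling_s)}"
        )

    lengths = branches.set_index("branch_id")["length_um"]
    pos = spines["position_um"].to_numpy()
    lim = lengths.reindex(spines["branch_id"]).to_numpy()
    out = (pos < 0) | (pos > lim)
    if out.any():
        bad = spines.loc[out, "spine_id"].tolist()
        raise CohortIntegrityError(
            f"spine position outside [0, branch length] for spine(s): {bad}"
        )

    dup_pos = spines.duplicated(subset=["branch_id", "position_um"], keep=False)
    if dup_pos.any():
        bad = spines.loc[dup_pos, "spine_id"].tolist()
        raise CohortIntegrityError(
            f"spines sharing an exact position on one branch: {bad}"
        )

    pats = list(
        zip(*(spines[c].astype(bool) for c in PRESENCE_COLS))
    )
    bad_pat = [
        sid for sid, p in zip(spines["spine_id"], pats) if p not in _VALID_PATTERNS
    ]
    if bad_pat:
        raise CohortIntegrityError(
            "presence pattern must be one contiguous run with at least one "
            f"session present; offending spine(s): {bad_pat}"
        )


def _read_table(path, which: str, required) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{which} table not found: {path}")
    # sep=None sniffs comma vs tab from the header row
    df = pd.read_csv(path, sep=None, engine="python")
    _require_columns(df, required, which)
    return df


def read_cohort(spine_table_path, branch_table_path, animal_table_path) -> CohortTable:
    """Load a cohort from three delimited text files (comma or tab)."""
    spines = _read_table(spine_table_path, "spines", SPINE_COLS)
    branches = _read_table(branch_table_path, "branches", BRANCH_COLS)
    animals = _read_table(animal_table_path, "animals", ANIMAL_COLS)
    for c in PRESENCE_COLS:
        spines[c] = spines[c].astype(int).astype(bool)
    for col in ("animal_id",):
        animals[col] = animals[col].astype(str)
    for col in ("branch_id", "animal_id"):
        branches[col] = branches[col].astype(str)
    for col in ("spine_id", "branch_id"):
        spines[col] = spines[col].astype(str)
    return CohortTable(animals=animals, branches=branches, spines=spines)


def write_cohort(cohort: CohortTable, out_dir, sep: str = ",") -> dict:
    """Write the three cohort tables; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "spines": out / "spines.csv",
        "branches": out / "branches.csv",
        "animals": out / "animals.csv",
    }
    spines = cohort.spines.copy()
    for c in PRESENCE_COLS:
        spines[c] = spines[c].astype(int)
    spines.to_csv(paths["spines"], sep=sep, index=False)
    cohort.branches.to_csv(paths["branches"], sep=sep, index=False)
    cohort.animals.to_csv(paths["animals"], sep=sep, index=False)
    return paths


def read_cohort_dir(cohort_dir) -> CohortTable:
    """Load a cohort from a directory laid out as by :func:`write_cohort`."""
    d = Path(cohort_dir)
    return read_cohort(d / "spines.csv", d / "branches.csv", d / "animals.csv")


def combine_cohorts(*cohorts: CohortTable) -> CohortTable:
    """Concatenate cohorts (e.g. one per genotype); IDs must not collide."""
    return CohortTable(
        animals=pd.concat([c.animals for c in cohorts], ignore_index=True),
        branches=pd.concat([c.branches for c in cohorts], ignore_index=True),
        spines=pd.concat([c.spines for c in cohorts], ignore_index=True),
    )


def classify_fates(cohort: CohortTable) -> pd.DataFrame:
    """Classify every spine's longitudinal fate from its presence pattern.

    Returns a DataFrame indexed like ``cohort.spines`` with columns

    * ``is_baseline`` — present at the first session (D1);
    * ``is_formed`` — absent at D1, present at D5;
    * ``is_stabilized`` — formed and still present at D9;
    * ``eliminated_interval1`` — baseline, gone by D5;
    * ``eliminated_interval2`` — baseline, present at D5, gone by D9;
    * ``late_formed`` — present only at D9 (formed during the second
      interval).  Late formations are excluded from every formation /
      stabilization density because the formed cohort is defined at D5.
    """
    s = cohort.spines
    t0 = s["present_t0"].to_numpy(bool)
    t1 = s["present_t1"].to_numpy(bool)
    t2 = s["present_t2"].to_numpy(bool)
    fates = pd.DataFrame(
        {
            "spine_id": s["spine_id"].to_numpy(),
            "branch_id": s["branch_id"].to_numpy(),
            "is_baseline": t0,
            "is_formed": ~t0 & t1,
            "is_stabilized": ~t0 & t1 & t2,
            "eliminated_interval1": t0 & ~t1,
            "eliminated_interval2": t0 & t1 & ~t2,
            "late_formed": ~t0 & ~t1 & t2,
        }
    )
    return fates
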