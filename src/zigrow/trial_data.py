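"""Reading, validation and quality control of common-garden trial tables.

A trial dataset couples three tables: per-individual, per-year growth and
survival measurements; per-genotype metadata (home climate, genomic PC
scores, ancestry proportion); and per-garden, per-year climate (mean coldest
month temperature, MCMT).  Quality control enforces the modelling
conventions: negative growth increments (herbivory / measurement error) are
excluded, dead trees are coded as growth 0, and live trees with missing
growth are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRowError,
    InsufficientDataError,
    ReferentialError,
    SchemaError,
)

MEASUREMENT_COLUMNS = (
    "individual_id",
    "genotype_id",
    "garden_id",
    "block_id",
    "year",
    "growth_increment_cm",
    "survived",
)
GENOTYPE_COLUMNS = ("genotype_id", "home_mcmt", "pc1", "pc2", "pc3", "ancestry_q")
GARDEN_COLUMNS = ("garden_id", "year", "garden_mcmt")


@dataclass
class TrialDataset:
    """Analysis-ready container for one provenance trial.

    observations: one row per individual x year, measurement schema.
    genotypes: one row per genotype, indexed by ``genotype_id``.
    gardens: one row per garden x year, indexed by ``(garden_id, year)``.
    qc_report: counts of rows removed/modified per QC rule (empty pre-QC).
    """

    observations: pd.DataFrame
    genotypes: pd.DataFrame
    gardens: pd.DataFrame
    qc_report: dict = field(default_factory=dict)

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            observations=self.observations.copy(),
            genotypes=self.genotypes.copy(),
            gardens=self.gardens.copy(),
            qc_report=dict(self.qc_report),
        )


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


def _check_foreign_keys(obs: pd.DataFrame, genotypes: pd.DataFrame, gardens: pd.DataFrame) -> None:
    bad_geno = sorted(set(obs["genotype_id"]) - set(genotypes.index))
    garden_keys = set(gardens.index)
    obs_keys = set(zip(obs["garden_id"], obs["year"]))
    bad_garden = sorted(k for k in obs_keys if k not in garden_keys)
    problems = []
    if bad_geno:
        problems.append(f"unknown genotype id(s): {', '.join(bad_geno)}")
    if bad_garden:
        listed = ", ".join(f"{g}/{y}" for g, y in bad_garden)
        problems.append(f"unknown (garden, year) pair(s): {listed}")
    if problems:
        raise ReferentialError("; ".join(problems))


def read_trial_tables(measurements_path, genotypes_path, gardens_path) -> TrialDataset:
    """Read the three CSV tables into an unfiltered :class:`TrialDataset`.

    Raises :class:`SchemaError` for missing columns,
    :class:`DuplicateRowError` for repeated (individual_id, year) rows and
    :class:`ReferentialError` for unresolvable genotype/garden keys.
    """
    obs = pd.read_csv(measurements_path)
    genotypes = pd.read_csv(genotypes_path)
    gardens = pd.read_csv(gardens_path)

    _require_columns(obs, MEASUREMENT_COLUMNS, "measurements")
    _require_columns(genotypes, GENOTYPE_COLUMNS, "genotypes")
    _require_columns(gardens, GARDEN_COLUMNS, "gardens")

    obs = obs.copy()
    obs["year"] = obs["year"].astype(int)
    obs["survived"] = obs["survived"].astype(bool)
    obs["growth_increment_cm"] = pd.to_numeric(obs["growth_increment_cm"], errors="coerce")
    for col in ("individual_id", "genotype_id", "garden_id", "block_id"):
        obs[col] = obs[col].astype(str)

    dup = obs.duplicated(subset=["individual_id", "year"], keep=False)
    if dup.any():
        offenders = obs.loc[dup, ["individual_id", "year"]].drop_duplicates()
        listed = ", ".join(f"{r.individual_id}/{r.year}" for r in offenders.itertuples())
        raise DuplicateRowError(f"duplicate (individual_id, year) rows: {listed}")

    genotypes = genotypes.copy()
    genotypes["genotype_id"] = genotypes["genotype_id"].astype(str)
    if genotypes["genotype_id"].duplicated().any():
        raise DuplicateRowError("duplicate genotype_id rows in genotype table")
    genotypes = genotypes.set_index("genotype_id", drop=False)
    if not np.isfinite(genotypes["home_mcmt"]).all():
        raise SchemaError("home_mcmt must be finite for every genotype")
    q = genotypes["ancestry_q"].to_numpy(float)
    if ((q < 0) | (q > 1)).any() or not np.isfinite(q).all():
        raise SchemaError("ancestry_q must lie in [0, 1]")

    gardens = gardens.copy()
    gardens["garden_id"] = gardens["garden_id"].astype(str)
    gardens["year"] = gardens["year"].astype(int)
    if gardens.duplicated(subset=["garden_id", "year"]).any():
        raise DuplicateRowError("duplicate (garden_id, year) rows in garden table")
    if not np.isfinite(gardens["garden_mcmt"]).all():
        raise SchemaError("garden_mcmt must be finite for every garden x year")
    gardens = gardens.set_index(["garden_id", "year"], drop=False)

    _check_foreign_keys(obs, genotypes, gardens)
    return TrialDataset(observations=obs, genotypes=genotypes, gardens=gardens, qc_report={})


def apply_qc_filters(
    data: TrialDataset,
    excluded_genotypes=(),
    excluded_years=(),
) -> TrialDataset:
    """Apply the quality-control rules, returning a new dataset.

    Rules, in order: drop rows of excluded genotypes and excluded years;
    drop rows with negative growth; drop live rows with missing growth;
    set growth of dead rows (including missing) to exactly 0.  Counts per
    rule are recorded in ``qc_report``.  Idempotent: a second application
    removes nothing.
    """
    excluded_genotypes = set(map(str, excluded_genotypes))
    excluded_years = set(int(y) for y in excluded_years)
    obs = data.observations.copy()
    report = {}

    m = obs["genotype_id"].isin(excluded_genotypes)
    report["excluded_genotype_removed"] = int(m.sum())
    obs = obs.loc[~m]

    m = obs["year"].isin(excluded_years)
    report["excluded_year_removed"] = int(m.sum())
    obs = obs.loc[~m]

    m = obs["growth_increment_cm"] < 0
    report["negative_removed"] = int(m.sum())
    obs = obs.loc[~m]

    live_missing = obs["survived"] & obs["growth_increment_cm"].isna()
    report["live_missing_removed"] = int(live_missing.sum())
    obs = obs.loc[~live_missing]

    dead = ~obs["survived"]
    dead_changed = dead & (obs["growth_increment_cm"].isna() | (obs["growth_increment_cm"] != 0))
    report["dead_zeroed"] = int(dead_changed.sum())
    obs.loc[dead, "growth_increment_cm"] = 0.0

    genotypes = data.genotypes.loc[~data.genotypes.index.isin(excluded_genotypes)].copy()
    out = TrialDataset(
        observations=obs.reset_index(drop=True),
        genotypes=genotypes,
        gardens=data.gardens.copy(),
        qc_report=report,
    )
    return out


def summarize_dataset(data: TrialDataset) -> dict:
    """Summary counts for a QC'd dataset (zero fraction, per-garden counts)."""
    obs = data.observations
    if len(obs) == 0:
        return {"empty": True, "n_observations": 0}
    growth = obs["growth_increment_cm"].to_numpy(float)
    return {
        "empty": False,
        "n_observations": int(len(obs)),
        "n_individuals": int(obs["individual_id"].nunique()),
        "n_genotypes": int(obs["genotype_id"].nunique()),
        "n_gardens": int(obs["garden_id"].nunique()),
        "zero_fraction": float(np.mean(growth == 0)),
        "per_garden_counts": obs.groupby("garden_id").size().to_dict(),
    }


def subset_gardens(data: TrialDataset, garden_ids) -> TrialDataset:
    """Restrict a dataset to the given gardens (used by cross-validation)."""
    garden_ids = set(map(str, garden_ids))
    if not garden_ids:
        raise InsufficientDataError("empty garden subset")
    obs = data.observations.loc[data.observations["garden_id"].isin(garden_ids)]
    gardens = data.gardens.loc[data.gardens["garden_id"].isin(garden_ids)]
    return TrialDataset(
        observations=obs.reset_index(drop=True),
        genotypes=data.genotypes.copy(),
        gardens=gardens.copy(),
        qc_report=dict(data.qc_report),
    )
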