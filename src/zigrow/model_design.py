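"""Covariate scaling and fixed/random design construction.

The growth model regresses log(growth increment + 1) on garden winter
temperature (MCMT), home-climate MCMT, genomic PC scores, and their
polynomial interactions, with crossed random intercepts.  Numeric
covariates are scaled *without centering* (divide by the root mean square,
``sqrt(sum(x^2)/(n-1))``, the non-centered convention of R's ``scale``);
squares are computed on the scaled values and are not rescaled again.
Divisors are recorded so held-out or new data can be scaled identically.

Three model variants are supported:

``full``
    18 fixed-effect columns: intercept; g; h; g2; h2; g:h; g2:h2; g2:h;
    g:h2; pc1..pc3; pc1..pc3:g; pc1..pc3:g2, where g and h are scaled
    garden and home MCMT.
``genetics_only``
    drops every column containing h (home climate excluded).
``climate_only``
    drops every column containing a PC score (genetics excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateInputError
from .trial_data import TrialDataset

SCALED_VARIABLES = ("garden_mcmt", "home_mcmt", "pc1", "pc2", "pc3")

FULL_COLUMNS = (
    "intercept",
    "g",
    "h",
    "g2",
    "h2",
    "g:h",
    "g2:h2",
    "g2:h",
    "g:h2",
    "pc1",
    "pc2",
    "pc3",
    "pc1:g",
    "pc2:g",
    "pc3:g",
    "pc1:g2",
    "pc2:g2",
    "pc3:g2",
)

VARIANTS = ("full", "genetics_only", "climate_only")
DEFAULT_RANDOM_TERMS = ("genotype", "garden", "block", "year", "individual")


def variant_columns(variant: str) -> tuple:
    if variant == "full":
        return FULL_COLUMNS
    if variant == "genetics_only":
        return tuple(c for c in FULL_COLUMNS if "h" not in c)
    if variant == "climate_only":
        return tuple(c for c in FULL_COLUMNS if "pc" not in c)
    raise ConfigurationError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")


def scale_no_center(values) -> tuple:
    """Scale a vector by its non-centered root mean square.

    Returns ``(scaled, divisor)`` with ``divisor = sqrt(sum(x_i^2)/(n-1))``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("scale_no_center needs a 1-D vector of length >= 2")
    divisor = float(np.sqrt(np.sum(x**2) / (x.size - 1)))
    if divisor == 0.0 or not np.isfinite(divisor):
        raise DegenerateInputError("cannot scale an all-zero or non-finite vector")
    return x / divisor, divisor


@dataclass
class ScalingInfo:
    """Per-variable divisors from non-centered scaling, exactly invertible."""

    divisors: dict

    def scale(self, variable: str, values):
        return np.asarray(values, dtype=float) / self.divisors[variable]

    def unscale(self, variable: str, values):
        return np.asarray(values, dtype=float) * self.divisors[variable]

    @classmethod
    def from_observations(cls, table: pd.DataFrame) -> "ScalingInfo":
        divisors = {}
        for var in SCALED_VARIABLES:
            _, divisors[var] = scale_no_center(table[var].to_numpy(float))
        return cls(divisors=divisors)


@dataclass
class ModelSpec:
    """Which fixed-effect variant and random-intercept terms to fit."""

    variant: str = "full"
    random_terms: tuple = DEFAULT_RANDOM_TERMS
    zi_same_formula: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        self.random_terms = tuple(self.random_terms)
        if not self.random_terms:
            raise ConfigurationError("random_terms must be non-empty")

    @property
    def columns(self) -> tuple:
        return variant_columns(self.variant)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "random_terms": list(self.random_terms),
            "zi_same_formula": self.zi_same_formula,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            variant=d.get("variant", "full"),
            random_terms=tuple(d.get("random_terms", DEFAULT_RANDOM_TERMS)),
            zi_same_formula=bool(d.get("zi_same_formula", True)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def evaluate_columns(columns, scaled: dict) -> np.ndarray:
    """Evaluate named design columns from a dict of scaled base variables.

    ``scaled`` maps 'g', 'h', 'pc1', 'pc2', 'pc3' to arrays (or scalars).
    Squares are of the scaled values; ':' denotes a product.
    """
    base = dict(scaled)
    base["g2"] = base["g"] ** 2 if "g" in base else None
    if "h" in base and base["h"] is not None:
        base["h2"] = base["h"] ** 2
    n = None
    for v in base.values():
        if isinstance(v, np.ndarray):
            n = v.shape[0]
            break
    out = []
    for name in columns:
        if name == "intercept":
            col = np.ones(n) if n is not None else 1.0
        else:
            col = 1.0
            for part in name.split(":"):
                if base.get(part) is None:
                    raise ConfigurationError(f"column {name!r} needs missing covariate {part!r}")
                col = col * base[part]
        out.append(col)
    return np.column_stack(out) if n is not None else np.asarray(out, dtype=float)


@dataclass
class DesignMatrices:
    """Aligned responses, fixed-effect matrices and random-effect codings.

    ``X_zi is None`` denotes a conditional-only (no zero-inflation) model,
    used for Gaussian-only oracle instances.
    """

    y: np.ndarray
    is_zero: np.ndarray
    X: np.ndarray
    columns: tuple
    X_zi: Optional[np.ndarray]
    columns_zi: tuple
    factors: tuple  # ordered random-term names
    codes: dict  # factor -> int array (level code per row)
    n_levels: dict  # factor -> number of levels
    level_labels: dict  # factor -> list of labels
    scaling: Optional[ScalingInfo]
    spec: Optional[ModelSpec]
    meta: Optional[pd.DataFrame] = None

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def has_zi(self) -> bool:
        return self.X_zi is not None

    def validate(self) -> None:
        n = self.n_obs
        assert self.X.shape == (n, len(self.columns))
        assert self.is_zero.shape == (n,)
        if self.has_zi:
            assert self.X_zi.shape == (n, len(self.columns_zi))
        for f in self.factors:
            c = self.codes[f]
            assert c.shape == (n,) and c.min() >= 0 and c.max() < self.n_levels[f]


def _factor_codes(labels) -> tuple:
    """Deterministic (sorted-label) integer coding of a factor."""
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels).tolist())
    mapping = {lv: i for i, lv in enumerate(levels)}
    codes = np.fromiter((mapping[v] for v in labels), dtype=np.int64, count=len(labels))
    return codes, levels


def build_design(
    data: TrialDataset,
    spec: ModelSpec,
    scaling: Optional[ScalingInfo] = None,
) -> DesignMatrices:
    """Expand a QC'd dataset into design matrices for both model parts.

    Blocks are coded nested in gardens (block 'A' of garden 1 is a distinct
    level from block 'A' of garden 2).  If ``scaling`` is omitted it is
    computed from this dataset (training data); pass a training
    ScalingInfo when building held-out designs.
    """
    obs = data.observations
    if len(obs) == 0:
        raise DegenerateInputError("cannot build a design from an empty dataset")
    genos = data.genotypes
    columns = spec.columns

    table = obs[["individual_id", "genotype_id", "garden_id", "block_id", "year"]].copy()
    table["garden_mcmt"] = data.gardens.loc[
        pd.MultiIndex.from_frame(obs[["garden_id", "year"]]), "garden_mcmt"
    ].to_numpy(float)
    for col in ("home_mcmt", "pc1", "pc2", "pc3", "ancestry_q"):
        if col in genos.columns:
            table[col] = genos.loc[obs["genotype_id"], col].to_numpy(float)

    needs_pcs = any("pc" in c for c in columns)
    if needs_pcs:
        for c in ("pc1", "pc2", "pc3"):
            if c not in table.columns or not np.isfinite(table[c].to_numpy(float)).all():
                raise ConfigurationError(
                    f"variant {spec.variant!r} needs genotype PC scores but {c!r} is missing"
                )

    if scaling is None:
        scaling = ScalingInfo.from_observations(table)

    scaled = {"g": scaling.scale("garden_mcmt", table["garden_mcmt"])}
    if any("h" in c for c in columns):
        scaled["h"] = scaling.scale("home_mcmt", table["home_mcmt"])
    if needs_pcs:
        for c in ("pc1", "pc2", "pc3"):
            scaled[c] = scaling.scale(c, table[c])
    X = evaluate_columns(columns, scaled)

    growth = obs["growth_increment_cm"].to_numpy(float)
    y = np.log1p(growth)
    is_zero = growth == 0.0

    factor_sources = {
        "genotype": obs["genotype_id"],
        "garden": obs["garden_id"],
        "block": obs["garden_id"].astype(str) + ":" + obs["block_id"].astype(str),
        "year": obs["year"].astype(str),
        "individual": obs["individual_id"],
    }
    codes, n_levels, level_labels = {}, {}, {}
    for f in spec.random_terms:
        if f not in factor_sources:
            raise ConfigurationError(f"unknown random term {f!r}")
        c, levels = _factor_codes(factor_sources[f].to_numpy())
        codes[f], n_levels[f], level_labels[f] = c, len(levels), levels

    X_zi = X if spec.zi_same_formula else None
    return DesignMatrices(
        y=y,
        is_zero=is_zero,
        X=X,
        columns=columns,
        X_zi=X_zi,
        columns_zi=columns if spec.zi_same_formula else (),
        factors=tuple(spec.random_terms),
        codes=codes,
        n_levels=n_levels,
        level_labels=level_labels,
        scaling=scaling,
        spec=spec,
        meta=table,
    )


def fixed_effect_rows(
    columns,
    scaling: ScalingInfo,
    garden_mcmt,
    home_mcmt=None,
    pc1=None,
    pc2=None,
    pc3=None,
) -> np.ndarray:
    """Design rows for arbitrary covariate values on the raw (unscaled) scale.

    Broadcasts scalar/vector inputs; used for predictions and reaction norms.
    """
    arrays = {"g": scaling.scale("garden_mcmt", np.atleast_1d(np.asarray(garden_mcmt, float)))}
    raw = {"home_mcmt": home_mcmt, "pc1": pc1, "pc2": pc2, "pc3": pc3}
    names = {"home_mcmt": "h", "pc1": "pc1", "pc2": "pc2", "pc3": "pc3"}
    shapes = [arrays["g"].shape[0]]
    for var, val in raw.items():
        if val is not None:
            arrays[names[var]] = scaling.scale(var, np.atleast_1d(np.asarray(val, float)))
            shapes.append(arrays[names[var]].shape[0])
    n = max(shapes)
    for k, v in arrays.items():
        arrays[k] = np.broadcast_to(v, (n,)) if v.shape[0] != n else v
    return evaluate_columns(columns, arrays)
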