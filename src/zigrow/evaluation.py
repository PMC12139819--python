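"""Transferability evaluation: leave-one-garden-out cross-validation.

Each fold refits the model with one garden held out (covariate scaling
recomputed on the training gardens only, so no information leaks from the
held-out site), then predicts the held-out garden's trees.  Random effects
for the unseen garden and its blocks are zero by construction; genotype and
year effects can optionally be included since those levels were observed in
training.  Prediction ability is the Pearson correlation between observed
and predicted responses, reported two ways per garden x year:

* conditional — observed zeros (dead trees) excluded, growth only;
* overall — dead trees included as observed 0, predictions multiplied by
  survival probability.

Model variants (full / genetics_only / climate_only) are compared by a
paired two-sided exact Wilcoxon signed-rank test over the shared
(garden, year) fold scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, PairingError
from .model_design import ModelSpec, build_design, fixed_effect_rows
from .trial_data import TrialDataset, subset_gardens
from .zig_engine import FitControl, FittedZIG, fit_zig


class PredictionAbility(NamedTuple):
    r: float  # NaN when undefined (constant vector after exclusion)
    n: int
    undefined: bool


def prediction_ability(observed, predicted, exclude_zero_observed: bool = False) -> PredictionAbility:
    """Pearson correlation between observed and predicted responses.

    With ``exclude_zero_observed`` the pairs with observed 0 (dead trees)
    are dropped first.  A constant vector after exclusion yields an
    undefined correlation, reported as NaN (never coerced to 0).
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise InsufficientDataError("observed and predicted must have equal length")
    if exclude_zero_observed:
        keep = obs != 0.0
        obs, pred = obs[keep], pred[keep]
    n = len(obs)
    if n < 3:
        return PredictionAbility(np.nan, n, True)
    if np.ptp(obs) == 0.0 or np.ptp(pred) == 0.0:
        return PredictionAbility(np.nan, n, True)
    r = float(stats.pearsonr(obs, pred).statistic)
    return PredictionAbility(r, n, False)


@dataclass
class EvalConfig:
    """Cross-validation settings."""

    with_random_effects: tuple = (False, True)
    scale: str = "log"  # 'log' correlates on log(growth+1); 'response' on cm
    back_transform: str = "naive"
    control: Optional[FitControl] = None


def _predict_holdout(
    fit: FittedZIG, data: TrialDataset, test_obs: pd.DataFrame, with_re: bool
):
    """Fixed-effect predictions for held-out rows, optionally adding modes
    for levels seen in training (genotype, year); unseen levels are 0."""
    genos = data.genotypes
    gmc = data.gardens.loc[
        pd.MultiIndex.from_frame(test_obs[["garden_id", "year"]]), "garden_mcmt"
    ].to_numpy(float)
    kwargs = {"home_mcmt": genos.loc[test_obs["genotype_id"], "home_mcmt"].to_numpy(float)}
    if any("pc" in c for c in fit.columns):
        for c in ("pc1", "pc2", "pc3"):
            kwargs[c] = genos.loc[test_obs["genotype_id"], c].to_numpy(float)
    X = fixed_effect_rows(fit.columns, fit.scaling, garden_mcmt=gmc, **kwargs)
    eta = X @ fit.params.beta_cond
    eta_zi = X @ fit.params.beta_zi  # zi part shares the formula
    if with_re:
        for part, vec in (("cond", None), ("zi", None)):
            modes = fit.re_modes.get(part, {})
            dev = np.zeros(len(test_obs))
            gmap = modes.get("genotype", {})
            dev += test_obs["genotype_id"].map(lambda g: gmap.get(str(g), 0.0)).to_numpy(float)
            ymap = modes.get("year", {})
            dev += test_obs["year"].map(lambda y: ymap.get(str(y), 0.0)).to_numpy(float)
            # garden/block/individual of the held-out site are unseen: zero
            if part == "cond":
                eta = eta + dev
            else:
                eta_zi = eta_zi + dev
    p = 1.0 / (1.0 + np.exp(-np.clip(eta_zi, -500, 500)))
    return eta, p


def leave_one_garden_out(
    data: TrialDataset,
    specs,
    eval_config: Optional[EvalConfig] = None,
) -> pd.DataFrame:
    """Cross-validate one or more model variants over gardens.

    ``specs`` is a ModelSpec or list of them.  Returns a tidy frame with one
    row per (garden, year, variant, with_random_effects): prediction
    abilities, counts, and a ``failed`` flag for non-converged folds.
    """
    if isinstance(specs, ModelSpec):
        specs = [specs]
    cfg = eval_config or EvalConfig()
    gardens = sorted(data.observations["garden_id"].unique())
    if len(gardens) < 3:
        raise InsufficientDataError("leave-one-garden-out needs >= 3 gardens")
    rows = []
    for held_out in gardens:
        train = subset_gardens(data, [g for g in gardens if g != held_out])
        test_obs = data.observations.loc[data.observations["garden_id"] == held_out]
        for spec in specs:
            try:
                design = build_design(train, spec)  # scaling recomputed on train
                fit = fit_zig(design, control=cfg.control)
            except Exception as err:  # fold failed; others proceed
                for yr in sorted(test_obs["year"].unique()):
                    for wre in cfg.with_random_effects:
                        rows.append(
                            {
                                "garden_id": held_out,
                                "year": yr,
                                "variant": spec.variant,
                                "with_random_effects": wre,
                                "scale": cfg.scale,
                                "n_predicted": 0,
                                "pearson_r_conditional": np.nan,
                                "pearson_r_overall": np.nan,
                                "failed": True,
                                "error": str(err),
                            }
                        )
                continue
            for wre in cfg.with_random_effects:
                eta, p = _predict_holdout(fit, data, test_obs, wre)
                growth_obs = test_obs["growth_increment_cm"].to_numpy(float)
                if cfg.scale == "log":
                    obs_vec = np.log1p(growth_obs)
                    pred_cond = eta
                else:
                    obs_vec = growth_obs
                    pred_cond = np.expm1(eta)
                pred_overall = (1.0 - p) * pred_cond
                for yr in sorted(test_obs["year"].unique()):
                    sel = (test_obs["year"] == yr).to_numpy()
                    cond = prediction_ability(obs_vec[sel], pred_cond[sel], exclude_zero_observed=True)
                    over = prediction_ability(obs_vec[sel], pred_overall[sel], exclude_zero_observed=False)
                    rows.append(
                        {
                            "garden_id": held_out,
                            "year": yr,
                            "variant": spec.variant,
                            "with_random_effects": wre,
                            "scale": cfg.scale,
                            "n_predicted": int(sel.sum()),
                            "pearson_r_conditional": cond.r,
                            "pearson_r_overall": over.r,
                            "failed": False,
                            "error": "",
                        }
                    )
    return pd.DataFrame(rows)


class VariantComparison(NamedTuple):
    statistic: float
    p: float
    n_pairs: int
    n_zero_diffs: int
    degenerate: bool


def compare_model_variants(
    a: pd.DataFrame,
    b: pd.DataFrame,
    value: str = "pearson_r_conditional",
    method: str = "wilcoxon",
) -> VariantComparison:
    """Paired comparison of two CV results over shared (garden, year) keys.

    Default: two-sided exact Wilcoxon signed-rank on the per-fold
    prediction abilities; zero differences are dropped (exact-conditional
    convention) and counted.  ``method='ttest'`` gives a paired t-test.
    """
    keys = ["garden_id", "year"]
    merged = pd.merge(
        a[keys + [value]], b[keys + [value]], on=keys, suffixes=("_a", "_b")
    ).dropna()
    if merged.empty:
        raise PairingError("no shared (garden, year) keys between the two results")
    d = (merged[f"{value}_b"] - merged[f"{value}_a"]).to_numpy(float)
    n_pairs = len(d)
    n_zero = int(np.sum(d == 0.0))
    nonzero = d[d != 0.0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; test degenerate", RuntimeWarning)
        return VariantComparison(0.0, 1.0, n_pairs, n_zero, True)
    if method == "wilcoxon":
        res = stats.wilcoxon(
            nonzero, alternative="two-sided", method="exact", zero_method="wilcox"
        )
    elif method == "ttest":
        res = stats.ttest_rel(merged[f"{value}_b"], merged[f"{value}_a"])
    else:
        raise PairingError(f"unknown comparison method {method!r}")
    return VariantComparison(float(res.statistic), float(res.pvalue), n_pairs, n_zero, False)
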