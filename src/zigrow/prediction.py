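"""Predictions from a fitted model: growth, mortality, overall fitness.

Three quantities are reported for any covariate combination, mirroring the
two model parts and their product:

* ``eta_cond`` — predicted mean of log(growth increment + 1);
* ``p_mortality`` — zero-inflation probability (structural zero = death);
* ``overall`` — the fitness proxy ``(1 - p_mortality) * growth_response``.

``growth_response`` back-transforms ``eta_cond`` to centimetres; the
default is the naive inverse ``exp(eta) - 1``, with a lognormal-mean
correction ``exp(eta + sigma^2/2) - 1`` selectable.  Reaction norms
evaluate a genotype on an even MCMT grid with random effects zeroed
(population-level prediction); unknown random-effect levels always
contribute zero deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .model_design import fixed_effect_rows
from .zig_engine import FittedZIG

DEFAULT_GRID = (-23.9, 9.8, 100)  # degC span covering home and garden climates

BACK_TRANSFORMS = ("naive", "lognormal")


@dataclass
class PredictionRequest:
    """Covariates (raw units) and random-effect context for one prediction."""

    garden_mcmt: float
    home_mcmt: Optional[float] = None
    pc1: Optional[float] = None
    pc2: Optional[float] = None
    pc3: Optional[float] = None
    include_random_effects: bool = False
    genotype_id: Optional[str] = None
    garden_id: Optional[str] = None
    block_id: Optional[str] = None  # nested label, "garden:block"
    year: Optional[str] = None
    individual_id: Optional[str] = None


@dataclass
class Components:
    eta_cond: np.ndarray
    growth_response: np.ndarray
    p_mortality: np.ndarray
    overall: np.ndarray


@dataclass
class ReactionNorm:
    """Per-genotype predicted response over an MCMT grid."""

    genotype_id: str
    grid: np.ndarray
    eta_cond: np.ndarray
    growth_response: np.ndarray
    p_mortality: np.ndarray
    overall: np.ndarray
    t_opt_overall: float
    t_opt_growth: float
    ancestry_q: Optional[float] = None
    home_mcmt: Optional[float] = None


def _re_deviation(fit: FittedZIG, part: str, req: PredictionRequest) -> float:
    """Sum of known-level conditional modes; unknown levels contribute 0."""
    modes = fit.re_modes.get(part, {})
    keys = {
        "genotype": req.genotype_id,
        "garden": req.garden_id,
        "block": req.block_id,
        "year": req.year,
        "individual": req.individual_id,
    }
    dev = 0.0
    for factor, label in keys.items():
        if label is not None:
            dev += modes.get(factor, {}).get(str(label), 0.0)
    return dev


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def back_transform_growth(eta, sigma, method="naive"):
    if method == "naive":
        return np.expm1(eta)
    if method == "lognormal":
        return np.expm1(eta + 0.5 * sigma**2)
    raise ConfigurationError(f"unknown back-transform {method!r}; expected {BACK_TRANSFORMS}")


def predict_components(
    fit: FittedZIG,
    req: PredictionRequest,
    back_transform: str = "naive",
    guard_bounds: Optional[tuple] = None,
) -> Components:
    """Evaluate both model parts and the fitness proxy for a request.

    ``guard_bounds = (low, high)`` attaches an extrapolation warning when
    the requested garden MCMT is outside the bounds widened by 20% of their
    span; predictions are still returned.
    """
    t = np.atleast_1d(np.asarray(req.garden_mcmt, float))
    if guard_bounds is not None:
        lo, hi = guard_bounds
        margin = 0.2 * (hi - lo)
        if np.any(t < lo - margin) or np.any(t > hi + margin):
            warnings.warn(
                f"garden MCMT outside extrapolation guard [{lo - margin:.2f}, "
                f"{hi + margin:.2f}] degC; prediction is an extrapolation",
                RuntimeWarning,
            )
    X = fixed_effect_rows(
        fit.columns,
        fit.scaling,
        garden_mcmt=t,
        home_mcmt=req.home_mcmt,
        pc1=req.pc1,
        pc2=req.pc2,
        pc3=req.pc3,
    )
    eta = X @ fit.params.beta_cond
    if fit.params.has_zi and len(fit.columns_zi):
        Xz = fixed_effect_rows(
            fit.columns_zi,
            fit.scaling,
            garden_mcmt=t,
            home_mcmt=req.home_mcmt,
            pc1=req.pc1,
            pc2=req.pc2,
            pc3=req.pc3,
        )
        eta_zi = Xz @ fit.params.beta_zi
    else:
        eta_zi = np.full_like(eta, -np.inf)
    if req.include_random_effects:
        eta = eta + _re_deviation(fit, "cond", req)
        eta_zi = eta_zi + _re_deviation(fit, "zi", req)
    p = _sigmoid(eta_zi) if np.isfinite(eta_zi).any() else np.zeros_like(eta)
    p = np.where(np.isfinite(eta_zi), p, 0.0)
    growth = back_transform_growth(eta, fit.params.sigma_resid, back_transform)
    overall = (1.0 - p) * growth
    return Components(eta_cond=eta, growth_response=growth, p_mortality=p, overall=overall)


def mcmt_grid(grid_min: float, grid_max: float, n_points: int) -> np.ndarray:
    """``n_points`` equally spaced MCMT values, endpoints included."""
    if n_points < 2 or grid_min >= grid_max:
        raise ConfigurationError("need n_points >= 2 and grid_min < grid_max")
    return np.linspace(grid_min, grid_max, n_points)


def reaction_norm(
    fit: FittedZIG,
    genotype,
    grid_min: float = DEFAULT_GRID[0],
    grid_max: float = DEFAULT_GRID[1],
    n_points: int = DEFAULT_GRID[2],
    back_transform: str = "naive",
) -> ReactionNorm:
    """Population-level (fixed-effects-only) response of one genotype.

    ``genotype`` is a genotype-table row (Series/dict) with home_mcmt and
    PC scores.  Optimum temperatures are grid argmaxes; ties break toward
    the lower temperature.
    """
    grid = mcmt_grid(grid_min, grid_max, n_points)
    g = dict(genotype)
    req = PredictionRequest(
        garden_mcmt=grid,
        home_mcmt=g.get("home_mcmt"),
        pc1=g.get("pc1"),
        pc2=g.get("pc2"),
        pc3=g.get("pc3"),
        include_random_effects=False,
    )
    comp = predict_components(fit, req, back_transform=back_transform)
    # np.argmax returns the first maximum; the grid is increasing, so ties
    # already resolve toward the lower temperature
    t_opt_overall = float(grid[int(np.argmax(comp.overall))])
    t_opt_growth = float(grid[int(np.argmax(comp.growth_response))])
    return ReactionNorm(
        genotype_id=str(g.get("genotype_id", "?")),
        grid=grid,
        eta_cond=comp.eta_cond,
        growth_response=comp.growth_response,
        p_mortality=comp.p_mortality,
        overall=comp.overall,
        t_opt_overall=t_opt_overall,
        t_opt_growth=t_opt_growth,
        ancestry_q=float(g["ancestry_q"]) if "ancestry_q" in g else None,
        home_mcmt=float(g["home_mcmt"]) if g.get("home_mcmt") is not None else None,
    )


def transfer_distance_view(norm: ReactionNorm, home_mcmt: float) -> pd.DataFrame:
    """Re-index a reaction norm by transfer distance (garden - home MCMT)."""
    return pd.DataFrame(
        {
            "transfer_distance": norm.grid - home_mcmt,
            "mcmt": norm.grid,
            "eta_cond": norm.eta_cond,
            "growth_response": norm.growth_response,
            "p_mortality": norm.p_mortality,
            "overall": norm.overall,
        }
    )


def norms_to_frame(norms) -> pd.DataFrame:
    """Tidy CSV-ready frame for a collection of reaction norms."""
    frames = []
    for nm in norms:
        frames.append(
            pd.DataFrame(
                {
                    "genotype_id": nm.genotype_id,
                    "mcmt": nm.grid,
                    "eta_cond": nm.eta_cond,
                    "growth_response": nm.growth_response,
                    "p_mortality": nm.p_mortality,
                    "overall": nm.overall,
                    "ancestry_q": nm.ancestry_q,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def plot_reaction_norms(norms, path, quantity="overall") -> None:
    """Per-genotype curves over the MCMT grid, colored by ancestry q."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    cmap = plt.get_cmap("coolwarm")
    for nm in norms:
        q = 0.5 if nm.ancestry_q is None else nm.ancestry_q
        ax.plot(nm.grid, getattr(nm, quantity), color=cmap(q), lw=1, alpha=0.8)
    ax.set_xlabel("garden MCMT (degC)")
    labels = {
        "overall": "overall fitness proxy (cm)",
        "growth_response": "predicted growth increment (cm)",
        "p_mortality": "predicted mortality probability",
        "eta_cond": "predicted log(growth + 1)",
    }
    ax.set_ylabel(labels.get(quantity, quantity))
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, 1))
    fig.colorbar(sm, ax=ax, label="ancestry q (warm-species proportion)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
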