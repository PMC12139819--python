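"""Synthetic multi-garden provenance trials with known generating truth.

The generator emulates the study conditions the pipeline targets: ~45
clonal genotypes spanning an admixture gradient (ancestry proportion q at
K = 2) between a warm-adapted and a cold-adapted parental species; home
MCMT increasing with q over [-23.9, -3.8] degC; genomic PC1 strongly
negatively correlated with home MCMT (target r = -0.69, realized by
calibrating the PC1 noise scale against the drawn values); 17 gardens x 2
blocks x 2 years with garden MCMT spread over [-16.5, 9.8] degC on a
quasi-even grid (anchor gardens at both climatic extremes); a quadratic
growth response to garden MCMT whose optimum shifts warmer with
warm-species ancestry; and structural zeros from mortality concentrated at
the temperature extremes, targeting a 27% overall zero fraction.

The zero-inflation intercept is calibrated per realization (a Brent solve
against the drawn covariates and random effects) so that the mean
structural-zero probability equals the configured target; only binomial
sampling noise remains in the realized zero fraction.  The calibrated
intercept is recorded in :class:`SimTruth` as the true value.

True fixed effects are expressed in the *scaled* design-column space (the
same non-centered scaling the model applies), so recovery experiments
compare like with like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import pearsonr

from .errors import ConfigurationError
from .model_design import (
    FULL_COLUMNS,
    ModelSpec,
    ScalingInfo,
    build_design,
    evaluate_columns,
)
from .trial_data import TrialDataset
from .zig_engine import FitControl, ZIGParameters, fit_zig

# Default true fixed effects, scaled-column space.  Conditional part: log
# growth peaks near 45 cm at mildly warm gardens and falls off toward both
# extremes; negative pc1 (= warm-species ancestry) raises growth and shifts
# the optimum warmer.  The pc2:g2 coefficient is exactly zero (a truly null
# genotype-by-environment curvature term).  Zero-inflation part: U-shaped
# mortality in garden MCMT, steeper at the cold end; the intercept is the
# pre-calibration value.
DEFAULT_BETA_COND = {
    "intercept": 4.8,
    "g": 0.50,
    "h": 0.10,
    "g2": -0.55,
    "h2": 0.0,
    "g:h": 0.08,
    "g2:h2": 0.0,
    "g2:h": 0.0,
    "g:h2": 0.0,
    "pc1": -0.25,
    "pc2": 0.0,
    "pc3": 0.12,
    "pc1:g": -0.12,
    "pc2:g": 0.03,
    "pc3:g": 0.04,
    "pc1:g2": 0.03,
    "pc2:g2": 0.0,
    "pc3:g2": 0.0,
}
DEFAULT_BETA_ZI = {
    "intercept": -1.8,
    "g": -0.35,
    "h": 0.0,
    "g2": 0.9,
    "h2": 0.0,
    "g:h": -0.05,
    "g2:h2": 0.0,
    "g2:h": 0.0,
    "g:h2": 0.0,
    "pc1": 0.12,
    "pc2": 0.0,
    "pc3": 0.0,
    "pc1:g": 0.10,
    "pc2:g": 0.0,
    "pc3:g": 0.0,
    "pc1:g2": 0.0,
    "pc2:g2": 0.0,
    "pc3:g2": 0.0,
}
DEFAULT_RE_SD_COND = {
    "genotype": 0.30,
    "garden": 0.20,
    "block": 0.15,
    "year": 0.15,
    "individual": 0.30,
}
DEFAULT_RE_SD_ZI = {
    "genotype": 0.15,
    "garden": 0.15,
    "block": 0.10,
    "year": 0.05,
    "individual": 0.15,
}


@dataclass
class SimConfig:
    """Generating conditions for one synthetic trial."""

    n_genotypes: int = 45
    n_gardens: int = 17
    n_blocks: int = 2
    n_years: int = 2
    garden_mcmt_range: tuple = (-16.5, 9.8)
    home_mcmt_range: tuple = (-23.9, -3.8)
    target_cor_pc1_home: float = -0.69
    target_zero_fraction: float = 0.27
    beta_cond: dict = field(default_factory=lambda: dict(DEFAULT_BETA_COND))
    beta_zi: dict = field(default_factory=lambda: dict(DEFAULT_BETA_ZI))
    re_sd_cond: dict = field(default_factory=lambda: dict(DEFAULT_RE_SD_COND))
    re_sd_zi: dict = field(default_factory=lambda: dict(DEFAULT_RE_SD_ZI))
    sigma_resid: float = 0.5
    first_year: int = 2021
    year_effect_sd_mcmt: float = 0.8  # shared warm/cold-year shift, degC
    garden_year_jitter_mcmt: float = 0.4  # garden x year wobble, degC
    include_sampling_zeros: bool = False
    calibrate_zero_fraction: bool = True

    def validate(self) -> None:
        if self.garden_mcmt_range[0] >= self.garden_mcmt_range[1]:
            raise ConfigurationError("garden_mcmt_range must be ordered")
        if self.home_mcmt_range[0] >= self.home_mcmt_range[1]:
            raise ConfigurationError("home_mcmt_range must be ordered")
        if not 0.0 < self.target_zero_fraction < 1.0:
            raise ConfigurationError("target_zero_fraction must be in (0, 1)")
        # exactly +-1 is the noise-free affine limit; targets between 0.999
        # and 1 in magnitude are not reliably calibratable at n ~ 45
        t = abs(self.target_cor_pc1_home)
        if 0.999 < t < 1.0 or t > 1.0:
            raise ConfigurationError(
                "target PC1/home correlation beyond +-0.999 is infeasible "
                "(exactly +-1 selects the noise-free limit)"
            )
        for d in (self.re_sd_cond, self.re_sd_zi):
            if any(v < 0 for v in d.values()):
                raise ConfigurationError("random-effect SDs must be >= 0")


@dataclass
class SimTruth:
    """Everything needed to recompute each observation's generating mean."""

    params: ZIGParameters  # betas aligned with FULL_COLUMNS, calibrated zi intercept
    columns: tuple
    genotypes: pd.DataFrame
    re_draws_cond: dict  # factor -> {level label: value}
    re_draws_zi: dict
    scaling: ScalingInfo
    realized_cor_pc1_home: float
    realized_zero_fraction: float
    zi_intercept_adjustment: float


def _draw_ancestry(rng, n):
    """Mixture of near-0, near-1 and intermediate admixture proportions."""
    comp = rng.choice(3, size=n, p=(0.3, 0.3, 0.4))
    q = np.empty(n)
    q[comp == 0] = rng.beta(1.0, 15.0, int((comp == 0).sum()))
    q[comp == 1] = rng.beta(15.0, 1.0, int((comp == 1).sum()))
    q[comp == 2] = rng.uniform(0.05, 0.95, int((comp == 2).sum()))
    return q


def _calibrated_pc1(rng, home, target_r):
    """PC1 as minus standardized home MCMT plus noise, with the noise scale
    solved so the realized Pearson correlation equals the target."""
    z = (home - home.mean()) / home.std()
    base = -z  # correlation with home is exactly -1
    if abs(target_r) >= 1.0 - 1e-12:
        return -base if target_r > 0 else base
    noise = rng.normal(size=len(home))
    noise = noise - noise.mean()
    # orthogonalize against home so r -> 0 monotonically as the noise grows
    noise = noise - (noise @ z) / (z @ z) * z
    if np.allclose(noise, 0.0):
        raise ConfigurationError("degenerate noise draw; cannot calibrate PC1")

    sign = -1.0 if target_r > 0 else 1.0  # flip base so noise moves r toward 0
    start = sign * base

    def gap(s):
        return pearsonr(start + s * noise, home).statistic - target_r

    s_hi = 1.0
    while gap(s_hi) * gap(0.0) > 0 and s_hi < 1e4:
        s_hi *= 2.0
    if gap(s_hi) * gap(0.0) > 0:
        raise ConfigurationError("could not calibrate PC1 noise for target correlation")
    s = brentq(gap, 0.0, s_hi, xtol=1e-12)
    pc1 = start + s * noise
    return 1.5 * pc1 / pc1.std()  # arbitrary PC-score units


def simulate_genotypes(cfg: SimConfig, seed) -> tuple:
    """Draw the genotype panel; returns (genotype table, partial truth dict)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = cfg.n_genotypes
    q = _draw_ancestry(rng, n)
    lo, hi = cfg.home_mcmt_range
    home = lo + q * (hi - lo) + rng.normal(0.0, 2.5, n)
    home = np.clip(home, lo, hi)
    pc1 = _calibrated_pc1(rng, home, cfg.target_cor_pc1_home)
    z = (home - home.mean()) / home.std()

    def weak_axis(loading, scale):
        # orthonormalized noise keeps the realized home-climate correlation
        # at loading/sqrt(loading^2 + 1) by construction (|r| < 0.3)
        e = rng.normal(size=n)
        e = e - e.mean()
        e = e - (e @ z) / (z @ z) * z
        e = e / e.std()
        return scale * (loading * z + e)

    pc2 = weak_axis(-0.20, 1.2)
    pc3 = weak_axis(-0.30, 1.0)
    table = pd.DataFrame(
        {
            "genotype_id": [f"G{i:03d}" for i in range(n)],
            "home_mcmt": home,
            "pc1": pc1,
            "pc2": pc2,
            "pc3": pc3,
            "ancestry_q": q,
            "latitude": 61.0 - 17.0 * q + rng.normal(0.0, 1.5, n),
            "longitude": -146.0 + 20.0 * q + rng.normal(0.0, 3.0, n),
        }
    ).set_index("genotype_id", drop=False)
    realized_r = float(pearsonr(pc1, home).statistic)
    return table, {"realized_cor_pc1_home": realized_r}


def simulate_trial(cfg: SimConfig, seed) -> tuple:
    """Generate one full trial; returns ``(TrialDataset, SimTruth)``.

    Structural zeros code mortality: the zero indicator also sets
    ``survived = False``.  Positive growth is ``exp(eta + eps) - 1`` with a
    truncation re-draw below zero, so live trees have strictly positive
    growth by default (``include_sampling_zeros`` switches the re-draw off
    and clips instead, producing live zeros for mixture stress tests).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    genotypes, ginfo = simulate_genotypes(cfg, int(rng.integers(0, 2**31 - 1)))

    glo, ghi = cfg.garden_mcmt_range
    garden_ids = [f"S{j:02d}" for j in range(cfg.n_gardens)]
    base = np.linspace(glo, ghi, cfg.n_gardens)
    years = [cfg.first_year + t for t in range(cfg.n_years)]
    year_shift = rng.normal(0.0, cfg.year_effect_sd_mcmt, cfg.n_years)
    garden_rows = []
    for j, gid in enumerate(garden_ids):
        for t, yr in enumerate(years):
            mcmt = base[j] + year_shift[t] + rng.normal(0.0, cfg.garden_year_jitter_mcmt)
            garden_rows.append({"garden_id": gid, "year": yr, "garden_mcmt": mcmt})
    gardens = pd.DataFrame(garden_rows).set_index(["garden_id", "year"], drop=False)

    # one individual per genotype x garden x block, observed every year
    geno_idx, gard_idx, block_idx = np.meshgrid(
        np.arange(cfg.n_genotypes),
        np.arange(cfg.n_gardens),
        np.arange(cfg.n_blocks),
        indexing="ij",
    )
    geno_idx, gard_idx, block_idx = geno_idx.ravel(), gard_idx.ravel(), block_idx.ravel()
    n_ind = len(geno_idx)
    ind_ids = np.array(
        [
            f"{genotypes.index[g]}_{garden_ids[s]}_B{b + 1}"
            for g, s, b in zip(geno_idx, gard_idx, block_idx)
        ]
    )
    obs = pd.DataFrame(
        {
            "individual_id": np.tile(ind_ids, cfg.n_years),
            "genotype_id": np.tile(genotypes.index.to_numpy()[geno_idx], cfg.n_years),
            "garden_id": np.tile(np.array(garden_ids)[gard_idx], cfg.n_years),
            "block_id": np.tile(np.array([f"B{b + 1}" for b in block_idx]), cfg.n_years),
            "year": np.repeat(years, n_ind),
        }
    )

    covars = pd.DataFrame(
        {
            "garden_mcmt": gardens.loc[
                pd.MultiIndex.from_frame(obs[["garden_id", "year"]]), "garden_mcmt"
            ].to_numpy(),
        }
    )
    for c in ("home_mcmt", "pc1", "pc2", "pc3"):
        covars[c] = genotypes.loc[obs["genotype_id"], c].to_numpy()
    scaling = ScalingInfo.from_observations(covars)
    scaled = {
        "g": scaling.scale("garden_mcmt", covars["garden_mcmt"]),
        "h": scaling.scale("home_mcmt", covars["home_mcmt"]),
        "pc1": scaling.scale("pc1", covars["pc1"]),
        "pc2": scaling.scale("pc2", covars["pc2"]),
        "pc3": scaling.scale("pc3", covars["pc3"]),
    }
    X = evaluate_columns(FULL_COLUMNS, scaled)
    beta_c = np.array([cfg.beta_cond.get(c, 0.0) for c in FULL_COLUMNS])
    beta_z = np.array([cfg.beta_zi.get(c, 0.0) for c in FULL_COLUMNS])

    factor_labels = {
        "genotype": obs["genotype_id"],
        "garden": obs["garden_id"],
        "block": obs["garden_id"] + ":" + obs["block_id"],
        "year": obs["year"].astype(str),
        "individual": obs["individual_id"],
    }
    re_draws_c, re_draws_z = {}, {}
    dev_c = np.zeros(len(obs))
    dev_z = np.zeros(len(obs))
    for f, labels in factor_labels.items():
        levels = sorted(labels.unique())
        draws_c = rng.normal(0.0, cfg.re_sd_cond[f], len(levels))
        draws_z = rng.normal(0.0, cfg.re_sd_zi[f], len(levels))
        re_draws_c[f] = dict(zip(levels, draws_c))
        re_draws_z[f] = dict(zip(levels, draws_z))
        pos = labels.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
        dev_c += draws_c[pos]
        dev_z += draws_z[pos]

    eta_c = X @ beta_c + dev_c
    eta_z = X @ beta_z + dev_z

    adjustment = 0.0
    if cfg.calibrate_zero_fraction:
        target = cfg.target_zero_fraction

        def excess(delta):
            return float(np.mean(expit(eta_z + delta))) - target

        adjustment = brentq(excess, -20.0, 20.0, xtol=1e-12)
        eta_z = eta_z + adjustment
        beta_z = beta_z.copy()
        beta_z[0] += adjustment

    p = expit(eta_z)
    dead = rng.random(len(obs)) < p
    eps = rng.normal(0.0, cfg.sigma_resid, len(obs))
    growth = np.exp(eta_c + eps) - 1.0
    if cfg.include_sampling_zeros:
        growth = np.maximum(growth, 0.0)
    else:
        bad = (~dead) & (growth <= 0.0)
        while bad.any():
            eps_new = rng.normal(0.0, cfg.sigma_resid, int(bad.sum()))
            growth[bad] = np.exp(eta_c[bad] + eps_new) - 1.0
            bad = (~dead) & (growth <= 0.0)
    growth[dead] = 0.0

    obs["growth_increment_cm"] = growth
    obs["survived"] = ~dead
    dataset = TrialDataset(
        observations=obs, genotypes=genotypes, gardens=gardens, qc_report={}
    )
    params = ZIGParameters(
        beta_cond=beta_c,
        beta_zi=beta_z,
        sigma_resid=cfg.sigma_resid,
        re_sd_cond=dict(cfg.re_sd_cond),
        re_sd_zi=dict(cfg.re_sd_zi),
    )
    truth = SimTruth(
        params=params,
        columns=FULL_COLUMNS,
        genotypes=genotypes,
        re_draws_cond=re_draws_c,
        re_draws_zi=re_draws_z,
        scaling=scaling,
        realized_cor_pc1_home=ginfo["realized_cor_pc1_home"],
        realized_zero_fraction=float(np.mean(growth == 0.0)),
        zi_intercept_adjustment=float(adjustment),
    )
    return dataset, truth


def write_trial_csvs(data: TrialDataset, out_dir, truth: Optional[SimTruth] = None) -> dict:
    """Write the three input CSVs (and truth JSON) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out / "measurements.csv",
        "genotypes": out / "genotypes.csv",
        "gardens": out / "gardens.csv",
    }
    obs = data.observations.copy()
    obs["survived"] = obs["survived"].astype(int)
    obs.to_csv(paths["measurements"], index=False)
    data.genotypes.to_csv(paths["genotypes"], index=False)
    data.gardens.to_csv(paths["gardens"], index=False)
    if truth is not None:
        paths["truth"] = out / "truth.json"
        doc = {
            "beta_cond": dict(zip(truth.columns, truth.params.beta_cond.tolist())),
            "beta_zi": dict(zip(truth.columns, truth.params.beta_zi.tolist())),
            "sigma_resid": truth.params.sigma_resid,
            "re_sd_cond": truth.params.re_sd_cond,
            "re_sd_zi": truth.params.re_sd_zi,
            "scaling_divisors": truth.scaling.divisors,
            "realized_cor_pc1_home": truth.realized_cor_pc1_home,
            "realized_zero_fraction": truth.realized_zero_fraction,
            "zi_intercept_adjustment": truth.zi_intercept_adjustment,
        }
        with open(paths["truth"], "w") as fh:
            json.dump(doc, fh, indent=1)
    return paths


def recovery_experiment(
    cfg: SimConfig,
    n_reps: int,
    base_seed: int = 0,
    control: Optional[FitControl] = None,
) -> pd.DataFrame:
    """Repeated simulate-and-refit: bias, spread and Wald CI coverage.

    Returns one row per fixed-effect coefficient (both parts) with the mean
    estimate, bias, empirical SD, mean Wald SE and 95% CI coverage over
    replicates.  Replicates whose fit fails are dropped and counted; more
    than 20% failures aborts the experiment.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    control = control or FitControl()
    spec = ModelSpec(variant="full")
    records = []
    failures = 0
    for rep in range(n_reps):
        seed = base_seed + rep
        try:
            data, truth = simulate_trial(cfg, seed)
            design = build_design(data, spec)
            fit = fit_zig(design, control=control)
            if not fit.converged:
                raise RuntimeError("outer optimizer did not converge")
        except Exception:
            failures += 1
            if failures > max(1, int(0.2 * n_reps)):
                raise RuntimeError(f"more than 20% of fits failed ({failures}/{rep + 1})")
            continue
        se = np.sqrt(np.maximum(np.diag(fit.vcov_fixed), 0.0))
        est = np.concatenate([fit.params.beta_cond, fit.params.beta_zi])
        tru = np.concatenate([truth.params.beta_cond, truth.params.beta_zi])
        parts = ["cond"] * len(fit.columns) + ["zi"] * len(fit.columns_zi)
        names = list(fit.columns) + list(fit.columns_zi)
        for i, (part, name) in enumerate(zip(parts, names)):
            records.append(
                {
                    "rep": rep,
                    "part": part,
                    "term": name,
                    "estimate": est[i],
                    "truth": tru[i],
                    "se": se[i],
                }
            )
    df = pd.DataFrame(records)
    if df.empty:
        raise RuntimeError("no successful replicates")
    zcrit = 1.959963984540054
    df["covered"] = (np.abs(df["estimate"] - df["truth"]) <= zcrit * df["se"]).astype(float)
    out = (
        df.groupby(["part", "term"], sort=False)
        .agg(
            truth=("truth", "mean"),
            mean_estimate=("estimate", "mean"),
            empirical_sd=("estimate", "std"),
            mean_se=("se", "mean"),
            coverage=("covered", "mean"),
            n_reps=("rep", "count"),
        )
        .reset_index()
    )
    out["bias"] = out["mean_estimate"] - out["truth"]
    if n_reps == 1:
        out["coverage"] = np.nan  # undefined with a single replicate
    out.attrs["n_failures"] = failures
    return out
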