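import numpy as np
import pytest

from zigrow.model_design import FULL_COLUMNS, ScalingInfo, fixed_effect_rows
from zigrow.prediction import (
    PredictionRequest,
    mcmt_grid,
    predict_components,
    reaction_norm,
    transfer_distance_view,
)
from zigrow.zig_engine import FittedZIG, ZIGParameters

UNIT_SCALING = ScalingInfo(
    divisors={"garden_mcmt": 1.0, "home_mcmt": 1.0, "pc1": 1.0, "pc2": 1.0, "pc3": 1.0}
)


def manual_fit(beta_cond, beta_zi=None, columns=FULL_COLUMNS, scaling=None, sigma=0.5,
               re_modes=None):
    """Construct a FittedZIG directly from coefficients (no fitting)."""
    beta_cond = np.asarray(beta_cond, float)
    has_zi = beta_zi is not None
    return FittedZIG(
        params=ZIGParameters(
            beta_cond=beta_cond,
            beta_zi=None if beta_zi is None else np.asarray(beta_zi, float),
            sigma_resid=sigma,
            re_sd_cond={"genotype": 0.3},
            re_sd_zi={"genotype": 0.2} if has_zi else None,
        ),
        vcov_fixed=None,
        re_modes=re_modes or {},
        loglik=0.0,
        converged=True,
        n_obs=100,
        scaling=scaling or UNIT_SCALING,
        spec=None,
        columns=tuple(columns),
        columns_zi=tuple(columns) if has_zi else (),
    )


GENO = {
    "genotype_id": "G1",
    "home_mcmt": -10.0,
    "pc1": 1.0,
    "pc2": -0.5,
    "pc3": 0.2,
    "ancestry_q": 0.4,
}


def test_eta_is_exact_dot_product():
    rng = np.random.default_rng(0)
    beta = rng.normal(size=18) / 100.0
    fit = manual_fit(beta, beta_zi=np.zeros(18))
    req = PredictionRequest(garden_mcmt=3.0, home_mcmt=-10.0, pc1=1.0, pc2=-0.5, pc3=0.2)
    comp = predict_components(fit, req)
    row = fixed_effect_rows(
        FULL_COLUMNS, UNIT_SCALING, 3.0, home_mcmt=-10.0, pc1=1.0, pc2=-0.5, pc3=0.2
    )[0]
    assert comp.eta_cond[0] == pytest.approx(float(row @ beta), abs=1e-12)


def test_mixture_identities():
    beta = np.zeros(18)
    fit = manual_fit(beta, beta_zi=np.r_[-50.0, np.zeros(17)])
    req = PredictionRequest(garden_mcmt=0.0, home_mcmt=-5.0, pc1=0.0, pc2=0.0, pc3=0.0)
    comp = predict_components(fit, req)
    # p = 0 -> overall equals growth_response exactly
    assert comp.p_mortality[0] == pytest.approx(0.0, abs=1e-20)
    assert comp.overall[0] == comp.growth_response[0]
    # all-zero betas -> eta 0, growth 0 under exp(eta)-1, p = logistic(0)
    fit2 = manual_fit(beta, beta_zi=np.zeros(18))
    comp2 = predict_components(fit2, req)
    assert comp2.eta_cond[0] == 0.0
    assert comp2.growth_response[0] == 0.0
    assert comp2.p_mortality[0] == pytest.approx(0.5)


def test_grid_construction():
    grid = mcmt_grid(-23.9, 9.8, 100)
    assert len(grid) == 100
    assert grid[0] == -23.9 and grid[-1] == 9.8
    assert np.allclose(np.diff(grid), 33.7 / 99)
    assert np.all(np.diff(grid) > 0)


def test_optimum_matches_parabola_vertex():
    # conditional part: eta = 0.8 g - 0.3 g^2 on the raw axis -> vertex 4/3
    beta = np.zeros(18)
    beta[FULL_COLUMNS.index("g")] = 0.8
    beta[FULL_COLUMNS.index("g2")] = -0.3
    fit = manual_fit(beta, beta_zi=np.r_[-50.0, np.zeros(17)])
    nm = reaction_norm(fit, GENO, -23.9, 9.8, 100)
    vertex = 0.8 / (2 * 0.3)
    step = 33.7 / 99
    assert abs(nm.t_opt_growth - vertex) <= step
    assert abs(nm.t_opt_overall - vertex) <= step
    # a scaled garden axis changes nothing after unscaling
    scaling = ScalingInfo(divisors={**UNIT_SCALING.divisors, "garden_mcmt": 9.7})
    fit2 = manual_fit(beta, beta_zi=np.r_[-50.0, np.zeros(17)], scaling=scaling)
    nm2 = reaction_norm(fit2, GENO, -23.9, 9.8, 100)
    vertex2 = 9.7 * 0.8 / (2 * 0.3)  # vertex on the raw axis, beta on scaled
    assert vertex2 > 9.8  # outside the grid: argmax clamps to the hot edge
    assert nm2.t_opt_growth == pytest.approx(9.8)


def test_mortality_is_u_shaped_for_convex_logit():
    beta_zi = np.zeros(18)
    beta_zi[FULL_COLUMNS.index("g")] = -0.05
    beta_zi[FULL_COLUMNS.index("g2")] = 0.02
    fit = manual_fit(np.zeros(18), beta_zi=beta_zi)
    nm = reaction_norm(fit, GENO, -23.9, 9.8, 100)
    d = np.diff(nm.p_mortality)
    sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
    assert sign_changes == 1  # decreasing then increasing
    assert np.all((nm.p_mortality >= 0) & (nm.p_mortality <= 1))


def test_overall_never_exceeds_growth(small_fit, small_trial):
    data, _ = small_trial
    geno = data.genotypes.iloc[0]
    nm = reaction_norm(small_fit, geno, -23.9, 9.8, 100)
    pos = nm.growth_response > 0
    assert np.all(nm.overall[pos] <= nm.growth_response[pos] + 1e-12)
    assert np.allclose(nm.overall, (1 - nm.p_mortality) * nm.growth_response)


def test_grid_refinement_stability(small_fit, small_trial):
    data, _ = small_trial
    geno = data.genotypes.iloc[3]
    coarse = reaction_norm(small_fit, geno, -23.9, 9.8, 100)
    fine = reaction_norm(small_fit, geno, -23.9, 9.8, 200)
    coarse_step = 33.7 / 99
    assert abs(fine.t_opt_overall - coarse.t_opt_overall) <= coarse_step
    assert abs(fine.t_opt_growth - coarse.t_opt_growth) <= coarse_step


def test_fixed_effect_predictions_ignore_unknown_levels():
    beta = np.arange(18) / 10.0
    fit_a = manual_fit(beta, beta_zi=np.zeros(18), re_modes={})
    fit_b = manual_fit(
        beta,
        beta_zi=np.zeros(18),
        re_modes={"cond": {"genotype": {"G1": 5.0}}, "zi": {"genotype": {"G1": 1.0}}},
    )
    req = PredictionRequest(garden_mcmt=2.0, home_mcmt=-8.0, pc1=0.3, pc2=0.1, pc3=0.0)
    assert predict_components(fit_a, req).eta_cond[0] == pytest.approx(
        predict_components(fit_b, req).eta_cond[0]
    )
    # with random effects requested, the known genotype mode shifts eta
    req_re = PredictionRequest(
        garden_mcmt=2.0, home_mcmt=-8.0, pc1=0.3, pc2=0.1, pc3=0.0,
        include_random_effects=True, genotype_id="G1",
    )
    assert predict_components(fit_b, req_re).eta_cond[0] == pytest.approx(
        predict_components(fit_a, req).eta_cond[0] + 5.0
    )
    # unknown level contributes zero deviation
    req_new = PredictionRequest(
        garden_mcmt=2.0, home_mcmt=-8.0, pc1=0.3, pc2=0.1, pc3=0.0,
        include_random_effects=True, genotype_id="NEW",
    )
    assert predict_components(fit_b, req_new).eta_cond[0] == pytest.approx(
        predict_components(fit_a, req).eta_cond[0]
    )


def test_transfer_distance_view():
    beta = np.zeros(18)
    beta[FULL_COLUMNS.index("g")] = 0.5
    beta[FULL_COLUMNS.index("g2")] = -0.1
    fit = manual_fit(beta, beta_zi=np.r_[-50.0, np.zeros(17)])
    nm = reaction_norm(fit, GENO, -23.9, 9.8, 100)
    view = transfer_distance_view(nm, home_mcmt=-10.0)
    i = np.argmin(np.abs(nm.grid + 10.0))
    assert view["transfer_distance"].iloc[i] == pytest.approx(nm.grid[i] + 10.0)
    assert np.all(np.diff(view["transfer_distance"]) > 0)  # order preserved
    # optimum warmer than home -> argmax at positive transfer distance
    best = view.loc[view["overall"].idxmax()]
    assert (nm.t_opt_overall > -10.0) == (best["transfer_distance"] > 0)


def test_extrapolation_guard_warns():
    fit = manual_fit(np.zeros(18), beta_zi=np.zeros(18))
    req = PredictionRequest(garden_mcmt=50.0, home_mcmt=-5.0, pc1=0, pc2=0, pc3=0)
    with pytest.warns(RuntimeWarning, match="extrapolation"):
        predict_components(fit, req, guard_bounds=(-16.5, 9.8))
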