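import numpy as np
import pandas as pd
import pytest

from zigrow.errors import PairingError
from zigrow.evaluation import (
    EvalConfig,
    compare_model_variants,
    leave_one_garden_out,
    prediction_ability,
)
from zigrow.model_design import ModelSpec, build_design
from zigrow.synthetic_data import SimConfig, simulate_trial
from zigrow.trial_data import subset_gardens
from zigrow.zig_engine import FitControl, fit_zig


class TestPredictionAbility:
    def test_self_and_reflected_correlation(self):
        obs = np.array([1.0, 2.0, 3.0, 5.0])
        assert prediction_ability(obs, obs).r == pytest.approx(1.0)
        assert prediction_ability(obs, -obs).r == pytest.approx(-1.0)

    def test_zero_exclusion_example(self):
        obs = [0.0, 2.0, 4.0, 6.0]
        pred = [9.0, 1.0, 2.0, 3.0]
        out = prediction_ability(obs, pred, exclude_zero_observed=True)
        assert out.r == pytest.approx(1.0)
        assert out.n == 3

    def test_constant_vector_is_undefined_not_zero(self):
        out = prediction_ability([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert out.undefined and np.isnan(out.r)
        out2 = prediction_ability([0.0, 0.0, 1.0, 2.0], [1.0, 2.0, 3.0, 4.0],
                                  exclude_zero_observed=True)
        assert out2.undefined and out2.n == 2


@pytest.fixture(scope="module")
def cv_setup():
    cfg = SimConfig(
        n_genotypes=10,
        n_gardens=5,
        re_sd_cond={k: 0.2 for k in ("genotype", "garden", "block", "year", "individual")},
        re_sd_zi={k: 0.1 for k in ("genotype", "garden", "block", "year", "individual")},
    )
    data, truth = simulate_trial(cfg, 21)
    return data, truth


def test_fold_structure_and_counts(cv_setup):
    data, _ = cv_setup
    spec = ModelSpec(variant="full")
    res = leave_one_garden_out(
        data, spec, EvalConfig(with_random_effects=(False,), control=FitControl(compute_vcov=False))
    )
    n_gardens = data.observations["garden_id"].nunique()
    n_years = data.observations["year"].nunique()
    assert len(res) == n_gardens * n_years
    assert not res["failed"].any()
    assert res["pearson_r_conditional"].between(-1, 1).all()
    assert (res["n_predicted"] > 2).all()


def test_holdout_exclusion_by_construction(cv_setup):
    """Perturbing the held-out garden's responses leaves the fold fit (and
    hence its predictions) bit-identical."""
    data, _ = cv_setup
    gardens = sorted(data.observations["garden_id"].unique())
    held_out = gardens[0]
    train_ids = [g for g in gardens if g != held_out]
    control = FitControl(compute_vcov=False)
    spec = ModelSpec(variant="full")

    fit1 = fit_zig(build_design(subset_gardens(data, train_ids), spec), control)
    perturbed = data.copy()
    mask = perturbed.observations["garden_id"] == held_out
    perturbed.observations.loc[mask, "growth_increment_cm"] *= 10.0
    fit2 = fit_zig(build_design(subset_gardens(perturbed, train_ids), spec), control)

    assert np.array_equal(fit1.params.beta_cond, fit2.params.beta_cond)
    assert np.array_equal(fit1.params.beta_zi, fit2.params.beta_zi)
    assert fit1.loglik == fit2.loglik


def test_noiseless_data_predicts_almost_perfectly():
    cfg = SimConfig(
        n_genotypes=10,
        n_gardens=6,
        sigma_resid=0.01,
        re_sd_cond={k: 0.0 for k in ("genotype", "garden", "block", "year", "individual")},
        re_sd_zi={k: 0.0 for k in ("genotype", "garden", "block", "year", "individual")},
        beta_zi={"intercept": -30.0},
        calibrate_zero_fraction=False,
    )
    data, _ = simulate_trial(cfg, 5)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zi pinned: no zeros
        res = leave_one_garden_out(
            data,
            ModelSpec(variant="full"),
            EvalConfig(with_random_effects=(False,), control=FitControl(compute_vcov=False)),
        )
    assert float(res["pearson_r_conditional"].median()) >= 0.99


class TestVariantComparison:
    def _cv_frame(self, values):
        n = len(values)
        return pd.DataFrame(
            {
                "garden_id": [f"S{i % 4}" for i in range(n)],
                "year": [2021 + i // 4 for i in range(n)],
                "pearson_r_conditional": values,
            }
        )

    def test_uniform_shift_has_exact_signed_rank_p(self):
        a = self._cv_frame([0.3, 0.4, 0.5, 0.35, 0.45, 0.55, 0.6, 0.25])
        b = self._cv_frame([v + 0.1 for v in a["pearson_r_conditional"]])
        out = compare_model_variants(a, b)
        assert out.n_pairs == 8
        assert out.p == pytest.approx(0.0078125, abs=1e-12)  # 2/256

    def test_identical_results_are_degenerate(self):
        a = self._cv_frame([0.3, 0.4, 0.5, 0.35, 0.45, 0.55])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            out = compare_model_variants(a, a.copy())
        assert out.p == 1.0
        assert out.degenerate
        assert out.n_zero_diffs == 6

    def test_sign_balanced_differences_are_null(self):
        # binary-exact values so the six differences are exactly +-0.25
        base = [0.0, 0.5, 1.0, 0.25, 0.75, 1.25]
        delta = [0.25, -0.25, 0.25, -0.25, 0.25, -0.25]
        a = self._cv_frame(base)
        b = self._cv_frame([v + d for v, d in zip(base, delta)])
        out = compare_model_variants(a, b)
        assert out.p == pytest.approx(1.0)

    def test_disjoint_keys_raise(self):
        a = self._cv_frame([0.3, 0.4, 0.5, 0.35])
        b = self._cv_frame([0.3, 0.4, 0.5, 0.35])
        b["garden_id"] = ["X1", "X2", "X3", "X4"]
        with pytest.raises(PairingError):
            compare_model_variants(a, b)
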