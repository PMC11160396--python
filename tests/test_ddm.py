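"""Full DDM density, contaminant mixture and hierarchy fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad as _quad

from skillfit.ddm import (
    ContaminantSpec,
    DDMModelSpec,
    DDMParams,
    DiffusionModel,
    QuadratureConfig,
    ddm_density,
    ddm_model_hierarchy,
    mixture_loglik,
    response_probability,
)
from skillfit.wiener import wiener_fpt_density

from conftest import FAST_DDM_OPT, FIT_QUAD, TRUE_DDM, make_ddm_condition_data


def test_density_reduces_to_wiener_without_variability():
    p = DDMParams(v=1.5, a=1.2, t0=0.3)
    t = np.linspace(0.31, 3.0, 100)
    full = ddm_density(t, "upper", p)
    pure = wiener_fpt_density(t - 0.3, 1.5, 1.2, 0.5, "upper")
    np.testing.assert_allclose(full, pure, atol=1e-10)


def test_density_mass_conserved_under_mixing():
    p = DDMParams(v=2.0, a=1.5, t0=0.3, sv=0.8, sz=0.3, st0=0.1)
    total = sum(
        _quad(lambda t: float(ddm_density([t], b, p)[0]), 0.0, 60.0, limit=400)[0]
        for b in ("upper", "lower")
    )
    assert abs(total - 1.0) < 1e-3


def test_density_positive_and_zero_before_nondecision():
    p = DDMParams(v=2.0, a=1.0, t0=0.30, sv=1.0, sz=0.2, st0=0.1)
    assert float(ddm_density([0.20], "upper", p)[0]) == 0.0
    assert float(ddm_density([0.60], "upper", p)[0]) > 0.0


def test_choice_probability_increases_with_drift():
    probs = [
        response_probability(DDMParams(v=v, a=1.2, t0=0.3, sv=0.5), "upper")
        for v in (0.0, 0.5, 1.0, 2.0, 4.0)
    ]
    assert all(b > a for a, b in zip(probs, probs[1:]))


def test_param_validation():
    with pytest.raises(ValueError):
        DDMParams(v=1, a=0, t0=0.3)
    with pytest.raises(ValueError):
        DDMParams(v=1, a=1, t0=0.3, sz=1.5)
    with pytest.raises(ValueError):
        DDMParams(v=1, a=1, t0=0.1, st0=0.3)


def test_hierarchy_specs_and_k():
    specs = ddm_model_hierarchy()
    assert len(specs) == 8
    assert specs[0].k() == 12 and specs[-1].k() == 6
    assert specs[-1].name == "none"
    v_only = next(s for s in specs if s.name == "v")
    assert v_only.k() == 8  # v and sv both doubled


def test_mixture_collapses_without_contaminants():
    trials = pd.DataFrame(
        {"rt": [0.5, 0.7, 0.9], "accuracy": [1, 1, 0], "instruction": ["F"] * 3}
    )
    p = {"F": DDMParams(v=2, a=1, t0=0.3)}
    sll0 = mixture_loglik(trials, p, ContaminantSpec(proportion=0.0))
    dens = [
        float(ddm_density([rt], "upper" if acc else "lower", p["F"])[0])
        for rt, acc in zip(trials["rt"], trials["accuracy"])
    ]
    assert abs(sll0 - np.sum(np.log(dens))) < 1e-10


def test_mixture_floor_for_implausibly_fast_trial():
    # rt below the non-decision window has zero DDM density, so the
    # likelihood is exactly p * 0.5 / range = 0.05 * 0.5 / 1.0
    trials = pd.DataFrame({"rt": [0.1], "accuracy": [1], "instruction": ["F"]})
    p = {"F": DDMParams(v=2, a=1, t0=0.3)}
    sll = mixture_loglik(
        trials, p, ContaminantSpec(proportion=0.05, rt_min=0.3, rt_max=1.3)
    )
    assert abs(np.exp(sll) - 0.025) < 1e-12


def test_duplicating_trials_doubles_loglik():
    trials = pd.DataFrame(
        {"rt": [0.5, 0.8], "accuracy": [1, 0], "instruction": ["F", "F"]}
    )
    p = {"F": DDMParams(v=2, a=1, t0=0.3, sv=0.5)}
    spec = ContaminantSpec(proportion=0.05, rt_min=0.3, rt_max=1.3)
    sll1 = mixture_loglik(trials, p, spec)
    sll2 = mixture_loglik(pd.concat([trials, trials]), p, spec)
    assert abs(sll2 - 2 * sll1) < 1e-9


def test_mixture_rejects_bad_rts_and_zero_range():
    p = {"F": DDMParams(v=2, a=1, t0=0.3)}
    bad = pd.DataFrame({"rt": [6.0], "accuracy": [1], "instruction": ["F"]})
    with pytest.raises(ValueError):
        mixture_loglik(bad, p)
    const = pd.DataFrame({"rt": [0.5] * 4, "accuracy": [1] * 4, "instruction": ["F"] * 4})
    with pytest.raises(ValueError):
        mixture_loglik(const, p)


def test_likelihood_at_truth_beats_perturbed_drift():
    for seed in (0, 1, 2):
        trials = make_ddm_condition_data(400, seed=seed)
        model = DiffusionModel(trials, quad=FIT_QUAD)
        truth = {c: TRUE_DDM for c in ("F", "I+F")}
        worse = {
            c: DDMParams(
                v=TRUE_DDM.v * 1.25,
                a=TRUE_DDM.a,
                t0=TRUE_DDM.t0,
                sv=TRUE_DDM.sv,
                sz=TRUE_DDM.sz,
                st0=TRUE_DDM.st0,
            )
            for c in ("F", "I+F")
        }
        assert model.loglike(truth) > model.loglike(worse)


def test_quadrature_convergence_at_default_nodes():
    # doubling the node counts moves the SLL by < 0.01 on a synthetic set
    trials = make_ddm_condition_data(200, seed=3)
    truth = {c: TRUE_DDM for c in ("F", "I+F")}
    default = QuadratureConfig()
    doubled = QuadratureConfig(
        2 * default.n_drift, 2 * default.n_start, 2 * default.n_t0
    )
    sll1 = DiffusionModel(trials, quad=default).loglike(truth)
    sll2 = DiffusionModel(trials, quad=doubled).loglike(truth)
    assert abs(sll1 - sll2) < 0.01


def test_single_condition_rejects_freeing_spec():
    trials = make_ddm_condition_data(80, seed=4)
    one = trials[trials["instruction"] == "F"]
    model = DiffusionModel(one, quad=FIT_QUAD)
    with pytest.raises(ValueError):
        model.fit(DDMModelSpec(frozenset({"v"})))


def test_too_few_trials_rejected():
    trials = make_ddm_condition_data(5, seed=5)
    with pytest.raises(ValueError):
        DiffusionModel(trials, quad=FIT_QUAD).fit(DDMModelSpec())


def test_fit_recovers_main_parameters():
    # single-condition recovery at a liberal trial count
    trials = make_ddm_condition_data(1000, seed=6)
    one = trials[trials["instruction"] == "F"].drop(columns=["instruction"])
    model = DiffusionModel(one, quad=FIT_QUAD)
    fit = model.fit(DDMModelSpec(), optimizer=FAST_DDM_OPT, seed=7)
    got = fit.params_by_condition["all"]
    assert abs(got.v - TRUE_DDM.v) / TRUE_DDM.v < 0.15
    assert abs(got.a - TRUE_DDM.a) / TRUE_DDM.a < 0.15
    assert abs(got.t0 - TRUE_DDM.t0) / TRUE_DDM.t0 < 0.15
    assert fit.n == 1000 and fit.k == 6 and np.isfinite(fit.bic)


def test_tied_parameters_identical_across_conditions():
    trials = make_ddm_condition_data(120, seed=8)
    fit = DiffusionModel(trials, quad=FIT_QUAD).fit(
        DDMModelSpec(frozenset({"v"})), optimizer=FAST_DDM_OPT, seed=9
    )
    pf, pi = fit.params_by_condition["F"], fit.params_by_condition["I+F"]
    assert pf.a == pi.a and pf.t0 == pi.t0 and pf.sz == pi.sz and pf.st0 == pi.st0
    assert fit.k == 8
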