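"""BIC arithmetic, weights, model averaging and group Bayes factors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from skillfit.ddm import DDMModelSpec, DDMParams
from skillfit.learning_curve import CurveFit, CurveModelSpec, CurveParams
from skillfit.model_selection import (
    ModelComparison,
    bic_from_sll,
    bic_from_sse,
    bic_weights,
    group_bayes_factor,
    model_average,
)


def test_bic_from_sse_closed_forms():
    # n ln(SSE/n) vanishes at SSE = n, leaving k ln(n)
    assert abs(bic_from_sse(3, 100, 100.0) - 3 * np.log(100)) < 1e-10
    assert abs(bic_from_sse(3, 100, 100.0) - 13.815510557964274) < 1e-10
    assert abs(bic_from_sse(3, 100, 4.0) - (-308.0720719288558)) < 1e-9
    # linear in k with slope ln(n)
    assert abs(
        (bic_from_sse(4, 100, 4.0) - bic_from_sse(3, 100, 4.0)) - np.log(100)
    ) < 1e-12


def test_bic_from_sse_rejects_zero_sse():
    with pytest.raises(ValueError):
        bic_from_sse(3, 100, 0.0)
    with pytest.raises(ValueError):
        bic_from_sse(3, 0, 1.0)


def test_bic_from_sll_closed_forms():
    assert abs(bic_from_sll(6, 160, 0.0) - 6 * np.log(160)) < 1e-10
    assert abs(bic_from_sll(6, 160, 0.0) - 30.45104289140296) < 1e-10
    assert abs((bic_from_sll(6, 160, 1.0) - bic_from_sll(6, 160, 0.0)) - (-2.0)) < 1e-12
    assert bic_from_sll(0, 10, -5.0) == 10.0


def test_bic_monotonicity():
    assert bic_from_sse(3, 50, 2.0) < bic_from_sse(3, 50, 3.0)
    assert bic_from_sll(3, 50, 10.0) < bic_from_sll(3, 50, 9.0)


def test_equal_bics_give_equal_weights():
    w = bic_weights([12.0, 12.0, 12.0])
    np.testing.assert_allclose(w, 1 / 3)


def test_delta_two_gives_logistic_weights():
    w = bic_weights([0.0, 2.0])
    np.testing.assert_allclose(w, [0.7310585786300049, 0.2689414213699951], atol=1e-12)


def test_weights_stable_under_huge_bics():
    w = bic_weights([1e6, 1e6 + 2])
    np.testing.assert_allclose(w, [0.7310585786300049, 0.2689414213699951], atol=1e-12)


@given(st.lists(st.floats(-500, 500), min_size=1, max_size=10))
def test_weights_sum_to_one_and_are_nonnegative(bics):
    w = bic_weights(bics)
    assert abs(w.sum() - 1.0) < 1e-10
    assert np.all(w >= 0)


def test_weight_ratio_identity():
    bics = [10.0, 13.7, 8.2, 25.0]
    w = bic_weights(bics)
    for i in range(4):
        for j in range(4):
            assert abs(w[i] / w[j] - np.exp(-(bics[i] - bics[j]) / 2)) < 1e-10


def test_nonfinite_bic_rejected():
    with pytest.raises(ValueError):
        bic_weights([1.0, np.inf])


def _curve_fit(spec_names, bic, params, n=100):
    spec = CurveModelSpec(frozenset(spec_names))
    return CurveFit(
        spec=spec,
        params_by_condition={c: params for c in ("F", "I+F")},
        sse=1.0,
        n=n,
        k=spec.k(),
        bic=bic,
    )


def _comparison(bics, values, n=100):
    fits = [
        _curve_fit(set(), b, CurveParams(v, 0.1, 0.1), n=n) for b, v in zip(bics, values)
    ]
    # distinct specs are irrelevant for averaging identities; reuse none spec
    return ModelComparison(participant_id="p", fits=fits)


def test_model_average_simple_cases():
    comp = _comparison([10.0, 10.0], [1.0, 2.0])
    assert abs(model_average(comp, "RT0", "F") - 1.5) < 1e-12
    comp = _comparison([0.0, 1e4], [0.42, 3.0])
    assert abs(model_average(comp, "RT0", "F") - 0.42) < 1e-12


def test_model_average_weighted_dot_product():
    # weights (0.8, 0.15, 0.05) x values (0.50, 0.55, 0.70) = 0.5175
    w = np.array([0.8, 0.15, 0.05])
    bics = -2 * np.log(w)  # exact inverse of the weight construction
    comp = _comparison(list(bics), [0.50, 0.55, 0.70])
    assert abs(model_average(comp, "RT0", "F") - 0.5175) < 1e-10


def test_model_average_bounded_by_extremes():
    comp = _comparison([3.0, 5.0, 4.0], [0.3, 0.9, 0.6])
    avg = model_average(comp, "RT0", "F")
    assert 0.3 <= avg <= 0.9


def test_comparison_requires_shared_n():
    fits = [
        _curve_fit(set(), 1.0, CurveParams(0.5, 0.1, 0.1), n=100),
        _curve_fit({"B"}, 2.0, CurveParams(0.5, 0.1, 0.1), n=99),
    ]
    with pytest.raises(ValueError):
        ModelComparison(participant_id="p", fits=fits)


def _two_model_comparison(w_a, name_b="B"):
    # build BICs that produce weight w_a for the none model exactly
    b_a = -2 * np.log(w_a)
    b_b = -2 * np.log(1 - w_a)
    fits = [
        _curve_fit(set(), b_a, CurveParams(0.5, 0.1, 0.1)),
        _curve_fit({name_b}, b_b, CurveParams(0.5, 0.1, 0.1)),
    ]
    return ModelComparison(participant_id="p", fits=fits)


def test_group_bf_equal_weights_is_one():
    comps = [_two_model_comparison(0.5) for _ in range(3)]
    assert abs(group_bayes_factor(comps, "none", "B") - 1.0) < 1e-10


def test_group_bf_symmetric_means_is_one():
    comps = [_two_model_comparison(0.6 / 0.8), _two_model_comparison(0.2 / 0.8)]
    # per-participant none-weights 0.75 and 0.25 vs B-weights 0.25 and 0.75
    assert abs(group_bayes_factor(comps, "none", "B") - 1.0) < 1e-10


def test_group_bf_single_participant_equals_weight_ratio():
    comp = _two_model_comparison(0.7)
    bf = group_bayes_factor([comp], "none", "B")
    b_none = comp.fits[0].bic
    b_b = comp.fits[1].bic
    assert abs(bf - np.exp(-(b_none - b_b) / 2)) < 1e-9


def test_group_bf_zero_denominator_warns_inf():
    # dBIC so large that the underdog's weight underflows to exactly zero
    fits = [
        _curve_fit(set(), 0.0, CurveParams(0.5, 0.1, 0.1)),
        _curve_fit({"B"}, 4000.0, CurveParams(0.5, 0.1, 0.1)),
    ]
    comp = ModelComparison(participant_id="p", fits=fits)
    with pytest.warns(RuntimeWarning):
        assert group_bayes_factor([comp], "none", "B") == np.inf


def test_model_average_works_on_ddm_fits():
    from skillfit.ddm import DDMFit

    fits = []
    for bic, v in ((10.0, 4.0), (12.0, 6.0)):
        fits.append(
            DDMFit(
                spec=DDMModelSpec(frozenset()),
                params_by_condition={
                    c: DDMParams(v=v, a=1.2, t0=0.3) for c in ("F", "I+F")
                },
                sll=-100.0,
                n=160,
                k=6,
                bic=bic,
            )
        )
    comp = ModelComparison(participant_id="p", fits=fits)
    avg = model_average(comp, "v", "F")
    w = bic_weights([10.0, 12.0])
    assert abs(avg - (w[0] * 4.0 + w[1] * 6.0)) < 1e-12
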