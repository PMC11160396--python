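"""Residual-learning LLR, DDM evidence ratio, quantile summaries."""

import numpy as np
import pandas as pd
import pytest

from skillfit.ddm import DDMFit, DDMModelSpec, DDMParams, ddm_model_hierarchy
from skillfit.diagnostics import (
    condition_param_diff,
    llr_ddm,
    llr_slope,
    qq_table,
    rt_quantiles,
)
from skillfit.model_selection import ModelComparison
from skillfit.synthetic import simulate_ddm_trials


def _trials(rt, rep):
    return pd.DataFrame({"rt": rt, "repetition": rep})


def _gaussian_llr_oracle(rt, rep):
    """Brute-force two-likelihood computation of the slope LLR."""
    rt, rep = np.asarray(rt, float), np.asarray(rep, float)
    n = rt.size

    def loglik(resid):
        s2 = np.mean(resid**2)
        return -0.5 * n * (np.log(2 * np.pi * s2) + 1)

    X = np.column_stack([np.ones(n), rep])
    beta = np.linalg.lstsq(X, rt, rcond=None)[0]
    l1 = loglik(rt - X @ beta)
    l0 = loglik(rt - rt.mean())
    llr = l1 - l0
    return llr if beta[1] < 0 else -llr


def test_llr_zero_when_no_trend():
    # flat means with symmetric residuals: slope exactly 0
    rep = np.repeat(np.arange(30, 40), 2)
    rt = np.tile([0.5, 0.7], 10)
    assert abs(llr_slope(_trials(rt, rep))) < 1e-10


def test_llr_positive_and_growing_for_decreasing_rts():
    vals = []
    for K in (5, 10, 20):
        rep = np.arange(K, dtype=float)
        rt = 1.0 - 0.01 * rep + 0.001 * np.sin(rep * 12.9898)  # deterministic jitter
        vals.append(llr_slope(_trials(rt, rep)))
    assert vals[0] > 0
    assert vals[0] < vals[1] < vals[2]


def test_llr_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    rep = np.repeat(np.arange(30, 40), 16)  # 10 repetitions x 16 stimuli
    rt = 0.9 - 0.005 * rep + rng.normal(0, 0.1, rep.size)
    got = llr_slope(_trials(rt, rep))
    want = _gaussian_llr_oracle(rt, rep)
    assert abs(got - want) < 1e-6


def test_llr_location_invariant():
    rng = np.random.default_rng(1)
    rep = np.repeat(np.arange(10), 8)
    rt = 0.8 - 0.004 * rep + rng.normal(0, 0.05, rep.size)
    a = llr_slope(_trials(rt, rep))
    b = llr_slope(_trials(rt + 3.0, rep))
    assert abs(a - b) < 1e-9


def test_llr_degenerate_inputs_raise():
    with pytest.raises(ValueError):
        llr_slope(_trials([0.5] * 6, [1, 1, 2, 2, 3, 3]))  # constant RT
    with pytest.raises(ValueError):
        llr_slope(_trials([0.5, 0.6, 0.7, 0.8], [1, 1, 2, 2]))  # < 3 rep values


def _ddm_comparison(weights):
    """Build an 8-spec comparison with the requested BIC weights."""
    weights = np.asarray(weights, float)
    bics = -2 * np.log(weights)
    fits = []
    for spec, bic in zip(ddm_model_hierarchy(), bics):
        fits.append(
            DDMFit(
                spec=spec,
                params_by_condition={
                    c: DDMParams(v=2, a=1, t0=0.3) for c in ("F", "I+F")
                },
                sll=-10.0,
                n=160,
                k=spec.k(),
                bic=float(bic),
            )
        )
    return ModelComparison(participant_id="p", fits=fits)


def test_llr_ddm_uniform_weights_is_log7():
    comp = _ddm_comparison(np.full(8, 1 / 8))
    assert abs(llr_ddm(comp) - np.log(7)) < 1e-10


def test_llr_ddm_even_split_is_zero():
    w = np.full(8, 0.5 / 7)
    w[-1] = 0.5  # the none spec is last in the hierarchy
    comp = _ddm_comparison(w)
    assert abs(llr_ddm(comp)) < 1e-10


def test_llr_ddm_dominant_none_is_strongly_negative():
    w = np.full(8, 0.005 / 7)
    w[-1] = 0.995
    comp = _ddm_comparison(w)
    assert llr_ddm(comp) < -4


def test_llr_ddm_definition_identity():
    w = np.array([0.1, 0.05, 0.02, 0.03, 0.3, 0.05, 0.05, 0.4])
    comp = _ddm_comparison(w)
    w_none = comp.weight_of("none")
    assert abs(llr_ddm(comp) + np.log(w_none) - np.log(1 - w_none)) < 1e-10


def test_quantiles_midpoint_and_constant():
    df = pd.DataFrame({"rt": np.arange(1, 10) / 10.0, "accuracy": 1})
    (s,) = rt_quantiles(df)
    assert abs(s.quantile_rts[2] - 0.5) < 1e-12  # median of 0.1..0.9
    df = pd.DataFrame({"rt": [0.42] * 9, "accuracy": 1})
    (s,) = rt_quantiles(df)
    np.testing.assert_allclose(s.quantile_rts, 0.42)


def test_quantiles_permutation_invariant():
    rng = np.random.default_rng(3)
    rt = rng.random(50) + 0.3
    df1 = pd.DataFrame({"rt": rt, "accuracy": 1})
    df2 = df1.sample(frac=1.0, random_state=1)
    (a,) = rt_quantiles(df1)
    (b,) = rt_quantiles(df2)
    np.testing.assert_array_equal(a.quantile_rts, b.quantile_rts)


def test_quantiles_skip_sparse_class_with_warning():
    df = pd.DataFrame({"rt": [0.5] * 20 + [0.4], "accuracy": [1] * 20 + [0]})
    with pytest.warns(RuntimeWarning):
        out = rt_quantiles(df)
    assert len(out) == 1 and out[0].response_class == "correct"


def test_observed_quantiles_match_inverted_model_cdf():
    # large simulated sample vs numerically inverted analytic CDF
    p = DDMParams(v=2.5, a=1.0, t0=0.3, sv=0.8, sz=0.25, st0=0.1)
    sim = simulate_ddm_trials(100000, p, seed=21, dt=1e-4)
    table = qq_table(sim, p)
    corr = table[table["response_class"] == "correct"]
    assert np.max(np.abs(corr["observed_rt"] - corr["predicted_rt"])) < 0.01


def test_condition_diff_zero_and_antisymmetric():
    table = pd.DataFrame(
        {
            "participant": ["p1", "p1", "p2", "p2", "p3", "p3"],
            "condition": ["F", "I+F"] * 3,
            "v": [4.0, 4.5, 5.0, 4.8, 5.5, 5.5],
        }
    )
    out = condition_param_diff(table, ["v"])
    p3 = out[out["participant"] == "p3"]["normalized_diff"].iloc[0]
    assert abs(p3) < 1e-12  # identical conditions
    swapped = table.copy()
    swapped["condition"] = swapped["condition"].map({"F": "I+F", "I+F": "F"})
    out2 = condition_param_diff(swapped, ["v"])
    merged = out.merge(out2, on="participant", suffixes=("_a", "_b"))
    np.testing.assert_allclose(
        merged["normalized_diff_a"], -merged["normalized_diff_b"], atol=1e-12
    )


def test_condition_diff_matches_spreadsheet_oracle():
    table = pd.DataFrame(
        {
            "participant": ["p1", "p1", "p2", "p2", "p3", "p3"],
            "condition": ["F", "I+F"] * 3,
            "v": [4.0, 4.5, 5.0, 4.8, 5.5, 5.1],
        }
    )
    out = condition_param_diff(table, ["v"]).set_index("participant")
    scale = np.std([4.0, 4.5, 5.0, 4.8, 5.5, 5.1], ddof=1)
    for pid, f, i in (("p1", 4.0, 4.5), ("p2", 5.0, 4.8), ("p3", 5.5, 5.1)):
        assert abs(out.loc[pid, "normalized_diff"] - (f - i) / scale) < 1e-10


def test_condition_diff_zero_scale_raises():
    table = pd.DataFrame(
        {
            "participant": ["p1", "p1", "p2", "p2"],
            "condition": ["F", "I+F"] * 2,
            "v": [4.0] * 4,
        }
    )
    with pytest.raises(ValueError):
        condition_param_diff(table, ["v"])
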