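"""Synthetic designs and simulators: counts, curves, diffusion paths."""

import numpy as np
import pandas as pd
import pytest

from skillfit.ddm import ContaminantSpec, DDMParams, ddm_cdf
from skillfit.learning_curve import CurveParams
from skillfit.synthetic import (
    make_design,
    simulate_curve_rts,
    simulate_ddm_trials,
    simulate_experiment,
)


@pytest.mark.parametrize("mapping,blocks_per_cond", [(1, 8), (2, 4), (4, 2), (8, 1)])
def test_experiment1_design_counts(mapping, blocks_per_cond):
    design, df = make_design(1, mapping, seed=0)
    assert len(df) == 1280
    assert design.n_trials == 1280
    counts = df.groupby("stimulus").size()
    assert (counts == 40).all() and counts.size == 32
    per_cond = df.groupby("instruction")["stimulus"].nunique()
    assert (per_cond == 16).all()
    block_conds = df.groupby("block")["instruction"].agg(lambda s: s.unique().tolist())
    assert all(len(c) == 1 for c in block_conds)
    flat = [c[0] for c in block_conds]
    assert flat.count("F") == blocks_per_cond
    # alternating F / I+F blocks
    assert all(flat[i] != flat[i + 1] for i in range(len(flat) - 1))


def test_experiment1_start_block_configurable():
    _, df_if = make_design(1, 8, start_block="I+F", seed=0)
    _, df_f = make_design(1, 8, start_block="F", seed=0)
    assert df_if.loc[0, "instruction"] == "I+F"
    assert df_f.loc[0, "instruction"] == "F"


def test_experiment2_design():
    design, df = make_design(2, 8, seed=1, instruction="F")
    assert len(df) == 16 * 60 == 960
    assert (df["instruction"] == "F").all()
    assert df.groupby("stimulus").size().eq(60).all()


def test_repetition_index_contiguous_from_zero(exp1_skeleton):
    g = exp1_skeleton.groupby("stimulus")["repetition"]
    assert (g.min() == 0).all()
    assert (g.max() == 39).all()
    # contiguity: within each stimulus the sorted repetitions are 0..39
    for _, reps in g:
        assert sorted(reps) == list(range(40))


def test_invalid_design_combinations_raise():
    with pytest.raises(ValueError):
        make_design(2, 4)
    with pytest.raises(ValueError):
        make_design(1, 3)
    with pytest.raises(ValueError):
        make_design(3, 8)


def test_same_seed_identical_tables():
    a = simulate_experiment(1, 4, participants=2, seed=99, dt=1e-3)
    b = simulate_experiment(1, 4, participants=2, seed=99, dt=1e-3)
    pd.testing.assert_frame_equal(a, b)


def test_curve_rts_noiseless_closed_form(exp1_skeleton):
    params = CurveParams(RT0=0.5, B=0.4, alpha=0.0)
    df = simulate_curve_rts(exp1_skeleton, params, 1e-12, seed=0, accuracy_curve=None)
    np.testing.assert_allclose(df["rt"], 0.9, atol=1e-9)
    params = CurveParams(RT0=0.5, B=0.4, alpha=0.1)
    df = simulate_curve_rts(exp1_skeleton, params, 1e-12, seed=0, accuracy_curve=None)
    r10 = df[df["repetition"] == 10]
    np.testing.assert_allclose(r10["rt"], 0.64715177646857, atol=1e-9)


def test_flat_curve_mean_matches_asymptote(exp1_skeleton):
    sd = 0.1
    df = simulate_curve_rts(
        exp1_skeleton, CurveParams(RT0=0.6, B=0.0, alpha=0.3), sd, seed=3
    )
    for _, sub in df.groupby("repetition"):
        se = sd / np.sqrt(len(sub))
        assert abs(sub["rt"].mean() - 0.6) < 3 * se + 1e-9


def test_curve_rt_floor_and_deadline(exp1_skeleton):
    df = simulate_curve_rts(
        exp1_skeleton, CurveParams(RT0=0.2, B=0.0, alpha=0.0), 0.5, seed=4
    )
    assert (df["rt"] >= 0.15).all()
    assert (df["rt"] <= 5.0).all()


def test_ddm_sim_unbiased_drift_gives_even_choices():
    sim = simulate_ddm_trials(4000, DDMParams(v=0.0, a=1.0, t0=0.2), seed=5)
    p = sim["accuracy"].mean()
    assert abs(p - 0.5) < 3 * 0.5 / np.sqrt(4000)


def test_ddm_sim_choice_probability_closed_form():
    # P(upper) = 1 / (1 + exp(-v a)) = 0.7311 for v = a = 1
    sim = simulate_ddm_trials(20000, DDMParams(v=1.0, a=1.0, t0=0.2), seed=6)
    p = sim["accuracy"].mean()
    assert abs(p - 0.7310585786) < 3 * np.sqrt(0.731 * 0.269 / 20000)


def test_ddm_sim_mean_rt_closed_form():
    # E[T] = z (a - z) + t0 = 1.3 for v=0, a=2, t0=0.3
    sim = simulate_ddm_trials(5000, DDMParams(v=0.0, a=2.0, t0=0.3), seed=7)
    se = sim["rt"].std() / np.sqrt(len(sim))
    assert abs(sim["rt"].mean() - 1.3) < 4 * se


def test_contaminant_fraction_and_flag():
    spec = ContaminantSpec(proportion=0.08)
    sim = simulate_ddm_trials(20000, DDMParams(v=2, a=1, t0=0.3), spec, seed=8)
    frac = sim["is_contaminant"].mean()
    assert abs(frac - 0.08) < 3 * np.sqrt(0.08 * 0.92 / 20000)


def test_degenerate_boundary_rejected():
    with pytest.raises(ValueError):
        simulate_ddm_trials(10, DDMParams(v=1, a=-1, t0=0.3), seed=0)


def test_simulator_matches_analytic_density_ks():
    # pure Wiener case: KS between 50k simulated trials (dt = 1e-4) and the
    # analytic defective CDFs, on signed RTs (sign encodes the boundary)
    p = DDMParams(v=2.5, a=1.0, t0=0.3)
    sim = simulate_ddm_trials(50000, p, seed=11, dt=1e-4)
    grid = np.linspace(0.0, 5.0, 4000)
    cu = ddm_cdf(grid, "upper", p)
    cl = ddm_cdf(grid, "lower", p)
    x = np.where(sim["accuracy"] == 1, sim["rt"], -sim["rt"])
    sgrid = np.concatenate([-grid[::-1], grid])
    model = np.concatenate([(cl[-1] - cl)[::-1], cl[-1] + cu])
    emp = np.searchsorted(np.sort(x), sgrid, side="right") / len(x)
    assert np.max(np.abs(emp - model)) < 0.02


def test_full_experiment_table_schema():
    df = simulate_experiment(2, 8, participants=2, seed=1, dt=1e-3)
    assert len(df) == 2 * 960
    assert set(df["instruction"]) == {"F", "I+F"}  # between-subject alternation
    for col in ("participant", "rt", "accuracy", "repetition", "is_contaminant"):
        assert col in df.columns
    assert (df["rt"] > 0).all() and (df["rt"] <= 5.0).all()
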