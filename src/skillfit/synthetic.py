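"""Synthetic experiment designs and trial data.

Generates data with the statistical structure the analyses assume, so every
downstream stage can be exercised and validated without the behavioural
study's data:

* the two experiment designs — a within-participant design with 32 objects
  (16 per instruction condition), 40 repetitions each and alternating
  feedback-only (F) and instructed (I+F) blocks whose number depends on the
  stimulus-to-response mapping ratio (1280 trials per participant); and a
  between-participant design with 16 mappings presented 60 times each;
* RT decline following the exponential law of practice with additive
  Gaussian noise, truncated below at a floor;
* asymptotic-phase trials drawn from the full DDM (drift, start-point and
  non-decision-time variability) via Euler-Maruyama path simulation, with a
  configurable fraction of uniform contaminant trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ddm import ContaminantSpec, DDMParams
from .learning_curve import CurveParams, predict_rt

try:  # compiled path simulator; the blocked numpy version is the fallback
    import numba as _nb
except ImportError:  # pragma: no cover
    _nb = None

__all__ = [
    "DesignSpec",
    "GeneratorConfig",
    "AccuracyCurve",
    "make_design",
    "simulate_curve_rts",
    "simulate_ddm_trials",
    "simulate_experiment",
    "default_generator_config",
]

CONDITIONS = ("F", "I+F")
RESPONSE_DEADLINE = 5.0  # seconds

#: trial-table schema for delimited-text round trips
TRIAL_COLUMNS = [
    "participant",
    "experiment",
    "mapping",
    "instruction",
    "block",
    "stimulus",
    "repetition",
    "response",
    "accuracy",
    "rt",
    "is_contaminant",
]


@dataclass(frozen=True)
class DesignSpec:
    """Structure of one participant's session."""

    experiment: int
    mapping_ratio: int
    n_stimuli_per_condition: int
    n_repetitions: int
    instruction_design: str  # "within" | "between"
    block_structure: tuple  # ordered (condition, n_trials) pairs

    @property
    def n_trials(self) -> int:
        return sum(n for _, n in self.block_structure)


@dataclass(frozen=True)
class AccuracyCurve:
    """Optional Bernoulli accuracy for curve-generated trials:
    p(R) = p_inf - (p_inf - p0) exp(-alpha R).  Plumbing only — accuracy from
    this curve is never used for inference."""

    p0: float = 0.65
    p_inf: float = 0.95
    alpha: float = 0.12


@dataclass(frozen=True)
class GeneratorConfig:
    """True parameters of the synthetic study.

    The defaults are the study conditions the analyses assume: a learning
    curve with asymptote 0.55 s, head start 0.45 s and rate 0.12 per
    repetition in both instruction conditions; additive RT noise of 0.15 s;
    asymptotic trials from a full DDM with drift 5, boundary separation 1.2,
    non-decision time 0.33 s and non-zero variability components; and 5%
    uniform contaminants.
    """

    true_curve_params: dict = field(
        default_factory=lambda: {
            c: CurveParams(RT0=0.55, B=0.45, alpha=0.12) for c in CONDITIONS
        }
    )
    rt_noise_sd: float = 0.15
    true_ddm_params: dict = field(
        default_factory=lambda: {
            c: DDMParams(v=5.0, a=1.2, t0=0.33, sv=1.5, sz=0.3, st0=0.1)
            for c in CONDITIONS
        }
    )
    contaminant_proportion: float = 0.05
    contaminant_range: tuple = (0.2, 2.0)
    rng_seed: int | None = None
    rt_floor: float = 0.15
    accuracy_curve: AccuracyCurve | None = AccuracyCurve()
    ddm_last_k: int | None = 10  # repetitions drawn from the DDM (asymptotic window)

    def __post_init__(self):
        if not 0 <= self.contaminant_proportion < 1:
            raise ValueError("contaminant_proportion must lie in [0, 1)")
        if self.rt_noise_sd <= 0:
            raise ValueError("rt_noise_sd must be > 0")


def default_generator_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides)


def make_design(
    experiment: int,
    mapping_ratio: int = 8,
    start_block: str = "I+F",
    seed: int | None = None,
    participant_id: str = "p1",
    instruction: str = "I+F",
) -> tuple[DesignSpec, pd.DataFrame]:
    """Build a session design and its ordered trial skeleton.

    Experiment 1 alternates F and I+F blocks (``start_block`` first); each
    block contains ``2 * mapping_ratio`` stimuli presented 40 times each in a
    seeded random order, 1280 trials in total.  Experiment 2 supports the
    8:1 mapping only: 16 stimuli, 60 repetitions, one instruction condition
    per participant (``instruction``).

    Returns the :class:`DesignSpec` and a skeleton DataFrame (responses and
    RTs unfilled).
    """
    rng = np.random.default_rng(seed)
    if experiment == 1:
        if mapping_ratio not in (1, 2, 4, 8):
            raise ValueError("experiment 1 mapping ratio must be 1, 2, 4 or 8")
        if start_block not in CONDITIONS:
            raise ValueError(f"start_block must be one of {CONDITIONS}")
        n_stim, n_rep = 16, 40
        n_blocks_per_cond = 8 // mapping_ratio
        stim_per_block = 2 * mapping_ratio
        other = "F" if start_block == "I+F" else "I+F"
        block_conditions = []
        for i in range(n_blocks_per_cond):
            block_conditions.extend([start_block, other])
        structure = tuple(
            (cond, stim_per_block * n_rep) for cond in block_conditions
        )
        design = DesignSpec(1, mapping_ratio, n_stim, n_rep, "within", structure)

        stimuli = {
            cond: [f"{cond}{i:02d}" for i in range(n_stim)] for cond in CONDITIONS
        }
        # partition each condition's stimuli over its blocks
        rows = []
        block_count = {c: 0 for c in CONDITIONS}
        for block_index, cond in enumerate(block_conditions):
            j = block_count[cond]
            block_count[cond] += 1
            block_stims = stimuli[cond][j * stim_per_block : (j + 1) * stim_per_block]
            trial_stims = np.repeat(block_stims, n_rep)
            rng.shuffle(trial_stims)
            for s in trial_stims:
                rows.append((block_index, cond, s))
    elif experiment == 2:
        if mapping_ratio != 8:
            raise ValueError("experiment 2 supports the 8:1 mapping only")
        if instruction not in CONDITIONS:
            raise ValueError(f"instruction must be one of {CONDITIONS}")
        n_stim, n_rep = 16, 60
        structure = ((instruction, n_stim * n_rep),)
        design = DesignSpec(2, 8, n_stim, n_rep, "between", structure)
        block_stims = [f"{instruction}{i:02d}" for i in range(n_stim)]
        trial_stims = np.repeat(block_stims, n_rep)
        rng.shuffle(trial_stims)
        rows = [(0, instruction, s) for s in trial_stims]
    else:
        raise ValueError("experiment must be 1 or 2")

    df = pd.DataFrame(rows, columns=["block", "instruction", "stimulus"])
    df.insert(0, "participant", participant_id)
    df.insert(1, "experiment", experiment)
    df.insert(2, "mapping", design.mapping_ratio)
    # 0-based count of prior presentations per stimulus, in trial order
    df["repetition"] = df.groupby("stimulus").cumcount()
    # alternate correct keys over each condition's stimulus list
    stim_ids = sorted(df["stimulus"].unique())
    key = {s: ("upper" if i % 2 == 0 else "lower") for i, s in enumerate(stim_ids)}
    df["correct_response"] = df["stimulus"].map(key)
    df["response"] = pd.NA
    df["accuracy"] = pd.NA
    df["rt"] = np.nan
    df["is_contaminant"] = False
    return design, df


def simulate_curve_rts(
    skeleton: pd.DataFrame,
    true_curve_params: dict | CurveParams,
    rt_noise_sd: float,
    seed: int | None = None,
    rt_floor: float = 0.15,
    accuracy_curve: AccuracyCurve | None = AccuracyCurve(),
) -> pd.DataFrame:
    """Fill a trial skeleton with exponential-law RTs plus Gaussian noise.

    ``rt = RT0 + B exp(-alpha R) + eps`` with ``eps ~ N(0, rt_noise_sd)``,
    truncated below at ``rt_floor`` and above at the 5 s response deadline.
    ``true_curve_params`` is either one :class:`CurveParams` or a mapping
    from instruction condition to parameters.  Accuracy, when an
    :class:`AccuracyCurve` is given, is Bernoulli with an exponential rise.
    """
    rng = np.random.default_rng(seed)
    df = skeleton.copy()
    R = np.asarray(df["repetition"], dtype=float)
    if isinstance(true_curve_params, CurveParams):
        params_of = {c: true_curve_params for c in df["instruction"].unique()}
    else:
        params_of = dict(true_curve_params)
    mean_rt = np.empty(len(df))
    for cond, params in params_of.items():
        mask = np.asarray(df["instruction"] == cond)
        if mask.any():
            mean_rt[mask] = predict_rt(params, R[mask])
    rt = mean_rt + rng.normal(0.0, rt_noise_sd, size=len(df))
    df["rt"] = np.clip(rt, rt_floor, RESPONSE_DEADLINE)
    if accuracy_curve is not None:
        p = accuracy_curve.p_inf - (accuracy_curve.p_inf - accuracy_curve.p0) * np.exp(
            -accuracy_curve.alpha * R
        )
        acc = (rng.random(len(df)) < p).astype(int)
    else:
        acc = np.ones(len(df), dtype=int)
    df["accuracy"] = acc
    correct = df["correct_response"].to_numpy()
    flip = {"upper": "lower", "lower": "upper"}
    df["response"] = np.where(acc == 1, correct, [flip[c] for c in correct])
    df["is_contaminant"] = False
    return df


# ---------------------------------------------------------------------------
# Euler-Maruyama path simulation


if _nb is not None:

    @_nb.njit(cache=True)
    def _advance_block(x, drift, a, dt, noise, bridge_seed, out_step, out_up):  # pragma: no cover
        """Advance each path through one block of pre-generated noise;
        out_step[i] is the 1-based crossing step within the block or -1.

        Between-step boundary crossings are resolved by the Brownian-bridge
        probability exp(-2 d0 d1 / dt) (d0, d1 the distances to the boundary
        before and after the step), removing the O(sqrt(dt)) bias of
        discretely monitored Euler paths.
        """
        np.random.seed(bridge_seed)
        m, block = noise.shape
        sqdt = np.sqrt(dt)
        # skip the bridge draw when the crossing probability is < ~7e-13
        cut = 14.0 * dt
        for i in range(m):
            xi = x[i]
            di = drift[i]
            step = -1
            up = False
            for j in range(block):
                x_new = xi + di + sqdt * noise[i, j]
                if x_new >= a:
                    step, up = j + 1, True
                    xi = x_new
                    break
                if x_new <= 0.0:
                    step, up = j + 1, False
                    xi = x_new
                    break
                du = (a - xi) * (a - x_new)
                if du < cut and np.random.random() < np.exp(-2.0 * du / dt):
                    step, up = j + 1, True
                    xi = x_new
                    break
                dl = xi * x_new
                if dl < cut and np.random.random() < np.exp(-2.0 * dl / dt):
                    step, up = j + 1, False
                    xi = x_new
                    break
                xi = x_new
            x[i] = xi
            out_step[i] = step
            out_up[i] = up


def _euler_first_passage(
    v: np.ndarray,
    z: np.ndarray,
    a: float,
    dt: float,
    rng: np.random.Generator,
    t_max: float = RESPONSE_DEADLINE,
    block: int = 400,
    chunk: int = 20000,
):
    """First-passage times and boundaries of Euler-discretised paths.

    Paths advance in blocks of ``block`` steps, vectorised over all
    still-active trials; absorbed paths are compressed out between blocks.

    Returns (decision_time, hit_upper).
    """
    n = v.size
    if _nb is not None:
        dec_t = np.full(n, t_max)
        hit_up = np.zeros(n, dtype=np.bool_)
        sqdt = np.sqrt(dt)
        max_blocks = int(np.ceil(t_max / (dt * block)))
        chunk = min(chunk, n)
        noise = np.empty((chunk, block))
        steps = np.empty(chunk, dtype=np.int64)
        ups = np.empty(chunk, dtype=np.bool_)
        for start in range(0, n, chunk):
            stop = min(start + chunk, n)
            idx = np.arange(start, stop)
            x = np.ascontiguousarray(z[start:stop], dtype=float)
            drift = np.ascontiguousarray(v[start:stop], dtype=float) * dt
            elapsed = 0.0
            for _ in range(max_blocks):
                m = idx.size
                if m == 0:
                    break
                rng.standard_normal(out=noise[:m])
                bridge_seed = int(rng.integers(2**31))
                _advance_block(
                    x, drift, float(a), float(dt), noise[:m], bridge_seed, steps[:m], ups[:m]
                )
                done = steps[:m] > 0
                if done.any():
                    tgt = idx[done]
                    dec_t[tgt] = elapsed + steps[:m][done] * dt
                    hit_up[tgt] = ups[:m][done]
                keep = ~done
                x = np.ascontiguousarray(x[keep])
                drift = np.ascontiguousarray(drift[keep])
                idx = idx[keep]
                elapsed += block * dt
            if idx.size:
                hit_up[idx] = x >= a / 2.0
        return dec_t, hit_up
    dec_t = np.full(n, t_max)
    hit_up = np.zeros(n, dtype=bool)
    sqdt = np.sqrt(dt)
    max_blocks = int(np.ceil(t_max / (dt * block)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        idx = np.arange(start, stop)
        x = z[start:stop].copy()
        drift = v[start:stop] * dt
        elapsed = 0.0
        for _ in range(max_blocks):
            m = idx.size
            if m == 0:
                break
            g = rng.standard_normal((m, block))
            g *= sqdt
            g += drift[:, None]
            np.cumsum(g, axis=1, out=g)
            g += x[:, None]
            up = g >= a
            lo = g <= 0.0
            crossed = up | lo
            any_cross = crossed.any(axis=1)
            if any_cross.any():
                rows = np.nonzero(any_cross)[0]
                first = crossed[rows].argmax(axis=1)
                tgt = idx[rows]
                dec_t[tgt] = elapsed + (first + 1) * dt
                hit_up[tgt] = up[rows, first]
            keep = ~any_cross
            x = g[keep, -1]
            drift = drift[keep]
            idx = idx[keep]
            elapsed += block * dt
        # paths still active at the deadline: censor at t_max, resolve by side
        if idx.size:
            hit_up[idx] = x >= a / 2.0
    return dec_t, hit_up


def simulate_ddm_trials(
    n_trials: int,
    ddm_params: DDMParams,
    contaminant_spec: ContaminantSpec | None = None,
    seed: int | None = None,
    dt: float = 1e-4,
    contaminant_range: tuple = (0.2, 2.0),
) -> pd.DataFrame:
    """Simulate asymptotic-phase trials from the full DDM.

    Each trial draws drift ~ N(v, sv), start point uniform on
    ``a/2 +- sz/2`` and non-decision time uniform on ``t0 +- st0/2``, then
    runs an Euler-Maruyama path (diffusion coefficient s = 1) to absorption.
    With probability ``contaminant_spec.proportion`` the trial is replaced by
    a uniform-RT, fair-coin-response contaminant and flagged.

    Responses are accuracy-coded: the upper boundary is the correct
    response (``accuracy = 1``).
    """
    p = ddm_params
    if p.a <= 0:
        raise ValueError("boundary separation a must be > 0")
    contaminant_spec = contaminant_spec or ContaminantSpec(proportion=0.0)
    rng = np.random.default_rng(seed)
    v = rng.normal(p.v, p.sv, n_trials) if p.sv > 0 else np.full(n_trials, p.v)
    z = (
        rng.uniform(p.a / 2 - p.sz / 2, p.a / 2 + p.sz / 2, n_trials)
        if p.sz > 0
        else np.full(n_trials, p.a / 2)
    )
    t0 = (
        rng.uniform(p.t0 - p.st0 / 2, p.t0 + p.st0 / 2, n_trials)
        if p.st0 > 0
        else np.full(n_trials, p.t0)
    )
    dec_t, hit_up = _euler_first_passage(v, z, p.a, dt, rng)
    rt = np.minimum(dec_t + t0, RESPONSE_DEADLINE)

    is_cont = rng.random(n_trials) < contaminant_spec.proportion
    if is_cont.any():
        lo = contaminant_spec.rt_min if contaminant_spec.rt_min is not None else contaminant_range[0]
        hi = contaminant_spec.rt_max if contaminant_spec.rt_max is not None else contaminant_range[1]
        n_c = int(is_cont.sum())
        rt[is_cont] = rng.uniform(lo, hi, n_c)
        hit_up[is_cont] = rng.random(n_c) < 0.5

    return pd.DataFrame(
        {
            "response": np.where(hit_up, "upper", "lower"),
            "accuracy": hit_up.astype(int),
            "rt": rt,
            "is_contaminant": is_cont,
        }
    )


def simulate_experiment(
    experiment: int,
    mapping_ratio: int = 8,
    participants: int = 1,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate full sessions for one or more participants.

    RTs follow the exponential learning curve everywhere except the final
    ``config.ddm_last_k`` repetitions of each stimulus, which are drawn from
    the full DDM (per instruction condition) with contaminants — the
    asymptotic window downstream DDM fits consume.  Even-indexed
    participants start with an I+F block, odd-indexed with an F block.
    """
    config = config or GeneratorConfig()
    root = np.random.SeedSequence(seed if seed is not None else config.rng_seed)
    frames = []
    for i, child in enumerate(root.spawn(participants)):
        s_design, s_curve, s_ddm = [int(x) for x in child.generate_state(3) % (2**31)]
        pid = f"sim{i:03d}"
        start = "I+F" if i % 2 == 0 else "F"
        instruction = CONDITIONS[i % 2]
        design, skel = make_design(
            experiment,
            mapping_ratio,
            start_block=start,
            seed=s_design,
            participant_id=pid,
            instruction=instruction,
        )
        df = simulate_curve_rts(
            skel,
            config.true_curve_params,
            config.rt_noise_sd,
            seed=s_curve,
            rt_floor=config.rt_floor,
            accuracy_curve=config.accuracy_curve,
        )
        if config.ddm_last_k:
            cutoff = design.n_repetitions - config.ddm_last_k
            window = df["repetition"] >= cutoff
            rng_ddm = np.random.default_rng(s_ddm)
            for cond, params in config.true_ddm_params.items():
                mask = window & (df["instruction"] == cond)
                n = int(mask.sum())
                if n == 0:
                    continue
                sim = simulate_ddm_trials(
                    n,
                    params,
                    ContaminantSpec(proportion=config.contaminant_proportion),
                    seed=int(rng_ddm.integers(2**31)),
                    dt=dt,
                    contaminant_range=config.contaminant_range,
                )
                df.loc[mask, "rt"] = sim["rt"].to_numpy()
                df.loc[mask, "accuracy"] = sim["accuracy"].to_numpy()
                df.loc[mask, "is_contaminant"] = sim["is_contaminant"].to_numpy()
                correct = df.loc[mask, "correct_response"].to_numpy()
                flip = {"upper": "lower", "lower": "upper"}
                df.loc[mask, "response"] = np.where(
                    sim["accuracy"].to_numpy() == 1,
                    correct,
                    [flip[c] for c in correct],
                )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.drop(columns=["correct_response"])
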