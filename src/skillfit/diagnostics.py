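"""Asymptote diagnostics and fit summaries.

Quantities used to judge whether behaviour in the final repetitions is
stationary and whether the DDM stage found condition differences:

* ``llr_slope`` — one-sided log likelihood ratio for residual learning (a
  negative RT trend over the final repetitions);
* ``llr_ddm`` — log evidence ratio of the 7 condition-difference DDM specs
  against the no-difference spec, from BIC weights;
* ``rt_quantiles`` / ``qq_table`` — empirical 0.1/0.3/0.5/0.7/0.9 RT
  quantiles per response class, and their model-predicted counterparts for
  QQ comparison;
* ``condition_param_diff`` — normalised F minus I+F differences of
  model-averaged parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import DDMParams, QuadratureConfig, predicted_quantiles
from .model_selection import ModelComparison

__all__ = [
    "QuantileSummary",
    "llr_slope",
    "llr_ddm",
    "rt_quantiles",
    "qq_table",
    "condition_param_diff",
    "DEFAULT_QUANTILE_LEVELS",
]

DEFAULT_QUANTILE_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class QuantileSummary:
    """Empirical RT quantiles for one response class."""

    participant: object
    condition: object
    response_class: str  # "correct" | "error"
    levels: tuple
    quantile_rts: np.ndarray
    proportion: float


def llr_slope(trials: pd.DataFrame, rt_col: str = "rt", repetition_col: str = "repetition") -> float:
    """One-sided evidence for residual learning in the final repetitions.

    Fits ordinary least squares ``rt ~ repetition`` with Gaussian errors and
    returns the log likelihood ratio of the unconstrained fit against the
    zero-slope fit, signed positive when the fitted slope is negative
    (RT still decreasing, i.e. learning not finished) and negative
    otherwise.
    """
    R = np.asarray(trials[repetition_col], dtype=float)
    rt = np.asarray(trials[rt_col], dtype=float)
    if np.unique(R).size < 3:
        raise ValueError("llr_slope needs at least 3 distinct repetition values")
    n = rt.size
    X = np.column_stack([np.ones(n), R])
    beta, *_ = np.linalg.lstsq(X, rt, rcond=None)
    resid = rt - X @ beta
    sse1 = float(resid @ resid)
    sse0 = float(np.sum((rt - rt.mean()) ** 2))
    if sse1 <= 0 or sse0 <= 0:
        raise ValueError("degenerate (constant) RTs: zero residual variance")
    # Gaussian profile log likelihood: l = -n/2 (log(2 pi sse/n) + 1)
    llr = 0.5 * n * (np.log(sse0 / n) - np.log(sse1 / n))
    return float(llr if beta[1] < 0 else -llr)


def llr_ddm(comparison: ModelComparison) -> float:
    """Log evidence ratio of any-condition-difference vs the none DDM spec.

    ``log( sum of weights of the 7 difference specs / weight of none )``;
    requires the full 8-spec hierarchy in ``comparison``.
    """
    names = comparison.spec_names
    if len(names) != 8 or "none" not in names:
        raise ValueError("llr_ddm requires the full 8-spec hierarchy")
    w_none = comparison.weight_of("none")
    if w_none == 0:
        warnings.warn(
            "none-spec weight is zero; LLR reported as inf", RuntimeWarning, stacklevel=2
        )
        return float("inf")
    return float(np.log((1.0 - w_none) / w_none))


def rt_quantiles(
    trials: pd.DataFrame,
    levels=DEFAULT_QUANTILE_LEVELS,
    participant=None,
    condition=None,
    min_trials: int = 5,
    rt_col: str = "rt",
    accuracy_col: str = "accuracy",
) -> list[QuantileSummary]:
    """Empirical RT quantiles (linear interpolation) per response class.

    Classes with fewer than ``min_trials`` trials are skipped with a
    warning.  Proportions are relative to all trials passed in.
    """
    out = []
    n_total = len(trials)
    for response_class, mask in (
        ("correct", trials[accuracy_col] == 1),
        ("error", trials[accuracy_col] == 0),
    ):
        rts = np.asarray(trials.loc[mask, rt_col], dtype=float)
        if rts.size < min_trials:
            warnings.warn(
                f"{response_class}: only {rts.size} trials (< {min_trials}); class skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        q = np.quantile(rts, levels)
        out.append(
            QuantileSummary(
                participant=participant,
                condition=condition,
                response_class=response_class,
                levels=tuple(levels),
                quantile_rts=q,
                proportion=rts.size / n_total,
            )
        )
    return out


def qq_table(
    trials: pd.DataFrame,
    params: DDMParams,
    levels=DEFAULT_QUANTILE_LEVELS,
    quad: QuadratureConfig | None = None,
    **kw,
) -> pd.DataFrame:
    """Observed vs model-predicted quantiles for QQ assessment of a DDM fit.

    Predicted quantiles come from numerically inverting the fitted model's
    conditional RT CDF per response class.
    """
    rows = []
    for summary in rt_quantiles(trials, levels=levels, **kw):
        pred = predicted_quantiles(
            params, levels=levels, response_class=summary.response_class, quad=quad
        )
        for lvl, obs, prd in zip(summary.levels, summary.quantile_rts, pred):
            rows.append(
                {
                    "participant": summary.participant,
                    "condition": summary.condition,
                    "response_class": summary.response_class,
                    "level": lvl,
                    "observed_rt": obs,
                    "predicted_rt": prd,
                    "proportion": summary.proportion,
                }
            )
    return pd.DataFrame(rows)


def condition_param_diff(
    table: pd.DataFrame,
    parameters: list[str] | None = None,
    participant_col: str = "participant",
    condition_col: str = "condition",
    mapping_col: str | None = None,
) -> pd.DataFrame:
    """Normalised F minus I+F differences of model-averaged parameters.

    ``table`` holds one row per (participant, condition) with one column per
    parameter.  For each parameter the per-participant difference
    ``value_F - value_I+F`` is divided by the pooled scale: the standard
    deviation of that parameter over all (participant, condition) values
    within the participant's mapping group (or the whole table when
    ``mapping_col`` is None).
    """
    if parameters is None:
        reserved = {participant_col, condition_col, mapping_col}
        parameters = [c for c in table.columns if c not in reserved]
    groups = (
        table.groupby(mapping_col) if mapping_col is not None else [(None, table)]
    )
    rows = []
    for mapping, sub in groups:
        wide = sub.pivot_table(
            index=participant_col, columns=condition_col, values=parameters
        )
        for param in parameters:
            scale = float(np.std(sub[param].to_numpy(dtype=float), ddof=1))
            if not np.isfinite(scale) or scale == 0:
                raise ValueError(f"zero pooled scale for parameter {param!r}")
            diff = (wide[(param, "F")] - wide[(param, "I+F")]) / scale
            for pid, value in diff.items():
                row = {participant_col: pid, "parameter": param, "normalized_diff": value}
                if mapping_col is not None:
                    row[mapping_col] = mapping
                rows.append(row)
    return pd.DataFrame(rows)
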