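"""Exponential law-of-practice fitting with a condition-constraint hierarchy.

Response time declines over repetitions of a stimulus-response mapping as

    RT(R) = RT0 + B * exp(-alpha * R)

where ``RT0`` is the asymptote (the automatic-execution level), ``B`` the
difference between initial and asymptotic performance (the head start that
instructions may provide), and ``alpha`` the learning rate.  ``R`` counts
prior presentations of the stimulus and starts at 0, so initial performance
is exactly ``RT0 + B``.

Per participant, each of the three parameters may be constrained equal
across the two instruction conditions (feedback-only F vs instructed I+F) or
free to differ; the 8 resulting models are fitted by minimising the summed
squared error with particle swarm optimisation and compared by BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .optim import OptimizerConfig, minimize_pso

__all__ = [
    "CurveParams",
    "CurveModelSpec",
    "CurveBounds",
    "CurveFit",
    "ExponentialLearningModel",
    "predict_rt",
    "fit_curve",
    "curve_model_hierarchy",
]

_PARAMS = ("RT0", "B", "alpha")


@dataclass(frozen=True)
class CurveParams:
    """Exponential learning-curve parameters (seconds / per-repetition rate)."""

    RT0: float
    B: float
    alpha: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.RT0, self.B, self.alpha])):
            raise ValueError("curve parameters must be finite")
        if self.RT0 <= 0:
            raise ValueError("asymptote RT0 must be > 0")
        if self.B < 0 or self.alpha < 0:
            raise ValueError("B and alpha must be >= 0")

    def as_dict(self) -> dict:
        return {"RT0": self.RT0, "B": self.B, "alpha": self.alpha}


def predict_rt(params: CurveParams, R):
    """Expected RT after ``R`` prior presentations (R >= 0, 0-based)."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("repetition index R must be >= 0")
    return params.RT0 + params.B * np.exp(-params.alpha * R)


@dataclass(frozen=True)
class CurveModelSpec:
    """Subset of {RT0, B, alpha} free to differ between instruction conditions."""

    free_params: frozenset = frozenset()

    def __post_init__(self):
        extra = set(self.free_params) - set(_PARAMS)
        if extra:
            raise ValueError(f"unknown free parameters: {sorted(extra)}")
        object.__setattr__(self, "free_params", frozenset(self.free_params))

    @property
    def name(self) -> str:
        if not self.free_params:
            return "none"
        return "+".join(p for p in _PARAMS if p in self.free_params)

    def k(self, n_conditions: int = 2) -> int:
        if n_conditions == 1:
            return 3
        return 3 + len(self.free_params)

    def is_free(self, param: str) -> bool:
        return param in self.free_params


def curve_model_hierarchy() -> list[CurveModelSpec]:
    """All 8 constraint specs, ordered from all-free (k=6) to none (k=3)."""
    specs = []
    for size in (3, 2, 1, 0):
        for combo in combinations(_PARAMS, size):
            specs.append(CurveModelSpec(frozenset(combo)))
    return specs


@dataclass(frozen=True)
class CurveBounds:
    """Search box; covers plausible choice-RT curves with slack."""

    RT0: tuple = (0.15, 3.0)
    B: tuple = (0.0, 5.0)
    alpha: tuple = (0.0, 3.0)


@dataclass
class CurveFit:
    """Results of fitting one curve constraint spec to one participant."""

    spec: CurveModelSpec
    params_by_condition: dict
    sse: float
    n: int
    k: int
    bic: float
    optimizer_result: object = field(default=None, repr=False)

    @property
    def params(self) -> pd.DataFrame:
        rows = {c: p.as_dict() for c, p in self.params_by_condition.items()}
        return pd.DataFrame(rows).T

    def get_param(self, name: str, condition) -> float:
        return getattr(self.params_by_condition[condition], name)

    def predict(self, R, condition) -> np.ndarray:
        return predict_rt(self.params_by_condition[condition], R)

    def summary(self) -> str:
        lines = [
            f"Learning-curve fit  spec={self.spec.name}  k={self.k}  n={self.n}",
            f"SSE = {self.sse:.6f}   BIC = {self.bic:.4f}",
            self.params.round(4).to_string(),
        ]
        return "\n".join(lines)


def _spec_layout(spec: CurveModelSpec, conditions, bounds: CurveBounds):
    layout = []
    multi = len(conditions) > 1
    for name in _PARAMS:
        b = getattr(bounds, name)
        if multi and spec.is_free(name):
            for cond in conditions:
                layout.append((name, cond, b))
        else:
            layout.append((name, None, b))
    return layout


class ExponentialLearningModel:
    """Exponential learning curve for one participant's trials.

    Parameters
    ----------
    data : DataFrame
        Trials with columns ``rt`` (seconds), ``repetition`` (0-based count
        of prior presentations of the stimulus) and, for two-condition fits,
        ``instruction``.
    correct_only : bool
        Restrict the fit to correct trials (requires an ``accuracy`` column).
        By default all trials enter the fit.
    aggregate : bool
        Fit repetition-level mean RTs instead of raw trials (default raw).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        condition_col: str = "instruction",
        rt_col: str = "rt",
        repetition_col: str = "repetition",
        correct_only: bool = False,
        aggregate: bool = False,
        bounds: CurveBounds = CurveBounds(),
    ):
        df = data.reset_index(drop=True)
        if correct_only:
            df = df[df["accuracy"] == 1].reset_index(drop=True)
        if df.empty:
            raise ValueError("no trials to fit")
        self.condition_col = condition_col
        self.rt_col = rt_col
        self.repetition_col = repetition_col
        self.bounds = bounds
        if condition_col in df.columns:
            self.conditions = sorted(df[condition_col].unique().tolist())
        else:
            self.conditions = ["all"]
        if aggregate:
            keys = [repetition_col] + ([condition_col] if condition_col in df.columns else [])
            df = df.groupby(keys, as_index=False)[rt_col].mean()
        self.data = df
        self.nobs = len(df)
        self._split = {}
        for cond in self.conditions:
            sub = df if cond == "all" else df[df[condition_col] == cond]
            if sub.empty:
                raise ValueError(f"empty condition {cond!r}")
            self._split[cond] = (
                np.ascontiguousarray(sub[repetition_col], dtype=float),
                np.ascontiguousarray(sub[rt_col], dtype=float),
            )

    @classmethod
    def from_dataframe(cls, data, **kw):
        return cls(data, **kw)

    def sse(self, params_by_condition: dict) -> float:
        """Summed squared error of observed vs predicted RTs."""
        total = 0.0
        for cond, params in params_by_condition.items():
            R, rt = self._split[cond]
            resid = rt - predict_rt(params, R)
            total += float(resid @ resid)
        return total

    def _batch_sse(self, layout):
        conditions = self.conditions
        idx_by_cond = {c: [] for c in conditions}
        for j, (name, cond, _) in enumerate(layout):
            targets = [cond] if cond is not None else conditions
            for c in targets:
                idx_by_cond[c].append((name, j))

        def objective(X):
            X = np.atleast_2d(X)
            out = np.zeros(X.shape[0])
            for c in conditions:
                cols = dict(idx_by_cond[c])
                R, rt = self._split[c]
                rt0 = X[:, cols["RT0"]][:, None]
                b = X[:, cols["B"]][:, None]
                alpha = X[:, cols["alpha"]][:, None]
                pred = rt0 + b * np.exp(-alpha * R[None, :])
                resid = pred - rt[None, :]
                out += np.einsum("ij,ij->i", resid, resid)
            return out

        return objective

    def fit(
        self,
        spec: CurveModelSpec = CurveModelSpec(),
        optimizer: OptimizerConfig | None = None,
        seed: int | None = None,
        start_params: dict | None = None,
    ) -> CurveFit:
        """Fit one constraint spec by PSO on the SSE; returns the best restart."""
        if len(self.conditions) == 1 and spec.free_params:
            raise ValueError(
                "single-condition data cannot identify a condition-freeing spec"
            )
        k = spec.k(len(self.conditions))
        if self.nobs < k + 2:
            raise ValueError(f"need at least k+2={k + 2} trials, got {self.nobs}")
        optimizer = optimizer or OptimizerConfig(swarm_size=40, iterations=300, n_restarts=5)
        layout = _spec_layout(spec, self.conditions, self.bounds)
        objective = self._batch_sse(layout)
        x0 = None
        if start_params is not None:
            x0 = np.array(
                [
                    getattr(start_params[c if c is not None else self.conditions[0]], name)
                    for name, c, _ in layout
                ]
            )
        res = minimize_pso(objective, [b for _, _, b in layout], optimizer, seed=seed, x0=x0)
        params = {}
        for cond in self.conditions:
            d = {}
            for value, (name, c, _) in zip(res.x, layout):
                if c is None or c == cond:
                    d[name] = float(value)
            params[cond] = CurveParams(**d)
        sse = float(res.fun)
        from .model_selection import bic_from_sse

        return CurveFit(
            spec=spec,
            params_by_condition=params,
            sse=sse,
            n=self.nobs,
            k=k,
            bic=bic_from_sse(k, self.nobs, sse),
            optimizer_result=res,
        )

    def fit_hierarchy(
        self,
        optimizer: OptimizerConfig | None = None,
        seed: int | None = None,
        participant_id=None,
    ):
        """Fit all 8 specs and return a
        :class:`~skillfit.model_selection.ModelComparison`.

        The none spec is fitted first and its solution seeds the starting
        swarm of every larger spec, which preserves the SSE dominance of
        nested models over their constrained parents.
        """
        from .model_selection import ModelComparison

        specs = curve_model_hierarchy()
        seeds = np.random.SeedSequence(seed).generate_state(len(specs)) % (2**31)
        none_fit = self.fit(specs[-1], optimizer=optimizer, seed=int(seeds[-1]))
        fits = []
        for spec, s in zip(specs[:-1], seeds[:-1]):
            fits.append(
                self.fit(
                    spec,
                    optimizer=optimizer,
                    seed=int(s),
                    start_params=none_fit.params_by_condition,
                )
            )
        fits.append(none_fit)
        return ModelComparison(participant_id=participant_id, fits=fits)


def fit_curve(
    trials: pd.DataFrame,
    spec: CurveModelSpec = CurveModelSpec(),
    opt: OptimizerConfig | None = None,
    seed: int | None = None,
    **model_kw,
) -> CurveFit:
    """Functional wrapper: fit one curve constraint spec to one participant."""
    model = ExponentialLearningModel(trials, **model_kw)
    return model.fit(spec, optimizer=opt, seed=seed)
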