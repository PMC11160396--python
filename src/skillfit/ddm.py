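"""Diffusion decision model (DDM) likelihood and fitting.

The full DDM describes two-choice decisions as noisy evidence accumulation
(diffusion coefficient fixed at ``s = 1``) between two absorbing boundaries a
distance ``a`` apart, started without bias at ``a/2``.  Mean parameters are
drift rate ``v``, boundary separation ``a`` and non-decision time ``t0``;
between-trial variability enters as Gaussian drift variability ``sv``, a
uniform start-point range ``sz`` and a uniform non-decision-time range
``st0``.  The marginal response-time density integrates the Wiener
first-passage density over these mixing distributions by fixed-node Gaussian
quadrature (Gauss-Hermite over drift, Gauss-Legendre over start point and
non-decision time).

Observed data are scored under a two-component mixture: with probability
``1 - p`` a trial comes from the DDM, with probability ``p`` it is a
contaminant with uniform RT over the observed range of that participant and
condition and a fair-coin response.  Responses are accuracy-coded: a correct
response absorbs at the upper boundary, an error at the lower.

Fitting minimises the negative summed log likelihood (-SLL) with particle
swarm optimisation over a constraint hierarchy: each of ``v``, ``a``, ``t0``
may be free to differ between instruction conditions, and freeing a mean
parameter frees its variability counterpart with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optim import OptimizerConfig, minimize_pso
from .wiener import wiener_fpt_density, prob_upper

__all__ = [
    "DDMParams",
    "ContaminantSpec",
    "DDMModelSpec",
    "QuadratureConfig",
    "DDMBounds",
    "DDMFit",
    "DiffusionModel",
    "ddm_density",
    "ddm_cdf",
    "mixture_loglik",
    "fit_ddm",
    "ddm_model_hierarchy",
    "predicted_quantiles",
]

_MAIN_PARAMS = ("v", "a", "t0")
_VARIABILITY = {"v": "sv", "a": "sz", "t0": "st0"}


@dataclass(frozen=True)
class DDMParams:
    """Full-DDM parameter set for one condition (s = 1, start point a/2)."""

    v: float
    a: float
    t0: float
    sv: float = 0.0
    sz: float = 0.0
    st0: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite([self.v, self.a, self.t0, self.sv, self.sz, self.st0])):
            raise ValueError("DDM parameters must be finite")
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if self.sv < 0:
            raise ValueError("drift variability sv must be >= 0")
        if not 0 <= self.sz < self.a:
            raise ValueError("start-point range sz must satisfy 0 <= sz < a")
        if self.st0 < 0 or self.t0 <= self.st0 / 2:
            raise ValueError("non-decision window requires t0 > st0/2 >= 0")

    def as_dict(self) -> dict:
        return {
            "v": self.v,
            "a": self.a,
            "t0": self.t0,
            "sv": self.sv,
            "sz": self.sz,
            "st0": self.st0,
        }


@dataclass(frozen=True)
class ContaminantSpec:
    """Uniform contaminant component of the RT mixture.

    ``rt_min``/``rt_max`` default to None and are then taken from the data
    being scored (fastest to slowest RT per participant and condition).
    """

    proportion: float = 0.05
    rt_min: float | None = None
    rt_max: float | None = None

    def __post_init__(self):
        if not 0 <= self.proportion < 1:
            raise ValueError("contaminant proportion must lie in [0, 1)")
        if self.rt_min is not None and self.rt_max is not None and self.rt_min >= self.rt_max:
            raise ValueError("contaminant range requires rt_min < rt_max")


@dataclass(frozen=True)
class DDMModelSpec:
    """Which main parameters may differ between instruction conditions.

    Freeing a mean parameter also frees its between-trial variability
    counterpart (v with sv, a with sz, t0 with st0), so a two-condition fit
    has ``k = 6 + 2 * |free_params|`` free parameters.
    """

    free_params: frozenset = frozenset()

    def __post_init__(self):
        extra = set(self.free_params) - set(_MAIN_PARAMS)
        if extra:
            raise ValueError(f"unknown free parameters: {sorted(extra)}")
        object.__setattr__(self, "free_params", frozenset(self.free_params))

    @property
    def name(self) -> str:
        if not self.free_params:
            return "none"
        return "+".join(p for p in _MAIN_PARAMS if p in self.free_params)

    def k(self, n_conditions: int = 2) -> int:
        if n_conditions == 1:
            return 6
        return 6 + 2 * len(self.free_params)

    def is_free(self, param: str) -> bool:
        return param in self.free_params


def ddm_model_hierarchy() -> list[DDMModelSpec]:
    """The 8 constraint specs, ordered from all-free (k=12) to none (k=6)."""
    specs = []
    for size in (3, 2, 1, 0):
        subsets = [
            frozenset(c)
            for c in _ordered_subsets(_MAIN_PARAMS, size)
        ]
        specs.extend(DDMModelSpec(s) for s in subsets)
    return specs


def _ordered_subsets(items, size):
    from itertools import combinations

    return list(combinations(items, size))


@dataclass(frozen=True)
class QuadratureConfig:
    """Fixed-node quadrature over the three mixing distributions.

    Defaults give summed-log-likelihood truncation error well below 0.01 on
    a few hundred trials (doubling all node counts moves the SLL by less
    than that); fitting may use a lighter configuration.
    """

    n_drift: int = 11
    n_start: int = 7
    n_t0: int = 11

    def __post_init__(self):
        if min(self.n_drift, self.n_start, self.n_t0) < 1:
            raise ValueError("quadrature requires at least one node per dimension")


@dataclass(frozen=True)
class DDMBounds:
    """Optimisation box.  sz and st0 are searched as fractions: sz = f * a
    (f <= 0.9) and st0 = f * min(st0_max, 1.9 * t0), which keeps sz < a and
    t0 > st0/2 satisfied throughout the search."""

    v: tuple = (-2.0, 12.0)
    a: tuple = (0.3, 4.0)
    t0: tuple = (0.05, 1.0)
    sv: tuple = (0.0, 4.0)
    sz_frac: tuple = (0.0, 0.9)
    st0_frac: tuple = (0.0, 1.0)
    st0_max: float = 0.4


from functools import lru_cache


@lru_cache(maxsize=32)
def _hermegauss(n):
    return np.polynomial.hermite_e.hermegauss(n)


@lru_cache(maxsize=32)
def _leggauss(n):
    return np.polynomial.legendre.leggauss(n)


def _quad_nodes(params: DDMParams, quad: QuadratureConfig, force_full: bool = False):
    """(drift, relative start) node grid and weights, plus raw t0 nodes.

    With ``force_full`` the full node counts are kept even for degenerate
    (zero-variability) mixing distributions, so every parameter vector of a
    swarm yields identically shaped grids.
    """
    if quad.n_drift > 1 and (params.sv > 0 or force_full):
        xh, wh = _hermegauss(quad.n_drift)
        v_nodes = params.v + params.sv * xh
        v_w = wh / np.sqrt(2.0 * np.pi)
    else:
        v_nodes, v_w = np.array([params.v]), np.array([1.0])
    if quad.n_start > 1 and (params.sz > 0 or force_full):
        xl, wl = _leggauss(quad.n_start)
        z_nodes = params.a / 2.0 + (params.sz / 2.0) * xl
        z_w = wl / 2.0
    else:
        z_nodes, z_w = np.array([params.a / 2.0]), np.array([1.0])
    return v_nodes, v_w, z_nodes / params.a, z_w


def _mixing_arrays(
    params: DDMParams,
    quad: QuadratureConfig,
    rt: np.ndarray,
    force_full: bool = False,
):
    """Per-trial flattened quadrature grid for the three mixing integrals.

    The non-decision-time integral runs over ``[t0 - st0/2, t0 + st0/2]``
    but the Wiener density vanishes for non-decision times at or above the
    observed RT, so the interval is clipped per trial at ``rt`` before
    placing the Gauss-Legendre nodes.  Without the clip the integrand has a
    kink inside the interval and fixed-node quadrature converges slowly for
    leading-edge RTs.

    Returns ``tdec`` (n, D) decision times, ``v`` (D,), ``w`` (D,) and
    per-trial weights ``wts`` (n, D).
    """
    v_nodes, v_w, w_nodes, z_w = _quad_nodes(params, quad, force_full)
    n = rt.size
    if quad.n_t0 > 1 and params.st0 > 0:
        xt, wt = _leggauss(quad.n_t0)
        lo = params.t0 - params.st0 / 2.0
        hi = params.t0 + params.st0 / 2.0
        width = np.clip(np.minimum(hi, rt) - lo, 0.0, None)  # (n,)
        u = lo + width[:, None] * (xt[None, :] + 1.0) / 2.0  # (n, nt)
        u_w = (width[:, None] / params.st0) * (wt[None, :] / 2.0)
    elif quad.n_t0 > 1 and force_full:
        _, wt = _leggauss(quad.n_t0)
        u = np.full((n, quad.n_t0), params.t0)
        u_w = np.broadcast_to(wt / 2.0, (n, quad.n_t0))
    else:
        u = np.full((n, 1), params.t0)
        u_w = np.ones((n, 1))
    nd, nz, nt = v_nodes.size, w_nodes.size, u.shape[1]
    D = nd * nz * nt
    V = np.broadcast_to(v_nodes[:, None, None], (nd, nz, nt)).reshape(D)
    W = np.broadcast_to(w_nodes[None, :, None], (nd, nz, nt)).reshape(D)
    tdec = np.broadcast_to(
        (rt[:, None] - u)[:, None, None, :], (n, nd, nz, nt)
    ).reshape(n, D)
    wts = np.broadcast_to(
        (v_w[:, None] * z_w[None, :])[None, :, :, None] * u_w[:, None, None, :],
        (n, nd, nz, nt),
    ).reshape(n, D)
    return tdec, V, W, wts


def ddm_density(t, boundary, params: DDMParams, quad: QuadratureConfig | None = None):
    """Marginal defective RT density of the full DDM at one boundary.

    Integrates the Wiener first-passage density over the between-trial
    mixing distributions by Gaussian quadrature; reduces exactly to the pure
    Wiener density when ``sv = sz = st0 = 0``.  ``t`` is the observed RT in
    seconds (non-decision time included).
    """
    quad = quad or QuadratureConfig()
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tdec, V, W, wts = _mixing_arrays(params, quad, t)
    dens = wiener_fpt_density(
        tdec,
        np.broadcast_to(V, tdec.shape),
        params.a,
        np.broadcast_to(W, tdec.shape),
        boundary=boundary,
    )
    return np.sum(dens * wts, axis=1)


def ddm_cdf(t_grid, boundary, params: DDMParams, quad: QuadratureConfig | None = None):
    """Defective CDF at ``boundary`` on an increasing grid (trapezoid rule)."""
    t_grid = np.asarray(t_grid, dtype=float)
    dens = ddm_density(t_grid, boundary, params, quad)
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(dens, t_grid, initial=0.0)


def response_probability(params: DDMParams, boundary: str = "upper",
                         quad: QuadratureConfig | None = None) -> float:
    """Marginal probability of the response at ``boundary`` (drift/start mixing)."""
    quad = quad or QuadratureConfig()
    v_nodes, v_w, w_nodes, z_w = _quad_nodes(params, quad)
    p = prob_upper(v_nodes[:, None], params.a, w_nodes[None, :])
    if boundary == "lower":
        p = 1.0 - p
    return float(v_w @ p @ z_w)


def predicted_quantiles(
    params: DDMParams,
    levels=(0.1, 0.3, 0.5, 0.7, 0.9),
    response_class: str = "correct",
    quad: QuadratureConfig | None = None,
    t_max: float = 5.0,
    n_grid: int = 2048,
) -> np.ndarray:
    """Model-implied RT quantiles for one response class.

    The defective CDF is computed on a grid, normalised by the response-class
    probability and inverted by interpolation.  "correct" maps to the upper
    boundary under accuracy coding.
    """
    boundary = "upper" if response_class == "correct" else "lower"
    lo = max(params.t0 - params.st0 / 2.0, 0.0)
    grid = np.linspace(lo, t_max, n_grid)
    cdf = ddm_cdf(grid, boundary, params, quad)
    total = cdf[-1]
    if total <= 0:
        raise ValueError("response class has zero probability under the model")
    cdf = cdf / total
    return np.interp(np.asarray(levels, dtype=float), cdf, grid)


def mixture_loglik(
    trials: pd.DataFrame,
    params_by_condition: dict,
    contaminant: ContaminantSpec = ContaminantSpec(),
    quad: QuadratureConfig | None = None,
    condition_col: str = "instruction",
    rt_col: str = "rt",
    accuracy_col: str = "accuracy",
) -> float:
    """Summed log likelihood of trials under the DDM + uniform-contaminant mixture.

    Per trial: ``L = (1-p) f_DDM(rt, boundary(accuracy)) + p * 0.5 / range``
    where the contaminant range spans the fastest to the slowest observed RT
    of the scored trials (per condition) unless fixed in ``contaminant``.
    """
    rt = np.asarray(trials[rt_col], dtype=float)
    if np.any((rt < 0) | (rt > 5.0)):
        raise ValueError("RTs must lie within [0, 5] seconds")
    acc = np.asarray(trials[accuracy_col], dtype=int)
    sll = 0.0
    for cond, params in params_by_condition.items():
        if condition_col in trials.columns:
            mask = np.asarray(trials[condition_col] == cond)
        else:
            mask = np.ones(len(trials), dtype=bool)
        if not mask.any():
            raise ValueError(f"no trials for condition {cond!r}")
        rt_c, acc_c = rt[mask], acc[mask]
        rt_min = contaminant.rt_min if contaminant.rt_min is not None else rt_c.min()
        rt_max = contaminant.rt_max if contaminant.rt_max is not None else rt_c.max()
        p = contaminant.proportion
        if p > 0 and rt_max <= rt_min:
            raise ValueError(
                "zero contaminant range: all RTs identical in condition " + str(cond)
            )
        unif = p * 0.5 / (rt_max - rt_min) if p > 0 else 0.0
        lik = np.empty(rt_c.shape)
        for boundary, sel in (("upper", acc_c == 1), ("lower", acc_c == 0)):
            if sel.any():
                lik[sel] = ddm_density(rt_c[sel], boundary, params, quad)
        lik = (1.0 - p) * lik + unif
        sll += float(np.sum(np.log(np.maximum(lik, 1e-300))))
    return sll


# ---------------------------------------------------------------------------
# fitting


def _spec_layout(spec: DDMModelSpec, conditions: list, bounds: DDMBounds):
    """Free-vector layout: list of (name, condition-or-None, (lo, hi))."""
    layout = []
    multi = len(conditions) > 1
    for main in _MAIN_PARAMS:
        for name in (main, _VARIABILITY[main]):
            bname = {"sz": "sz_frac", "st0": "st0_frac"}.get(name, name)
            b = getattr(bounds, bname)
            if multi and spec.is_free(main):
                for cond in conditions:
                    layout.append((name, cond, b))
            else:
                layout.append((name, None, b))
    return layout


def _vector_to_params(x, layout, conditions, bounds: DDMBounds):
    raw = {cond: {} for cond in conditions}
    for value, (name, cond, _) in zip(x, layout):
        targets = [cond] if cond is not None else conditions
        for c in targets:
            raw[c][name] = float(value)
    out = {}
    for c in conditions:
        d = raw[c]
        sz = d["sz"] * d["a"]
        st0 = d["st0"] * min(bounds.st0_max, 1.9 * d["t0"])
        out[c] = DDMParams(v=d["v"], a=d["a"], t0=d["t0"], sv=d["sv"], sz=sz, st0=st0)
    return out


def _params_to_vector(params_by_condition, layout, bounds: DDMBounds):
    """Inverse of _vector_to_params (used to warm-start nested specs)."""
    x = []
    for name, cond, b in layout:
        c = cond if cond is not None else next(iter(params_by_condition))
        p = params_by_condition[c]
        if name == "sz":
            val = p.sz / p.a
        elif name == "st0":
            denom = min(bounds.st0_max, 1.9 * p.t0)
            val = p.st0 / denom if denom > 0 else 0.0
        else:
            val = getattr(p, name)
        x.append(np.clip(val, b[0], b[1]))
    return np.asarray(x, dtype=float)


def ez_diffusion_start(rt: np.ndarray, acc: np.ndarray, bounds: DDMBounds = DDMBounds()) -> DDMParams:
    """Closed-form EZ-diffusion estimates of (v, a, t0) used to seed the swarm.

    Method-of-moments inversion from accuracy and the RT variance/mean of
    correct responses (s = 1 scaling), with edge corrections for perfect
    accuracy; variability components are set to mid-range starting values.
    """
    rt = np.asarray(rt, float)
    acc = np.asarray(acc, int)
    n = rt.size
    pc = float(np.clip(acc.mean(), 0.5 + 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))
    rt_c = rt[acc == 1] if (acc == 1).sum() >= 5 else rt
    vrt = float(np.var(rt_c)) or 1e-4
    mrt = float(np.mean(rt_c))
    L = np.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
    v = float(np.clip(np.sign(pc - 0.5) * abs(x) ** 0.25, *bounds.v))
    v = max(v, 0.5)
    a = float(np.clip(L / v, *bounds.a))
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(-v * a)) / (1.0 + np.exp(-v * a))
    t0 = float(np.clip(mrt - mdt, max(bounds.t0[0], 0.06), bounds.t0[1]))
    return DDMParams(
        v=v, a=a, t0=t0, sv=1.0, sz=0.2 * a, st0=min(0.1, 1.8 * t0 / 2.0)
    )


class _BatchNegSLL:
    """Vectorised negative summed log likelihood over a swarm of parameter
    vectors.  Evaluates the Wiener kernel once per (particle, condition) on a
    flattened (trial, node) grid with preallocated buffers."""

    def __init__(self, rt_by_cond, acc_by_cond, layout, conditions, bounds,
                 contaminant: ContaminantSpec, quad: QuadratureConfig):
        self.layout = layout
        self.conditions = conditions
        self.bounds = bounds
        self.quad = quad
        self.data = {}
        for cond in conditions:
            rt = rt_by_cond[cond]
            acc = acc_by_cond[cond]
            rt_min = contaminant.rt_min if contaminant.rt_min is not None else rt.min()
            rt_max = contaminant.rt_max if contaminant.rt_max is not None else rt.max()
            p = contaminant.proportion
            if p > 0 and rt_max <= rt_min:
                raise ValueError("zero contaminant range in condition " + str(cond))
            unif = p * 0.5 / (rt_max - rt_min) if p > 0 else 0.0
            upper = acc == 1
            # each boundary's density is only needed for its own trials
            self.data[cond] = (
                np.ascontiguousarray(rt[upper]),
                np.ascontiguousarray(rt[~upper]),
                p,
                unif,
            )

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        P = X.shape[0]
        out = np.zeros(P)
        all_params, valid = [], []
        for i, x in enumerate(X):
            try:
                all_params.append(
                    _vector_to_params(x, self.layout, self.conditions, self.bounds)
                )
                valid.append(i)
            except ValueError:
                all_params.append(None)
                out[i] = np.inf
        if not valid:
            return out
        for cond in self.conditions:
            rt_up, rt_lo, p, unif = self.data[cond]
            for rt_b, boundary in ((rt_up, "upper"), (rt_lo, "lower")):
                if rt_b.size == 0:
                    continue
                # stack every particle's (n, D) grid into one kernel pass
                tds, vvs, wws, wtss, aas = [], [], [], [], []
                for i in valid:
                    par = all_params[i][cond]
                    tdec, V, W, wts = _mixing_arrays(
                        par, self.quad, rt_b, force_full=True
                    )
                    tds.append(tdec)
                    vvs.append(np.broadcast_to(V, tdec.shape))
                    wws.append(np.broadcast_to(W, tdec.shape))
                    wtss.append(wts)
                    aas.append(np.full(tdec.shape, par.a))
                dens = wiener_fpt_density(
                    np.concatenate(tds),
                    np.concatenate(vvs),
                    np.concatenate(aas),
                    np.concatenate(wws),
                    boundary,
                )
                dens = dens.reshape(len(valid), rt_b.size, -1)
                wts3 = np.stack(wtss)
                lik = (1.0 - p) * np.sum(dens * wts3, axis=2) + unif
                sll_part = np.sum(np.log(np.maximum(lik, 1e-300)), axis=1)
                for j, i in enumerate(valid):
                    out[i] -= sll_part[j]
        return out


@dataclass
class DDMFit:
    """Results of fitting one DDM constraint spec to one participant."""

    spec: DDMModelSpec
    params_by_condition: dict
    sll: float
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

    def summary(self) -> str:
        lines = [
            f"DDM fit  spec={self.spec.name}  k={self.k}  n={self.n}",
            f"SLL = {self.sll:.4f}   BIC = {self.bic:.4f}",
            self.params.round(4).to_string(),
        ]
        return "\n".join(lines)


class DiffusionModel:
    """Full DDM with contaminant mixture for one participant's asymptotic trials.

    Parameters
    ----------
    data : DataFrame
        Trials with columns ``rt`` (seconds), ``accuracy`` (0/1) and, for a
        two-condition fit, ``instruction``.  The caller restricts to the
        asymptotic window (the model assumes stationary behaviour).
    condition_col, rt_col, accuracy_col : str
        Column names.
    contaminant : ContaminantSpec
        Mixture spec; the default assumes 5% uniform contaminants spanning
        the observed RT range per condition.
    quad : QuadratureConfig
        Quadrature nodes for the variability integrals.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        condition_col: str = "instruction",
        rt_col: str = "rt",
        accuracy_col: str = "accuracy",
        contaminant: ContaminantSpec = ContaminantSpec(),
        quad: QuadratureConfig = QuadratureConfig(),
        bounds: DDMBounds = DDMBounds(),
    ):
        self.data = data.reset_index(drop=True)
        self.condition_col = condition_col
        self.rt_col = rt_col
        self.accuracy_col = accuracy_col
        self.contaminant = contaminant
        self.quad = quad
        self.bounds = bounds
        rt = np.asarray(self.data[rt_col], dtype=float)
        if np.any(~np.isfinite(rt)) or np.any((rt < 0) | (rt > 5.0)):
            raise ValueError("RTs must be finite and within [0, 5] seconds")
        if condition_col in self.data.columns:
            self.conditions = sorted(self.data[condition_col].unique().tolist())
        else:
            self.conditions = ["all"]
        self.nobs = len(self.data)

    @classmethod
    def from_dataframe(cls, data, **kw):
        return cls(data, **kw)

    def _split(self):
        rt_by, acc_by = {}, {}
        for cond in self.conditions:
            if cond == "all" and self.condition_col not in self.data.columns:
                sub = self.data
            else:
                sub = self.data[self.data[self.condition_col] == cond]
            rt_by[cond] = np.ascontiguousarray(sub[self.rt_col], dtype=float)
            acc_by[cond] = np.asarray(sub[self.accuracy_col], dtype=int)
        return rt_by, acc_by

    def loglike(self, params_by_condition: dict) -> float:
        """Mixture SLL at the given parameters."""
        return mixture_loglik(
            self.data,
            params_by_condition,
            self.contaminant,
            self.quad,
            condition_col=self.condition_col,
            rt_col=self.rt_col,
            accuracy_col=self.accuracy_col,
        )

    def fit(
        self,
        spec: DDMModelSpec = DDMModelSpec(),
        optimizer: OptimizerConfig | None = None,
        seed: int | None = None,
        start_params: dict | None = None,
        refine_quad: QuadratureConfig | None = None,
    ) -> DDMFit:
        """Fit one constraint spec by PSO on -SLL; returns the best restart.

        With ``refine_quad``, every restart's optimum is re-scored under the
        (finer) refinement quadrature and the winner is Nelder-Mead polished
        there.  This guards against spurious optima in extreme-variability
        corners where a light search quadrature is least accurate, while
        keeping the swarm itself cheap.
        """
        if len(self.conditions) == 1 and spec.free_params:
            raise ValueError(
                "single-condition data cannot identify a condition-freeing spec"
            )
        k = spec.k(len(self.conditions))
        if self.nobs < k + 5:
            raise ValueError(f"need at least k+5={k + 5} trials, got {self.nobs}")
        optimizer = optimizer or OptimizerConfig(swarm_size=24, iterations=80, n_restarts=2)
        layout = _spec_layout(spec, self.conditions, self.bounds)
        rt_by, acc_by = self._split()
        negsll = _BatchNegSLL(
            rt_by, acc_by, layout, self.conditions, self.bounds, self.contaminant, self.quad
        )
        if start_params is None:
            # closed-form EZ-diffusion estimates seed one swarm particle
            start_params = {
                cond: ez_diffusion_start(rt_by[cond], acc_by[cond], self.bounds)
                for cond in self.conditions
            }
        x0 = _params_to_vector(start_params, layout, self.bounds)
        res = minimize_pso(
            negsll,
            [b for _, _, b in layout],
            optimizer,
            seed=seed,
            x0=x0,
        )
        if refine_quad is not None:
            from scipy import optimize as _sciopt

            fine = _BatchNegSLL(
                rt_by, acc_by, layout, self.conditions, self.bounds,
                self.contaminant, refine_quad,
            )
            candidates = np.asarray(res.restart_xs)
            scores = fine(candidates)
            best = candidates[int(np.argmin(scores))]
            ndim = best.size
            polished = _sciopt.minimize(
                lambda x: float(fine(x[None, :])[0]),
                best,
                method="Nelder-Mead",
                bounds=[b for _, _, b in layout],
                options={"maxiter": 60 * ndim, "maxfev": 60 * ndim,
                         "xatol": 1e-5, "fatol": 1e-7},
            )
            res.x = np.clip(polished.x, *np.asarray([b for _, _, b in layout]).T)
            res.fun = float(polished.fun)
        params = _vector_to_params(res.x, layout, self.conditions, self.bounds)
        sll = -res.fun
        from .model_selection import bic_from_sll

        return DDMFit(
            spec=spec,
            params_by_condition=params,
            sll=sll,
            n=self.nobs,
            k=k,
            bic=bic_from_sll(k, self.nobs, sll),
            optimizer_result=res,
        )

    def fit_hierarchy(
        self,
        optimizer: OptimizerConfig | None = None,
        seed: int | None = None,
        participant_id=None,
    ):
        """Fit all 8 constraint specs and return a
        :class:`~skillfit.model_selection.ModelComparison`.

        The none spec is fitted first and its solution is injected into the
        starting swarm of every larger spec: since a nested optimum is a
        feasible point of every nesting model, the larger fits can never end
        below it, preserving the SLL dominance of the hierarchy.
        """
        from .model_selection import ModelComparison

        specs = ddm_model_hierarchy()
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


def fit_ddm(
    trials: pd.DataFrame,
    spec: DDMModelSpec = DDMModelSpec(),
    contaminant: ContaminantSpec = ContaminantSpec(),
    opt: OptimizerConfig | None = None,
    seed: int | None = None,
    **model_kw,
) -> DDMFit:
    """Functional wrapper: fit one DDM constraint spec to one participant."""
    model = DiffusionModel(trials, contaminant=contaminant, **model_kw)
    return model.fit(spec, optimizer=opt, seed=seed)
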