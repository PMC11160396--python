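"""BIC-based model comparison, weights, averaging and group Bayes factors.

Two BIC conventions are used, matching the two fitting regimes:

* least-squares fits:      ``BIC = k ln(n) + n ln(SSE / n)``
* maximum-likelihood fits: ``BIC = k ln(n) - 2 SLL``

BIC weights follow the Wagenmakers-Farrell convention
``w_i = exp(-dBIC_i / 2) / sum_j exp(-dBIC_j / 2)`` with ``dBIC_i`` the
difference from the minimum BIC, read as posterior model probabilities.
Model-averaged parameters are BIC-weight-weighted means over the candidate
models, and the group-level Bayes factor between two models is the ratio of
their mean per-participant weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "bic_from_sse",
    "bic_from_sll",
    "bic_weights",
    "ModelComparison",
    "model_average",
    "group_bayes_factor",
]


def bic_from_sse(k: int, n: int, sse: float) -> float:
    """BIC of a least-squares fit: ``k ln(n) + n ln(SSE/n)`` (natural log)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not np.isfinite(sse) or sse <= 0:
        raise ValueError(
            "SSE must be finite and > 0 (noiseless data give SSE = 0; jitter or reject)"
        )
    return float(k * np.log(n) + n * np.log(sse / n))


def bic_from_sll(k: int, n: int, sll: float) -> float:
    """BIC of a maximum-likelihood fit: ``k ln(n) - 2 SLL`` (natural log)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not np.isfinite(sll):
        raise ValueError("SLL must be finite")
    return float(k * np.log(n) - 2.0 * sll)


def bic_weights(bics) -> np.ndarray:
    """Normalised ``exp(-BIC/2)`` weights, computed after subtracting the
    minimum BIC for numerical stability."""
    bics = np.asarray(bics, dtype=float)
    if bics.size < 1:
        raise ValueError("need at least one BIC")
    if np.any(~np.isfinite(bics)):
        raise ValueError("all BICs must be finite")
    d = bics - bics.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


@dataclass
class ModelComparison:
    """A participant's fits over one model hierarchy, with BIC weights.

    All fits must score the same data (identical ``n``); weights are
    computed on construction and sum to 1.
    """

    participant_id: object = None
    fits: list = field(default_factory=list)
    weights: np.ndarray = field(init=False)

    def __post_init__(self):
        if not self.fits:
            raise ValueError("ModelComparison requires at least one fit")
        ns = {fit.n for fit in self.fits}
        if len(ns) != 1:
            raise ValueError(f"fits must share identical data; got n = {sorted(ns)}")
        self.weights = bic_weights([fit.bic for fit in self.fits])

    @property
    def spec_names(self) -> list[str]:
        return [fit.spec.name for fit in self.fits]

    def weight_of(self, spec_name: str) -> float:
        try:
            i = self.spec_names.index(spec_name)
        except ValueError:
            raise KeyError(f"no fit with spec {spec_name!r}") from None
        return float(self.weights[i])

    @property
    def best_spec(self) -> str:
        return self.spec_names[int(np.argmax(self.weights))]

    def model_average(self, parameter: str, condition) -> float:
        return model_average(self, parameter, condition)

    def summary(self) -> str:
        lines = [f"Model comparison  participant={self.participant_id}  n={self.fits[0].n}"]
        order = np.argsort([f.bic for f in self.fits])
        for i in order:
            f = self.fits[i]
            lines.append(
                f"  {f.spec.name:>12s}  k={f.k:2d}  BIC={f.bic:10.3f}  w={self.weights[i]:.4f}"
            )
        return "\n".join(lines)


def model_average(comparison: ModelComparison, parameter: str, condition) -> float:
    """BIC-weight-weighted mean of one parameter for one condition.

    Tied fits contribute their shared value; every fit must provide the
    parameter for the condition.
    """
    values = []
    for fit in comparison.fits:
        try:
            values.append(fit.get_param(parameter, condition))
        except (AttributeError, KeyError) as exc:
            raise ValueError(
                f"fit {fit.spec.name!r} does not supply {parameter!r} for {condition!r}"
            ) from exc
    return float(np.dot(comparison.weights, values))


def group_bayes_factor(comparisons, model_a: str, model_b: str) -> float:
    """Group-level Bayes factor of ``model_a`` over ``model_b``.

    Defined as the ratio of the mean per-participant BIC weight of the two
    models.  Returns ``inf`` with a warning when the mean weight of
    ``model_b`` is zero.
    """
    w_a = np.array([c.weight_of(model_a) for c in comparisons])
    w_b = np.array([c.weight_of(model_b) for c in comparisons])
    mean_b = w_b.mean()
    if mean_b == 0:
        warnings.warn(
            f"mean weight of {model_b!r} is zero; Bayes factor reported as inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(w_a.mean() / mean_b)
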