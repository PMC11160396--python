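"""First-passage-time density of the Wiener diffusion between two boundaries.

The density of a drift-diffusion process (drift ``v``, diffusion coefficient
``s = 1``) started at relative position ``w = z/a`` between absorbing
boundaries at 0 and ``a`` is evaluated with the classic pair of series
expansions — a small-time expansion in image terms and a large-time
eigenfunction expansion — choosing, per evaluation point, the representation
that needs fewer terms for a requested truncation error (Navarro-Fuss term
selection).  All functions broadcast over their array arguments.

Decision times here are measured from the start of accumulation, i.e. the
non-decision time has already been subtracted by the caller.
"""

from __future__ import annotations

import numpy as np

try:  # compiled kernel; the pure-numpy path below is the reference fallback
    import numba as _nb
except ImportError:  # pragma: no cover
    _nb = None

__all__ = ["wiener_fpt_density", "prob_upper", "mean_decision_time"]

_MAX_TERMS = 64


def _terms_small(tau: float, err: float) -> float:
    """Image-expansion terms needed at scaled time ``tau`` for error <= err."""
    arg = 2.0 * np.sqrt(2.0 * np.pi * tau) * err
    if arg < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tau * np.log(arg))
    else:
        ks = 2.0
    return max(ks, np.sqrt(tau) + 1.0)


def _terms_large(tau: float, err: float) -> float:
    """Eigenfunction-expansion terms needed at scaled time ``tau``."""
    arg = np.pi * tau * err
    if arg < 1.0:
        kl = np.sqrt(-2.0 * np.log(arg) / (np.pi**2 * tau))
    else:
        kl = 1.0 / (np.pi * np.sqrt(tau))
    return max(kl, 1.0 / (np.pi * np.sqrt(tau)))


def _crossover_tau(err: float) -> float:
    """Scaled time at which both expansions need equally many terms.

    Below the crossover the small-time (image) expansion is cheaper, above it
    the large-time (eigenfunction) expansion is; selecting by this threshold
    is exactly the per-evaluation fewest-terms rule.
    """
    lo, hi = 1e-4, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _terms_small(mid, err) < _terms_large(mid, err):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_CROSSOVER_CACHE: dict[float, float] = {}


def _fpt_density_lower_std(tau: np.ndarray, w: np.ndarray, err: float) -> np.ndarray:
    """Standardised (a=1, v=0) lower-boundary FPT density f(tau | 0, 1, w)."""
    tau = np.asarray(tau, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), tau.shape)
    out = np.zeros(tau.shape, dtype=float)
    pos = tau > 0
    if not np.any(pos):
        return out
    tt = tau[pos]
    ww = w[pos]

    tau_c = _CROSSOVER_CACHE.get(err)
    if tau_c is None:
        tau_c = _CROSSOVER_CACHE[err] = _crossover_tau(err)

    use_small = tt < tau_c
    dens = np.empty(tt.shape, dtype=float)

    # The series are accumulated term-by-term with in-place ops on n-sized
    # buffers; an (n, K) outer product would allocate large temporaries.
    if np.any(use_small):
        t_s, w_s = tt[use_small], ww[use_small]
        # term count is increasing in tau: the branch maximum covers all
        K = int(min(np.ceil(_terms_small(float(t_s.max()), err)), _MAX_TERMS))
        ks = range(-((K - 1) // 2), ((K - 1) // 2) + (K - 1) % 2 + 1)
        inv2t = -0.5 / t_s
        acc = np.zeros_like(t_s)
        x = np.empty_like(t_s)
        buf = np.empty_like(t_s)
        for k in ks:
            # term: (w + 2k) exp(-(w + 2k)^2 / (2 tau))
            np.add(w_s, 2.0 * k, out=x)
            np.multiply(x, x, out=buf)
            np.multiply(buf, inv2t, out=buf)
            np.exp(buf, out=buf)
            np.multiply(buf, x, out=buf)
            acc += buf
        acc /= np.sqrt(2.0 * np.pi * t_s**3)
        dens[use_small] = acc

    use_large = ~use_small
    if np.any(use_large):
        t_l, w_l = tt[use_large], ww[use_large]
        # term count is decreasing in tau: the branch minimum covers all
        K = int(min(np.ceil(_terms_large(float(t_l.min()), err)), _MAX_TERMS))
        half_pisq_t = -(np.pi**2) * 0.5 * t_l
        acc = np.zeros_like(t_l)
        buf = np.empty_like(t_l)
        buf2 = np.empty_like(t_l)
        for k in range(1, K + 1):
            # term: k exp(-k^2 pi^2 tau / 2) sin(k pi w)
            np.multiply(half_pisq_t, float(k * k), out=buf)
            np.exp(buf, out=buf)
            np.multiply(w_l, k * np.pi, out=buf2)
            np.sin(buf2, out=buf2)
            np.multiply(buf, buf2, out=buf)
            acc += float(k) * buf
        dens[use_large] = np.pi * acc

    out[pos] = np.maximum(dens, 0.0)
    return out


if _nb is not None:

    @_nb.njit(cache=True, fastmath=False)
    def _dens_kernel(t, v, a, w, err, out):  # pragma: no cover - exercised via wrapper
        sq2pi = np.sqrt(2.0 * np.pi)
        for i in range(t.size):
            ti = t[i]
            if ti <= 0.0:
                out[i] = 0.0
                continue
            ai = a[i]
            wi = w[i]
            vi = v[i]
            tau = ti / (ai * ai)
            # terms needed by each expansion (per-evaluation selection)
            arg_s = 2.0 * sq2pi * np.sqrt(tau) * err
            if arg_s < 1.0:
                ks = 2.0 + np.sqrt(-2.0 * tau * np.log(arg_s))
            else:
                ks = 2.0
            if ks < np.sqrt(tau) + 1.0:
                ks = np.sqrt(tau) + 1.0
            arg_l = np.pi * tau * err
            inv_pisqrt = 1.0 / (np.pi * np.sqrt(tau))
            if arg_l < 1.0:
                kl = np.sqrt(-2.0 * np.log(arg_l) / (np.pi * np.pi * tau))
            else:
                kl = inv_pisqrt
            if kl < inv_pisqrt:
                kl = inv_pisqrt

            if ks < kl:
                K = int(np.ceil(ks))
                if K > _MAX_TERMS:
                    K = _MAX_TERMS
                lo = -((K - 1) // 2)
                hi = (K - 1) // 2 + (K - 1) % 2
                acc = 0.0
                for k in range(lo, hi + 1):
                    x = wi + 2.0 * k
                    acc += x * np.exp(-x * x / (2.0 * tau))
                f = acc / np.sqrt(2.0 * np.pi * tau**3)
            else:
                K = int(np.ceil(kl))
                if K > _MAX_TERMS:
                    K = _MAX_TERMS
                acc = 0.0
                for k in range(1, K + 1):
                    acc += k * np.exp(-k * k * np.pi * np.pi * tau / 2.0) * np.sin(
                        k * np.pi * wi
                    )
                f = np.pi * acc
            if f < 0.0:
                f = 0.0
            out[i] = f * np.exp(-vi * ai * wi - vi * vi * ti / 2.0) / (ai * ai)


def wiener_fpt_density(t, v, a, w=0.5, boundary="upper", err: float = 1e-7):
    """Defective FPT density at one boundary of the Wiener diffusion.

    Parameters
    ----------
    t : array_like
        Decision time in seconds (time since accumulation onset); the density
        is 0 for ``t <= 0``.
    v : array_like
        Drift rate (evidence per second, s = 1 scaling).
    a : array_like
        Boundary separation (> 0).
    w : array_like
        Relative start point ``z/a`` in (0, 1); 0.5 is the unbiased start.
    boundary : {"upper", "lower"}
        Which absorbing boundary the density refers to.
    err : float
        Series truncation error per evaluation.

    Returns
    -------
    ndarray
        Density per second, integrating over ``t`` to the probability of
        absorption at ``boundary``.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v)) and np.all(np.isfinite(a)) and np.all(np.isfinite(w))):
        raise ValueError("wiener_fpt_density requires finite inputs")
    if np.any(a <= 0):
        raise ValueError("boundary separation a must be > 0")
    if np.any((w <= 0) | (w >= 1)):
        raise ValueError("relative start point w must lie strictly in (0, 1)")
    if boundary == "upper":
        v, w = -v, 1.0 - w
    elif boundary != "lower":
        raise ValueError("boundary must be 'upper' or 'lower'")

    t, v, a, w = np.broadcast_arrays(t, v, a, w)
    if _nb is not None:
        shape = t.shape
        out = np.empty(t.size, dtype=float)
        _dens_kernel(
            np.ascontiguousarray(t, dtype=float).ravel(),
            np.ascontiguousarray(v, dtype=float).ravel(),
            np.ascontiguousarray(a, dtype=float).ravel(),
            np.ascontiguousarray(w, dtype=float).ravel(),
            err,
            out,
        )
        return out.reshape(shape)
    tau = t / a**2
    base = _fpt_density_lower_std(tau, w, err)
    with np.errstate(over="ignore"):
        scale = np.exp(-v * a * w - v**2 * t / 2.0) / a**2
    return np.where(t > 0, base * scale, 0.0)


def prob_upper(v, a, w=0.5):
    """Probability of absorption at the upper boundary.

    Closed form ``(1 - exp(-2 v a w)) / (1 - exp(-2 v a))`` with the ``v -> 0``
    limit ``w``; evaluated stably with expm1.
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    v, a, w = np.broadcast_arrays(v, a, w)
    small = np.abs(v) * a < 1e-9
    vv = np.where(small, 1.0, v)
    with np.errstate(over="ignore"):
        p = np.expm1(-2.0 * vv * a * w) / np.expm1(-2.0 * vv * a)
    return np.where(small, w, p)


def mean_decision_time(v, a, w=0.5):
    """Expected decision time to absorption at either boundary.

    By Wald's identity ``E[X_T] = z + v E[T]`` and ``E[X_T] = a p_upper``,
    so ``E[T] = (a p_upper - z) / v``; the ``v -> 0`` limit is ``z (a - z)``
    (diffusion coefficient s = 1).
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    v, a, w = np.broadcast_arrays(v, a, w)
    z = w * a
    small = np.abs(v) * a < 1e-9
    vv = np.where(small, 1.0, v)
    p_up = prob_upper(v, a, w)
    return np.where(small, z * (a - z), (a * p_up - z) / vv)
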