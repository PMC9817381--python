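"""Seasonal ARIMA modelling of hourly activity series.

Implements SARIMA(p, d, q)(P, D, Q)_m with multiplicative seasonal
polynomials and no constant term (the study design fixes d = D = 1, so any
deterministic level is removed by differencing).  Two estimation routes are
provided:

* ``method="css"`` — conditional sum of squares: innovations are computed
  recursively with zero pre-sample values and the Gaussian likelihood is
  evaluated over the ``n_effective`` differenced observations.
* ``method="ml"`` (default) — exact Gaussian maximum likelihood of the
  differenced ARMA process via a Kalman filter in the Harvey state-space
  form, with the stationary initial state covariance and a steady-state
  switch once the filter covariance has converged.  The optimizer is
  warm-started from the CSS estimate.

The MA sign convention puts θ and Θ with a **plus** sign on the innovation
side: ``w_t = Σ φ_i w_{t-i} + Σ θ_j ε_{t-j} + ε_t`` (seasonal factors
multiplicative).  σ² is profiled out in closed form, so the optimizer works
on the concentrated likelihood of the AR/MA weights alone.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numba
import numpy as np
from scipy import optimize, signal

__all__ = [
    "SarimaSpec",
    "SarimaModel",
    "SarimaResults",
    "SarimaFit",
    "difference",
    "inverse_difference",
    "expand_polynomials",
    "check_roots",
    "css_innovations",
    "css_loglik",
    "NonInvertibleError",
]

#: margin by which AR/MA polynomial roots must exceed the unit circle
ROOT_MARGIN = 1e-3
#: large penalty returned by the objective outside the admissible region
_PENALTY = 1e10


def _coef_bounds(spec: "SarimaSpec") -> list[tuple[float, float]]:
    """Box bounds per coefficient from the polynomial structure.

    A degree-k polynomial with all roots outside the unit circle has its
    i-th coefficient bounded by C(k, i) in magnitude (elementary symmetric
    functions of roots inside the unit disk), so e.g. an AR(2) admits
    |phi_1| up to 2.  A small slack keeps the optimizer off the closure;
    admissibility proper is enforced by the root checks.
    """
    bounds: list[tuple[float, float]] = []
    for order in (spec.p, spec.q):
        for i in range(1, order + 1):
            b = math.comb(order, i) - 0.002
            bounds.append((-b, b))
    for order in (spec.P, spec.Q):
        for i in range(1, order + 1):
            b = math.comb(order, i) - 0.002
            bounds.append((-b, b))
    return bounds


class NonInvertibleError(ValueError):
    """Raised when AR/MA weights violate stationarity or invertibility."""


@dataclass(frozen=True)
class SarimaSpec:
    """Hyper-parameter orders of a SARIMA(p, d, q)(P, D, Q)_m model."""

    p: int
    d: int
    q: int
    P: int
    D: int
    Q: int
    m: int = 24

    def __post_init__(self) -> None:
        for name in ("p", "d", "q", "P", "D", "Q", "m"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"order {name} must be a nonnegative integer, got {v!r}")
        if self.m < 1:
            raise ValueError("seasonal period m must be >= 1")
        if (self.P or self.Q or self.D) and self.m < 2:
            raise ValueError("seasonal orders require m >= 2")

    # -- derived quantities -------------------------------------------------
    @property
    def n_params(self) -> int:
        """Number of free AR/MA weights (excluding sigma2)."""
        return self.p + self.q + self.P + self.Q

    @property
    def k(self) -> int:
        """Parameter count entering AIC (weights + sigma2)."""
        return self.n_params + 1

    @property
    def n_diff(self) -> int:
        """Observations lost to differencing: d + D*m."""
        return self.d + self.D * self.m

    @property
    def min_length(self) -> int:
        """Minimum series length for the likelihood to be defined."""
        return self.n_diff + max(self.p + self.P * self.m, self.q + self.Q * self.m) + 1

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def seasonal_order(self) -> tuple[int, int, int, int]:
        return (self.P, self.D, self.Q, self.m)

    @property
    def param_names(self) -> list[str]:
        names = [f"ar.L{i}" for i in range(1, self.p + 1)]
        names += [f"ma.L{i}" for i in range(1, self.q + 1)]
        names += [f"ar.S.L{(i + 1) * self.m}" for i in range(self.P)]
        names += [f"ma.S.L{(i + 1) * self.m}" for i in range(self.Q)]
        return names

    def label(self) -> str:
        return (
            f"SARIMA({self.p},{self.d},{self.q})"
            f"({self.P},{self.D},{self.Q})[{self.m}]"
        )

    def as_tuple(self) -> tuple[int, ...]:
        return (self.p, self.d, self.q, self.P, self.D, self.Q, self.m)

    def weights_from_mapping(self, weights: Mapping[str, float]) -> np.ndarray:
        """Build the parameter vector from short names (ar1, ma2, sar1, sma1).

        Exactly one value must be supplied per nonzero order; extra keys are
        rejected.
        """
        short = {}
        for i in range(1, self.p + 1):
            short[f"ar{i}"] = None
        for i in range(1, self.q + 1):
            short[f"ma{i}"] = None
        for i in range(1, self.P + 1):
            short[f"sar{i}"] = None
        for i in range(1, self.Q + 1):
            short[f"sma{i}"] = None
        unknown = set(weights) - set(short)
        if unknown:
            raise ValueError(f"weights {sorted(unknown)} not present in {self.label()}")
        missing = set(short) - set(weights)
        if missing:
            raise ValueError(f"missing weights {sorted(missing)} for {self.label()}")
        return np.array([float(weights[k]) for k in short], dtype=float)


# ---------------------------------------------------------------------------
# differencing
# ---------------------------------------------------------------------------

def difference(y: Sequence[float], d: int = 1, D: int = 1, m: int = 24) -> np.ndarray:
    """Apply the operator (1 - B)^d (1 - B^m)^D to ``y``.

    The output has length ``len(y) - d - D*m`` (165 -> 140 for the study's
    d = D = 1, m = 24 design).
    """
    y = np.asarray(y, dtype=float)
    need = d + D * m + 1
    if y.ndim != 1:
        raise ValueError("y must be one-dimensional")
    if len(y) < need:
        raise ValueError(
            f"series of length {len(y)} too short for d={d}, D={D}, m={m}; "
            f"minimum length is {need}"
        )
    w = y
    for _ in range(d):
        w = w[1:] - w[:-1]
    for _ in range(D):
        w = w[m:] - w[:-m]
    return w


def _diff_operator(d: int, D: int, m: int) -> np.ndarray:
    """Coefficients of (1 - B)^d (1 - B^m)^D in increasing powers of B."""
    c = np.array([1.0])
    one_b = np.array([1.0, -1.0])
    one_bm = np.zeros(m + 1)
    one_bm[0], one_bm[-1] = 1.0, -1.0
    for _ in range(d):
        c = np.convolve(c, one_b)
    for _ in range(D):
        c = np.convolve(c, one_bm)
    return c


def inverse_difference(
    w: Sequence[float], head: Sequence[float], d: int = 1, D: int = 1, m: int = 24
) -> np.ndarray:
    """Undo :func:`difference` given the first ``d + D*m`` original values.

    Reconstructs y of length ``len(head) + len(w)`` satisfying
    ``difference(y, d, D, m) == w`` with ``y[:d+D*m] == head``.
    """
    w = np.asarray(w, dtype=float)
    head = np.asarray(head, dtype=float)
    K = d + D * m
    if len(head) != K:
        raise ValueError(f"head must contain exactly d + D*m = {K} values")
    c = _diff_operator(d, D, m)  # c[0] == 1
    n = K + len(w)
    y = np.empty(n)
    y[:K] = head
    for t in range(K, n):
        acc = w[t - K]
        for i in range(1, K + 1):
            acc -= c[i] * y[t - i]
        y[t] = acc
    return y


# ---------------------------------------------------------------------------
# polynomials and admissibility
# ---------------------------------------------------------------------------

def _split_params(spec: SarimaSpec, params: np.ndarray):
    p, q, P, Q = spec.p, spec.q, spec.P, spec.Q
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.n_params,):
        raise ValueError(
            f"expected {spec.n_params} weights for {spec.label()}, got {params.shape}"
        )
    i = 0
    phi = params[i : i + p]
    i += p
    theta = params[i : i + q]
    i += q
    Phi = params[i : i + P]
    i += P
    Theta = params[i : i + Q]
    return phi, theta, Phi, Theta


def expand_polynomials(spec: SarimaSpec, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expanded AR and MA lag polynomials (coefficients of increasing B powers).

    AR side: φ(B)·Φ(B^m) written as ``1 + a_1 B + ...`` with a_i = -φ_i etc.;
    MA side: θ(B)·Θ(B^m) written as ``1 + b_1 B + ...``.
    """
    phi, theta, Phi, Theta = _split_params(spec, params)
    m = spec.m
    ar = np.r_[1.0, -phi]
    sar = np.zeros(spec.P * m + 1)
    sar[0] = 1.0
    for j, c in enumerate(Phi):
        sar[(j + 1) * m] = -c
    ma = np.r_[1.0, theta]
    sma = np.zeros(spec.Q * m + 1)
    sma[0] = 1.0
    for j, c in enumerate(Theta):
        sma[(j + 1) * m] = c
    return np.convolve(ar, sar), np.convolve(ma, sma)


def _poly_ok(coefs: np.ndarray, margin: float) -> bool:
    """True if all roots of 1 + c1 z + ... + ck z^k lie outside |z| = 1+margin.

    For degree <= 3 the reciprocal polynomial's Schur-Cohn (Jury) stability
    conditions are evaluated in closed form (the optimizer calls this in its
    inner loop); higher degrees fall back to an eigenvalue root find.
    """
    c = np.trim_zeros(coefs, "b")
    k = len(c) - 1
    if k <= 0:
        return True
    s = 1.0 + margin
    # roots of 1 + sum c_i z^i outside |z| = s  <=>  roots of the scaled
    # reciprocal monic polynomial w^k + a_1 w^(k-1) + ... + a_k strictly
    # inside the unit circle, with a_i = c_i * s^i
    a = [c[i] * s ** i for i in range(1, k + 1)]
    if k == 1:
        return abs(a[0]) < 1.0
    if k == 2:
        return abs(a[1]) < 1.0 and abs(a[0]) < 1.0 + a[1]
    if k == 3:
        a1, a2, a3 = a
        return (
            abs(a3) < 1.0
            and abs(a1 + a3) < 1.0 + a2
            and abs(a2 - a1 * a3) < 1.0 - a3 * a3
        )
    roots = np.roots(c[::-1])
    return bool(np.abs(roots).min() > s)


def check_roots(spec: SarimaSpec, params: np.ndarray, margin: float = ROOT_MARGIN) -> str | None:
    """Return the name of the first offending polynomial, or None if admissible.

    Each factor (non-seasonal AR/MA, seasonal AR/MA) is checked separately so
    the diagnostic names the polynomial that violates the condition.  A
    seasonal factor of degree k in B^m is checked through its roots in
    u = B^m (|u| must exceed (1+margin)^m), avoiding a degree-k*m root find.
    """
    phi, theta, Phi, Theta = _split_params(spec, params)
    checks = [
        ("non-seasonal AR", np.r_[1.0, -phi], margin),
        ("non-seasonal MA", np.r_[1.0, theta], margin),
        ("seasonal AR", np.r_[1.0, -Phi], (1.0 + margin) ** spec.m - 1.0),
        ("seasonal MA", np.r_[1.0, Theta], (1.0 + margin) ** spec.m - 1.0),
    ]
    for name, poly, eff_margin in checks:
        if not _poly_ok(poly, eff_margin):
            return name
    return None


# ---------------------------------------------------------------------------
# conditional sum of squares
# ---------------------------------------------------------------------------

def css_innovations(w: Sequence[float], spec: SarimaSpec, params: np.ndarray) -> np.ndarray:
    """Recursive innovations with zero pre-sample values for w and ε."""
    w = np.asarray(w, dtype=float)
    a, b = expand_polynomials(spec, params)
    # a(B) w_t = b(B) eps_t  =>  eps_t = w_t + sum a_i w_{t-i} - sum b_j eps_{t-j}
    eps = signal.lfilter(a, b, w)
    if not np.all(np.isfinite(eps)):
        raise NonInvertibleError(
            f"non-finite innovations for {spec.label()}: explosive weights"
        )
    return eps


def css_loglik(
    w: Sequence[float], spec: SarimaSpec, params: np.ndarray, sigma2: float
) -> float:
    """Conditional Gaussian log-likelihood at given weights and sigma2."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    eps = css_innovations(w, spec, params)
    n = len(eps)
    return float(-0.5 * n * math.log(2 * math.pi * sigma2) - (eps @ eps) / (2 * sigma2))


def _css_neg_concentrated(params: np.ndarray, w: np.ndarray, spec: SarimaSpec) -> float:
    a, b = expand_polynomials(spec, params)
    eps = signal.lfilter(a, b, w)
    if not np.all(np.isfinite(eps)):
        return _PENALTY
    sse = float(eps @ eps)
    if sse <= 0:
        return _PENALTY
    n = len(w)
    return 0.5 * n * (math.log(2 * math.pi * sse / n) + 1.0)


# ---------------------------------------------------------------------------
# exact Gaussian likelihood (Kalman filter)
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _stationary_cov(phi_f, RRT):  # pragma: no cover - exercised via wrapper
    """Stationary covariance of the companion state by doubling.

    Solves P = T P T' + RRT for the companion transition T built from
    phi_f, iterating P <- P + M P M', M <- M M (squared spectral radius per
    step, so convergence is fast well inside the stationary region).
    """
    r = phi_f.shape[0]
    T = np.zeros((r, r))
    for i in range(r):
        T[i, 0] = phi_f[i]
        if i + 1 < r:
            T[i, i + 1] = 1.0
    P = RRT.copy()
    M = T.copy()
    for _ in range(64):
        P_new = P + M @ P @ M.T
        M = M @ M
        diff = 0.0
        scale = 1.0
        for i in range(r):
            for j in range(r):
                d = abs(P_new[i, j] - P[i, j])
                if d > diff:
                    diff = d
                a = abs(P_new[i, j])
                if a > scale:
                    scale = a
        P = P_new
        if not np.isfinite(diff):
            return P, False
        if diff < 1e-13 * scale:
            return P, True
    return P, False


@numba.njit(cache=True)
def _kalman_core(w, phi_f, R):  # pragma: no cover - exercised via wrapper
    """Concentrated Kalman recursion for a zero-mean stationary ARMA.

    Harvey companion state space with transition T (first column phi_f,
    superdiagonal ones) and disturbance loading R; returns (ssq, sumlogF)
    where ssq = sum v_t^2 / F_t and sumlogF = sum log F_t.  Switches to a
    frozen steady-state gain once the covariance recursion has converged.
    Returns (nan, nan) if a prediction variance degenerates.
    """
    r = phi_f.shape[0]
    n = w.shape[0]
    a = np.zeros(r)
    a_new = np.zeros(r)
    M = np.empty((r, r))
    Pn = np.empty((r, r))
    TPe = np.empty(r)
    Kc = np.zeros(r)
    RRT = np.empty((r, r))
    for i in range(r):
        for j in range(r):
            RRT[i, j] = R[i] * R[j]
    P, ok = _stationary_cov(phi_f, RRT)
    if not ok:
        return np.nan, np.nan
    sumlogF = 0.0
    ssq = 0.0
    steady = False
    Fc = 1.0
    logFc = 0.0
    for t in range(n):
        if not steady:
            F = P[0, 0]
            if not np.isfinite(F) or F <= 0.0:
                return np.nan, np.nan
            v = w[t] - a[0]
            for i in range(r):
                nxt = P[i + 1, 0] if i + 1 < r else 0.0
                TPe[i] = phi_f[i] * P[0, 0] + nxt
            a0 = a[0]
            for i in range(r):
                nxt = a[i + 1] if i + 1 < r else 0.0
                a_new[i] = phi_f[i] * a0 + nxt + TPe[i] * (v / F)
            for i in range(r):
                a[i] = a_new[i]
            # M = T @ P ; Pn = M @ T' - outer(TPe,TPe)/F + RRT
            for i in range(r):
                for j in range(r):
                    nxt = P[i + 1, j] if i + 1 < r else 0.0
                    M[i, j] = phi_f[i] * P[0, j] + nxt
            diff = 0.0
            for i in range(r):
                for j in range(r):
                    nxt = M[i, j + 1] if j + 1 < r else 0.0
                    val = phi_f[j] * M[i, 0] + nxt - TPe[i] * TPe[j] / F + RRT[i, j]
                    Pn[i, j] = val
            for i in range(r):
                for j in range(i, r):
                    s = 0.5 * (Pn[i, j] + Pn[j, i])
                    d = abs(s - P[i, j])
                    if d > diff:
                        diff = d
                    Pn[i, j] = s
                    Pn[j, i] = s
            sumlogF += np.log(F)
            ssq += v * v / F
            if diff < 1e-12:
                steady = True
                Fc = Pn[0, 0]
                logFc = np.log(Fc)
                for i in range(r):
                    nxt = Pn[i + 1, 0] if i + 1 < r else 0.0
                    Kc[i] = (phi_f[i] * Pn[0, 0] + nxt) / Fc
            for i in range(r):
                for j in range(r):
                    P[i, j] = Pn[i, j]
        else:
            v = w[t] - a[0]
            a0 = a[0]
            for i in range(r):
                nxt = a[i + 1] if i + 1 < r else 0.0
                a_new[i] = phi_f[i] * a0 + nxt + Kc[i] * v
            for i in range(r):
                a[i] = a_new[i]
            sumlogF += logFc
            ssq += v * v / Fc
    return ssq, sumlogF


def _state_space(spec: SarimaSpec, params: np.ndarray):
    """(phi_f, R) of the Harvey form, or None if inadmissible."""
    if check_roots(spec, params, margin=1e-6) is not None:
        return None
    a, b = expand_polynomials(spec, params)
    phi = -a[1:]
    theta = b[1:]
    r = max(len(phi), len(theta) + 1)
    phi_f = np.zeros(r)
    phi_f[: len(phi)] = phi
    R = np.zeros(r)
    R[0] = 1.0
    R[1 : len(theta) + 1] = theta
    return phi_f, R


def _exact_filter(params: np.ndarray, w: np.ndarray, spec: SarimaSpec):
    ss = _state_space(spec, params)
    if ss is None:
        return None
    ssq, sumlogF = _kalman_core(w, *ss)
    if not np.isfinite(ssq) or ssq <= 0:
        return None
    return ssq, sumlogF


def _exact_neg_concentrated(params: np.ndarray, w: np.ndarray, spec: SarimaSpec) -> float:
    """Concentrated negative exact log-likelihood of the differenced ARMA."""
    out = _exact_filter(np.asarray(params, dtype=float), w, spec)
    if out is None:
        return _PENALTY
    ssq, sumlogF = out
    n = len(w)
    sig2 = ssq / n
    return 0.5 * (n * math.log(2 * math.pi * sig2) + n + sumlogF)


def exact_loglik(w: Sequence[float], spec: SarimaSpec, params: np.ndarray) -> tuple[float, float]:
    """Exact concentrated log-likelihood and the profiled sigma2."""
    w = np.asarray(w, dtype=float)
    out = _exact_filter(np.asarray(params, dtype=float), w, spec)
    if out is None:
        raise NonInvertibleError(f"inadmissible weights for {spec.label()}")
    ssq, sumlogF = out
    n = len(w)
    sig2 = ssq / n
    ll = -0.5 * (n * math.log(2 * math.pi * sig2) + n + sumlogF)
    return ll, sig2


def _profiled_sigma2(w: np.ndarray, spec: SarimaSpec, params: np.ndarray) -> float:
    """Profiled innovation variance under the exact likelihood."""
    return exact_loglik(w, spec, params)[1]


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class SarimaResults:
    """Fitted SARIMA model: weights, likelihood, AIC and diagnostics."""

    spec: SarimaSpec
    params: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    converged: bool
    n_effective: int
    method: str = "ml"
    n_obs: int = 0

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(self.spec.param_names, map(float, self.params)))

    def weight(self, name: str, default: float = 0.0) -> float:
        """Weight by serialization name (e.g. 'ar.L1'), 0 for absent orders."""
        return self.param_dict.get(name, default)

    def to_dict(self) -> dict:
        return {
            "spec": list(self.spec.as_tuple()),
            "weights": self.param_dict,
            "sigma2": float(self.sigma2),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "converged": bool(self.converged),
            "n_effective": int(self.n_effective),
            "method": self.method,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            f"{self.spec.label()}  [{self.method}]",
            f"  n_obs = {self.n_obs}, n_effective = {self.n_effective}",
            f"  loglik = {self.loglik:.3f}, AIC = {self.aic:.3f}, "
            f"sigma2 = {self.sigma2:.4f}, converged = {self.converged}",
        ]
        for name, value in self.param_dict.items():
            lines.append(f"  {name:>10s} = {value: .4f}")
        return "\n".join(lines)


SarimaFit = SarimaResults  # domain-type alias


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class SarimaModel:
    """SARIMA model for a single hourly activity series.

    Parameters
    ----------
    endog : array-like
        The hourly MET-minutes series (undifferenced).
    spec : SarimaSpec
        Model orders; the study grid uses d = D = 1, m = 24.
    """

    def __init__(self, endog, spec: SarimaSpec):
        values = getattr(endog, "values", endog)
        self.endog = np.asarray(values, dtype=float)
        if self.endog.ndim != 1:
            raise ValueError("endog must be one-dimensional")
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("endog contains non-finite values")
        self.spec = spec
        if len(self.endog) < spec.min_length:
            raise ValueError(
                f"series of length {len(self.endog)} too short for "
                f"{spec.label()}; minimum length is {spec.min_length}"
            )
        self.w = difference(self.endog, spec.d, spec.D, spec.m)

    def loglik(self, params, sigma2: float | None = None, method: str = "ml") -> float:
        """Log-likelihood at given weights (sigma2 profiled if omitted)."""
        params = np.asarray(params, dtype=float)
        if method == "css":
            if sigma2 is None:
                eps = css_innovations(self.w, self.spec, params)
                sigma2 = float(eps @ eps) / len(eps)
            return css_loglik(self.w, self.spec, params, sigma2)
        ll, _ = exact_loglik(self.w, self.spec, params)
        return ll

    def _optimize(self, objective, x0: np.ndarray):
        bounds = _coef_bounds(self.spec)
        x0 = np.clip(x0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        return optimize.minimize(
            objective,
            x0,
            args=(self.w, self.spec),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-9},
        )

    def _hr_start(self) -> np.ndarray | None:
        """Hannan-Rissanen-style starting values.

        A long autoregression supplies innovation proxies; the weights are
        then a single least-squares regression of w on its own lags and the
        proxy lags (multiplicative cross terms ignored).  Used as a second
        deterministic start because near-redundant specs (e.g. ARMA(2,2) on
        ARMA(1,1)-like data) have a multimodal likelihood.
        """
        spec, w = self.spec, self.w
        n = len(w)
        L = min(2 * spec.m, n // 3)
        if L < max(spec.q, 1):
            return None
        lagmat = np.column_stack([w[L - j : n - j] for j in range(1, L + 1)])
        target = w[L:]
        coef, *_ = np.linalg.lstsq(lagmat, target, rcond=None)
        eps = np.full(n, np.nan)
        eps[L:] = target - lagmat @ coef
        t0 = L + max(spec.p, spec.q, spec.m * spec.P, spec.m * spec.Q)
        if n - t0 < spec.n_params + 5:
            return None
        cols = []
        for j in range(1, spec.p + 1):
            cols.append(w[t0 - j : n - j])
        for j in range(1, spec.q + 1):
            cols.append(eps[t0 - j : n - j])
        for j in range(1, spec.P + 1):
            cols.append(w[t0 - j * spec.m : n - j * spec.m])
        for j in range(1, spec.Q + 1):
            cols.append(eps[t0 - j * spec.m : n - j * spec.m])
        X = np.column_stack(cols)
        if not np.all(np.isfinite(X)):
            return None
        beta, *_ = np.linalg.lstsq(X, w[t0:], rcond=None)
        x0 = beta.astype(float)
        for _ in range(20):
            if check_roots(spec, x0, margin=1e-4) is None:
                return x0
            x0 = x0 * 0.85
        return None

    def fit(self, method: str = "ml", start_params=None) -> SarimaResults:
        """Estimate the weights; sigma2 is profiled out in closed form.

        Deterministic: the optimizer starts from zero (CSS) and the exact-ML
        stage is warm-started from the CSS solution; no random restarts.
        """
        spec = self.spec
        n = len(self.w)
        k_free = spec.n_params
        if method not in ("ml", "css"):
            raise ValueError("method must be 'ml' or 'css'")

        if k_free == 0:
            # white noise after differencing: closed form
            sse = float(self.w @ self.w)
            sigma2 = sse / n
            params = np.zeros(0)
            if method == "css":
                ll = css_loglik(self.w, spec, params, sigma2)
            else:
                ll, sigma2 = exact_loglik(self.w, spec, params)
            aic = 2 * spec.k - 2 * ll
            return SarimaResults(spec, params, sigma2, ll, aic, True, n,
                                 method, len(self.endog))

        if start_params is not None:
            x0 = np.asarray(start_params, dtype=float)
        else:
            x0 = np.zeros(k_free)

        # stage 1: CSS from the zero vector (or the supplied start)
        res_css = self._optimize(_css_neg_concentrated, x0)
        x_css = res_css.x
        success = bool(res_css.success)

        if method == "css":
            x_hat, obj = x_css, _css_neg_concentrated(x_css, self.w, spec)
            obj0 = _css_neg_concentrated(np.zeros(k_free), self.w, spec)
            if obj > obj0 + 1e-8:  # never worse than the all-zero start
                res0 = self._optimize(_css_neg_concentrated, np.zeros(k_free))
                if res0.fun < obj:
                    x_hat, obj, success = res0.x, res0.fun, bool(res0.success)
            eps = css_innovations(self.w, spec, x_hat)
            sigma2 = float(eps @ eps) / n
            ll = css_loglik(self.w, spec, x_hat, sigma2)
        else:
            # stage 2: exact ML from deterministic multistart (CSS solution,
            # plus a Hannan-Rissanen start for redundancy-prone specs)
            x_start = x_css.copy()
            while check_roots(spec, x_start, margin=1e-4) is not None:
                x_start *= 0.9  # shrink toward the admissible interior
                if np.abs(x_start).max() < 1e-6:
                    x_start = np.zeros(k_free)
                    break
            starts = [x_start]
            redundancy_prone = (spec.p and spec.q) or (spec.P and spec.Q)
            if start_params is None and k_free >= 3 and redundancy_prone:
                hr = self._hr_start()
                if hr is not None and np.abs(hr - x_start).max() > 0.05:
                    starts.append(hr)
            best = None
            for s in starts:
                res_ml = self._optimize(_exact_neg_concentrated, s)
                if best is None or res_ml.fun < best.fun:
                    best = res_ml
            x_hat, obj = best.x, best.fun
            success = bool(best.success)
            obj0 = _exact_neg_concentrated(np.zeros(k_free), self.w, spec)
            if obj > obj0 + 1e-8:
                res0 = self._optimize(_exact_neg_concentrated, np.zeros(k_free))
                if res0.fun < obj:
                    x_hat, obj, success = res0.x, res0.fun, bool(res0.success)
            sigma2 = _profiled_sigma2(self.w, spec, x_hat)
            ll = -float(obj)

        offending = check_roots(spec, x_hat)
        if k_free:
            bnds = _coef_bounds(spec)
            at_bound = bool(
                np.any([abs(x) >= hi - 1e-6 for x, (_, hi) in zip(np.abs(x_hat), bnds)])
            )
        else:
            at_bound = False
        converged = success and offending is None and not at_bound and np.isfinite(ll)
        aic = 2 * spec.k - 2 * ll if np.isfinite(ll) else math.inf
        return SarimaResults(spec, x_hat, sigma2, ll, aic, converged, n,
                             method, len(self.endog))
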