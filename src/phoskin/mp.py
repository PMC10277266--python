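"""Multi-pass dialysis model: ODE definition, certified power-series
solution, Q = 0 closed form, and the reference numerical integrator used as
the internal oracle.

With recirculated dialysate the serum concentration x(t) and dialysate
concentration y(t) satisfy

    (Vb0 - Q t) dx/dt = Ks Cs - (Ks + Kb) x + Kb y
    (Vd0 + Q t) dy/dt = (Kb + Q) (x - y).

Both components admit power-series solutions x = sum a_k t^k,
y = sum b_k t^k whose coefficients obey a two-term matrix recursion; the
series provably converge for t < min(Vb0/Q, Vd0/Q), and truncating after N
terms incurs an error bounded by the magnitude of the first omitted term
(Lagrange remainder). When Q = 0 the system is linear time-invariant and
the solution is an explicit bi-exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import MPParameters, Q_ZERO_THRESHOLD, SPParameters

__all__ = [
    "SeriesSolution",
    "Trajectory",
    "EigenPair",
    "series_coefficients",
    "series_eval",
    "truncation_bound",
    "terms_for_tolerance",
    "eigenvalues_A",
    "closed_form_Q0",
    "closed_form_Q0_eigenbasis",
    "reference_integrate",
]

#: Slack added to the asymptotic coefficient-ratio eigenvalue bound when
#: reporting lambda_tilde (1/h).
LAMBDA_EPSILON = 1e-6

#: Maximum series order tried before terms_for_tolerance gives up.
DEFAULT_ORDER_CAP = 500


@dataclass(frozen=True)
class SeriesSolution:
    """Truncated power-series solution of the multi-pass model.

    Attributes
    ----------
    gamma : ndarray, shape (N+2, 2)
        Coefficient pairs (a_k, b_k) for orders k = 0..N+1; the extra
        order feeds the truncation bound. Units mmol/L/h^k.
    N : int
        Highest order retained when evaluating the partial sums.
    lambda_tilde : float
        Uniform bound on the coefficient-recursion eigenvalues,
        max(Q/Vb0, Q/Vd0) + epsilon (1/h).
    t_valid : float
        Proven convergence horizon min(Vb0/Q, Vd0/Q) in hours; ``inf``
        when Q = 0.
    """

    gamma: np.ndarray
    N: int
    lambda_tilde: float
    t_valid: float


@dataclass(frozen=True)
class Trajectory:
    """Concentrations (and derived compartment masses) on a time grid."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray | None
    mass_b: np.ndarray
    mass_d: np.ndarray | None
    provenance: str  # "series" | "closed_form" | "numeric"


@dataclass(frozen=True)
class EigenPair:
    """Eigenvalues of the Q = 0 system matrix, lambda1 >= lambda2 (1/h)."""

    lambda1: float
    lambda2: float


def _validity_horizon(params: MPParameters) -> float:
    if params.q_is_zero:
        return np.inf
    return min(params.Vb0, params.Vd0) / params.Q


def series_coefficients(params: MPParameters, N: int) -> SeriesSolution:
    """Power-series coefficients up to order ``N`` (plus one guard order).

    Recursion, with a_0 = x0 and b_0 = y0:

        a_1     = (Ks Cs - (Ks+Kb) a_0 + Kb b_0) / Vb0
        a_{k+1} = (Q k a_k - (Ks+Kb) a_k + Kb b_k) / (Vb0 (k+1)),  k >= 1
        b_{k+1} = (-Q k b_k + (Kb+Q)(a_k - b_k)) / (Vd0 (k+1)),    k >= 0
    """
    if N < 0:
        raise ValueError("N must be >= 0")
    Ks, Kb, Q = params.Ks, params.Kb, params.Q
    Vb0, Vd0 = params.Vb0, params.Vd0
    g = np.zeros((N + 2, 2))
    g[0] = (params.x0, params.y0)
    g[1, 0] = (Ks * params.Cs - (Ks + Kb) * g[0, 0] + Kb * g[0, 1]) / Vb0
    g[1, 1] = (Kb + Q) * (g[0, 0] - g[0, 1]) / Vd0
    for k in range(1, N + 1):
        a, b = g[k]
        g[k + 1, 0] = ((Q * k - (Ks + Kb)) * a + Kb * b) / (Vb0 * (k + 1))
        g[k + 1, 1] = (-Q * k * b + (Kb + Q) * (a - b)) / (Vd0 * (k + 1))
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("series coefficients overflowed double precision")
    lam = max(Q / Vb0, Q / Vd0) + LAMBDA_EPSILON
    return SeriesSolution(gamma=g, N=N, lambda_tilde=lam, t_valid=_validity_horizon(params))


def series_eval(series: SeriesSolution, params: MPParameters, t):
    """Evaluate the truncated series at time(s) ``t`` (Horner order).

    Raises if any ``t`` falls outside [0, t_valid), the proven region of
    convergence.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if np.any(t_arr >= series.t_valid):
        raise ValueError(
            f"t must be < t_valid = {series.t_valid:g} h (convergence proven "
            "only on that interval)"
        )
    x = np.full_like(t_arr, series.gamma[series.N, 0])
    y = np.full_like(t_arr, series.gamma[series.N, 1])
    for k in range(series.N - 1, -1, -1):
        x = x * t_arr + series.gamma[k, 0]
        y = y * t_arr + series.gamma[k, 1]
    if t_arr.ndim:
        return x, y
    return float(x), float(y)


def truncation_bound(series: SeriesSolution, t: float) -> tuple[float, float]:
    """Lagrange bound on the truncation error of both partial sums at ``t``:
    (|a_{N+1}| t^{N+1}, |b_{N+1}| t^{N+1})."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 0.0, 0.0
    a, b = np.abs(series.gamma[series.N + 1])
    # log-space product: t^(N+1) alone can overflow long before the bound does
    logt = (series.N + 1) * np.log(t)
    bx = 0.0 if a == 0 else float(np.exp(np.log(a) + logt))
    by = 0.0 if b == 0 else float(np.exp(np.log(b) + logt))
    return bx, by


def terms_for_tolerance(
    params: MPParameters,
    t_max: float,
    tol: float,
    cap: int = DEFAULT_ORDER_CAP,
) -> int:
    """Smallest order N whose Lagrange bound at ``t_max`` is <= ``tol`` for
    both the serum and dialysate series."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if t_max >= _validity_horizon(params):
        raise ValueError("t_max must be inside the convergence horizon")
    series = series_coefficients(params, cap)
    for N in range(cap + 1):
        trunc = SeriesSolution(
            gamma=series.gamma[: N + 2],
            N=N,
            lambda_tilde=series.lambda_tilde,
            t_valid=series.t_valid,
        )
        bx, by = truncation_bound(trunc, t_max)
        if bx <= tol and by <= tol:
            return N
    raise RuntimeError(
        f"no order <= {cap} meets tol={tol:g} at t={t_max:g} h"
    )


def eigenvalues_A(params: MPParameters) -> EigenPair:
    """Eigenvalues of the Q = 0 system matrix

        A = [[-(Ks+Kb)/Vb0, Kb/Vb0], [Kb/Vd0, -Kb/Vd0]].

    Both are real; both are negative whenever Ks > 0 (negative trace,
    positive determinant).
    """
    a = (params.Ks + params.Kb) / params.Vb0
    b = params.Kb / params.Vd0
    disc = np.sqrt((b - a) ** 2 + 4.0 * params.Kb**2 / (params.Vb0 * params.Vd0))
    lam1 = 0.5 * (-a - b + disc)
    lam2 = 0.5 * (-a - b - disc)
    return EigenPair(lambda1=float(lam1), lambda2=float(lam2))


def _biexp_coefficients(params: MPParameters) -> tuple[float, float, float, float, float, float]:
    """Amplitudes (cx1, cx2, cy1, cy2) and rates (lam1, lam2) of the Q = 0
    bi-exponential solution x = cx1 e^{l1 t} + cx2 e^{l2 t} + Cs (same for y)."""
    if params.Kb <= 0:
        raise ValueError("closed form requires Kb > 0")
    eig = eigenvalues_A(params)
    lam1, lam2 = eig.lambda1, eig.lambda2
    if abs(lam1 - lam2) < 1e-12:
        raise ArithmeticError("degenerate eigenvalues; bi-exponential form invalid")
    Kb, Vd0 = params.Kb, params.Vd0
    dx0 = params.x0 - params.Cs
    dy0 = params.y0 - params.Cs
    # eigenvector for lam_i is (Vd0 lam_i + Kb, Kb); projecting the initial
    # deviation onto the eigenbasis gives the amplitudes below
    w1 = (Kb * dx0 - (Vd0 * lam2 + Kb) * dy0) / (Vd0 * (lam1 - lam2))
    w2 = (-Kb * dx0 + (Vd0 * lam1 + Kb) * dy0) / (Vd0 * (lam1 - lam2))
    cx1 = (Vd0 * lam1 + Kb) / Kb * w1
    cx2 = (Vd0 * lam2 + Kb) / Kb * w2
    return cx1, cx2, w1, w2, lam1, lam2


def closed_form_Q0(params: MPParameters, t):
    """Explicit bi-exponential solution of the multi-pass model with Q = 0.

    Returns (x(t), y(t)); scalars for scalar ``t``, arrays otherwise.
    """
    if not params.q_is_zero:
        raise ValueError("closed form requires Q = 0")
    t_arr = np.asarray(t, dtype=float)
    cx1, cx2, cy1, cy2, lam1, lam2 = _biexp_coefficients(params)
    e1 = np.exp(lam1 * t_arr)
    e2 = np.exp(lam2 * t_arr)
    x = cx1 * e1 + cx2 * e2 + params.Cs
    y = cy1 * e1 + cy2 * e2 + params.Cs
    if t_arr.ndim:
        return x, y
    return float(x), float(y)


def closed_form_Q0_eigenbasis(params: MPParameters, t):
    """Matrix-exponential route P diag(e^{l1 t}, e^{l2 t}) P^{-1} with
    unit-norm eigenvector columns; agrees with :func:`closed_form_Q0` to
    floating-point accuracy (any consistent normalization of P does)."""
    if not params.q_is_zero:
        raise ValueError("closed form requires Q = 0")
    if params.Kb <= 0:
        raise ValueError("closed form requires Kb > 0")
    eig = eigenvalues_A(params)
    P = np.column_stack(
        [
            [params.Vd0 * eig.lambda1 + params.Kb, params.Kb],
            [params.Vd0 * eig.lambda2 + params.Kb, params.Kb],
        ]
    )
    P = P / np.linalg.norm(P, axis=0, keepdims=True)
    w0 = np.array([params.x0 - params.Cs, params.y0 - params.Cs])
    t_arr = np.asarray(t, dtype=float)
    expd = np.exp(np.outer([eig.lambda1, eig.lambda2], t_arr.ravel()))
    w = P @ (expd * np.linalg.solve(P, w0)[:, None])
    x = (w[0] + params.Cs).reshape(t_arr.shape)
    y = (w[1] + params.Cs).reshape(t_arr.shape)
    if t_arr.ndim:
        return x, y
    return float(x), float(y)


def reference_integrate(
    model: str,
    params: SPParameters | MPParameters,
    t_grid,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """Adaptive-step numerical integration of the governing ODEs.

    Serves as the internal oracle against which every analytic solver is
    validated; the local tolerance defaults to 1e-10.

    Parameters
    ----------
    model : {"sp", "mp"}
        Which system to integrate.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] < 0:
        raise ValueError("t_grid must start at t >= 0")
    Ks, Kb, Q = params.Ks, params.Kb, params.Q
    Vb0, Cs = params.Vb0, params.Cs
    if Q > 0 and t_grid[-1] >= Vb0 / Q:
        raise ValueError("t_grid exceeds the volume-depletion horizon Vb0/Q")

    if model == "sp":
        def rhs(t, state):
            return [
                (Ks * Cs - (Ks + Kb) * state[0] + Kb * params.Cd0) / (Vb0 - Q * t)
            ]

        y_init = [params.x0]
    elif model == "mp":
        if not isinstance(params, MPParameters):
            raise TypeError("mp integration requires MPParameters")
        Vd0 = params.Vd0

        def rhs(t, state):
            x, y = state
            return [
                (Ks * Cs - (Ks + Kb) * x + Kb * y) / (Vb0 - Q * t),
                (Kb + Q) * (x - y) / (Vd0 + Q * t),
            ]

        y_init = [params.x0, params.y0]
    else:
        raise ValueError(f"model must be 'sp' or 'mp', got {model!r}")

    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        rhs,
        (t0, t_grid[-1]),
        y_init,
        method="DOP853",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    vb = Vb0 - Q * t_grid
    if model == "sp":
        x = sol.y[0]
        return Trajectory(
            times=t_grid, x=x, y=None, mass_b=x * vb, mass_d=None,
            provenance="numeric",
        )
    x, y = sol.y
    vd = params.Vd0 + Q * t_grid
    return Trajectory(
        times=t_grid, x=x, y=y, mass_b=x * vb, mass_d=y * vd,
        provenance="numeric",
    )
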