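"""Exact solution of the single-pass dialysis model.

The serum concentration obeys

    (Vb0 - Q t) dx/dt = Ks Cs - (Ks + Kb) x + Kb Cd0,

whose solution with ultrafiltration is a power law in (1 - Q t / Vb0) and,
for Q = 0, a plain exponential relaxation to the steady state
(Ks Cs + Kb Cd0) / (Ks + Kb).
"""

from __future__ import annotations

import numpy as np

from .params import SPParameters

__all__ = ["sp_concentration", "sp_steady_state", "sp_reduction_ratio"]


def sp_steady_state(params: SPParameters) -> float:
    """Serum concentration plateau approached during a long session.

    Returns ``(Ks Cs + Kb Cd0) / (Ks + Kb)``.
    """
    denom = params.Ks + params.Kb
    if denom <= 0:
        raise ValueError("Ks + Kb must be positive for a steady state")
    return (params.Ks * params.Cs + params.Kb * params.Cd0) / denom


def sp_concentration(params: SPParameters, t):
    """Serum concentration x(t) during a single-pass session.

    Parameters
    ----------
    params : SPParameters
        Session parameters.
    t : float or array_like
        Time since session start (h). With ultrafiltration the model is
        only defined for ``t < Vb0 / Q`` (complete depletion of the
        plasma + extracellular volume at the endpoint).

    Returns
    -------
    float or ndarray
        x(t) in mmol/L, same shape as ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    xss = sp_steady_state(params)
    if params.q_is_zero:
        rate = (params.Ks + params.Kb) / params.Vb0
        out = xss + (params.x0 - xss) * np.exp(-rate * t_arr)
    else:
        t_max = params.Vb0 / params.Q
        if np.any(t_arr >= t_max):
            raise ValueError(
                f"t must be < Vb0/Q = {t_max:g} h (volume depleted)"
            )
        exponent = (params.Ks + params.Kb) / params.Q
        out = xss + (params.x0 - xss) * (1.0 - params.Q * t_arr / params.Vb0) ** exponent
    return out if out.ndim else float(out)


def sp_reduction_ratio(params: SPParameters, T: float) -> tuple[float, float]:
    """End-of-session serum reduction ratio x(T)/x(0) and its quadratic
    Taylor approximation.

    Uses the steady-start convention x(0) = Cs with Cd0 = 0 and Q = 0; the
    operation enforces that convention rather than generalizing it, so the
    ``Cs``, ``Cd0``, ``x0`` and ``Q`` fields of ``params`` are ignored.

    The exact ratio is

        Kb/(Ks+Kb) * exp(-(Ks+Kb) T / Vb0) + Ks/(Ks+Kb),

    and the approximation, linear in Ks, is

        1 - Kb T/Vb0 + (Kb T/Vb0)^2 / 2 + Kb (T/Vb0)^2 Ks / 2.

    Returns
    -------
    (exact, approx) : tuple of float
        Both lie in (0, 1] for T >= 0 and physiological rates.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    Ks, Kb, Vb0 = params.Ks, params.Kb, params.Vb0
    total = Ks + Kb
    exact = Kb / total * np.exp(-total * T / Vb0) + Ks / total
    u = Kb * T / Vb0
    approx = 1.0 - u + 0.5 * u**2 + 0.5 * Kb * (T / Vb0) ** 2 * Ks
    return float(exact), float(approx)
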