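"""Post-dialysis phosphate rebound.

After the session ends at time T the dialyzer is disconnected and the serum
concentration relaxes back toward the source level Cs by pure diffusion:

    Vb0 dx/dt = Ks (Cs - x),  x(T) = xT
    =>  x(t) = (xT - Cs) exp(-Ks (t - T) / Vb0) + Cs.

Two time conventions are exposed deliberately: :func:`rebound_concentration`
takes absolute time t >= T, while the percentage formulas take time *since
the end of treatment*, matching how rebound curves are reported clinically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReboundState",
    "rebound_concentration",
    "rebound_percent",
    "plateau_rebound_percent",
]

#: Session length (h) above which the end-of-session concentration is
#: usually close enough to the single-pass plateau for the plateau rebound
#: formula to apply.
PLATEAU_SESSION_HOURS = 2.0


@dataclass(frozen=True, kw_only=True)
class ReboundState:
    """End-of-session state from which the rebound evolves.

    ``Kb`` is only needed by the plateau formula and defaults to 0 (unused).
    """

    Cs: float
    xT: float
    Ks: float
    Vb0: float
    T: float
    Kb: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if self.Vb0 <= 0:
            raise ValueError(f"Vb0 must be > 0, got {self.Vb0}")
        if self.Ks < 0:
            raise ValueError(f"Ks must be >= 0, got {self.Ks}")
        if not 0 <= self.xT <= self.Cs:
            raise ValueError(
                "expected 0 <= xT <= Cs for a phosphate-lowering session, "
                f"got xT={self.xT}, Cs={self.Cs}"
            )


def rebound_concentration(state: ReboundState, t):
    """Serum concentration at absolute time ``t >= T`` (hours since session
    start); continuous with the end-of-session value xT and monotone toward
    Cs."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < state.T):
        raise ValueError(f"t must be >= T = {state.T:g} h")
    out = (state.xT - state.Cs) * np.exp(
        -state.Ks * (t_arr - state.T) / state.Vb0
    ) + state.Cs
    return out if out.ndim else float(out)


def rebound_percent(state: ReboundState, t):
    """Relative serum rebound, in percent, ``t`` hours after the end of
    treatment:

        (Cs - xT)/xT * (1 - exp(-Ks t / Vb0)) * 100.
    """
    if state.xT == 0:
        raise ValueError("rebound percent undefined for xT = 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t (time since end of treatment) must be >= 0")
    out = (
        (state.Cs - state.xT)
        / state.xT
        * (1.0 - np.exp(-state.Ks * t_arr / state.Vb0))
        * 100.0
    )
    return out if out.ndim else float(out)


def plateau_rebound_percent(Ks: float, Kb: float, Vb0: float, t, T: float | None = None):
    """Rebound percent when the session was long enough that the serum sat
    at the single-pass plateau Kb Cs/(Ks+Kb) (Cd0 ~ 0) at disconnection:

        Kb/Ks * (1 - exp(-Ks t / Vb0)) * 100,

    independent of session length T — short and long sessions then share
    one rebound curve. Passing ``T`` emits a warning when the session is
    shorter than the usual plateau-attainment time; attainment really
    depends on the rates, so this is advisory only.
    """
    if Ks <= 0:
        raise ValueError("plateau rebound requires Ks > 0")
    if Vb0 <= 0:
        raise ValueError("Vb0 must be > 0")
    if T is not None and T < PLATEAU_SESSION_HOURS:
        warnings.warn(
            f"session length T={T:g} h < {PLATEAU_SESSION_HOURS:g} h; the "
            "plateau formula may not apply",
            stacklevel=2,
        )
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t (time since end of treatment) must be >= 0")
    out = Kb / Ks * (1.0 - np.exp(-Ks * t_arr / Vb0)) * 100.0
    return out if out.ndim else float(out)
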