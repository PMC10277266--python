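import numpy as np
import pytest

from phoskin import CohortDesign, MPParameters, SPParameters

# Reference parameter set used for the worked figures: Ks=2.6 L/h,
# Kb=6.9 L/h, Q=0.23 L/h, Vb0=10 L, Cs=x0=2.9 mmol/L, y0=0. The dialysate
# volume for the multi-pass variant is taken as 25 L (mid-range of the
# reported per-patient values).
FIG_KW = dict(Ks=2.6, Kb=6.9, Cs=2.9, Vb0=10.0, x0=2.9)
FIG_VD0 = 25.0


@pytest.fixture
def fig_sp() -> SPParameters:
    return SPParameters(Q=0.23, Cd0=0.0, **FIG_KW)


@pytest.fixture
def fig_sp_q0() -> SPParameters:
    return SPParameters(Q=0.0, Cd0=0.0, **FIG_KW)


@pytest.fixture
def fig_mp() -> MPParameters:
    return MPParameters(Q=0.23, Vd0=FIG_VD0, y0=0.0, **FIG_KW)


@pytest.fixture
def fig_mp_q0() -> MPParameters:
    return MPParameters(Q=0.0, Vd0=FIG_VD0, y0=0.0, **FIG_KW)


def draw_mp_params(rng: np.random.Generator, q_zero: bool = True) -> MPParameters:
    """Random parameter set inside the estimation window, away from the
    degenerate edges."""
    return MPParameters(
        Ks=float(rng.uniform(0.5, 25.0)),
        Kb=float(rng.uniform(0.5, 25.0)),
        Vb0=float(rng.uniform(5.0, 55.0)),
        Cs=float(rng.uniform(0.5, 4.5)),
        x0=float(rng.uniform(0.5, 4.5)),
        y0=float(rng.uniform(0.0, 1.0)),
        Vd0=float(rng.uniform(10.0, 40.0)),
        Q=0.0 if q_zero else float(rng.uniform(0.05, 0.3)),
        Cd0=float(rng.uniform(0.0, 0.2)),
    )


def draw_mp_params_series_friendly(rng: np.random.Generator) -> MPParameters:
    """Random Q = 0 parameter set with (Ks+Kb)/Vb0 * 8h modest, so a
    moderate-order power series is certified accurate at t = 8 h and its
    floating-point cancellation stays far below the comparison tolerances."""
    return MPParameters(
        Ks=float(rng.uniform(0.5, 6.0)),
        Kb=float(rng.uniform(0.5, 6.0)),
        Vb0=float(rng.uniform(8.0, 23.0)),
        Cs=float(rng.uniform(0.5, 4.5)),
        x0=float(rng.uniform(0.5, 4.5)),
        y0=float(rng.uniform(0.0, 1.0)),
        Vd0=float(rng.uniform(14.0, 32.0)),
        Q=0.0,
        Cd0=0.0,
    )


@pytest.fixture
def quiet_design() -> CohortDesign:
    return CohortDesign(noise_sd=0.0, seed=0)
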