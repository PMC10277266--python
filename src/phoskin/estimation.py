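"""Two-stage parameter estimation for dialysis phosphate kinetics.

Stage 1 discretizes the governing ODEs with the trapezoidal rule, which is
linear in the rates (Ks, Kb) once volumes, Cs and initial conditions are
held fixed; a global linear least-squares solve gives the pre-estimate.
Stage 2 runs bounded nonlinear least squares on the RMSE objective

    RMSE(eta) = sqrt( sum_series sum_i (Y_ij - Xhat_j(t_i, eta))^2 / n_total )

over the free parameters of the chosen mode, started from the pre-estimate.
All fitting uses the Q = 0 model solutions (ultrafiltration is negligible
for these kinetics).

Modes and free parameters
-------------------------
SP : {Ks, Kb, z0}; Vb0 fixed at the clinical measurement, Cs = z0.
MP : {Ks, Kb, Vb0, x0}; Cs = x0, y0 = 0.
CP : {Ks, Kb, Vb0, z0, x0} shared across both sessions; Cs = max(z0, x0),
     y0 = 0.

95% confidence half-widths come from a finite-difference Hessian H of the
residual sum of squares at the optimum: cov = 2 s^2 H^-1 with
s^2 = RSS / (n_total - p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .mp import closed_form_Q0
from .params import MPParameters, SPParameters
from .sp import sp_concentration

__all__ = [
    "MeasurementSet",
    "FitSpec",
    "FitResult",
    "MultistartReport",
    "DEFAULT_BOUNDS",
    "rmse_objective",
    "linear_preestimate",
    "fit",
    "confidence_intervals",
    "multistart_robustness",
    "fd_hessian",
    "hessian_halfwidths",
]

#: Physiologically meaningful estimation window per parameter
#: (rates in L/h, volume in L, concentrations in mmol/L).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "Ks": (0.0, 30.0),
    "Kb": (0.0, 30.0),
    "Vb0": (0.0, 60.0),
    "z0": (0.0, 5.0),
    "x0": (0.0, 5.0),
}

_FREE_PARAMS = {
    "SP": ("Ks", "Kb", "z0"),
    "MP": ("Ks", "Kb", "Vb0", "x0"),
    "CP": ("Ks", "Kb", "Vb0", "z0", "x0"),
}

# evaluation-side floors: the optimizer may probe the lower bound 0 where
# the closed forms divide by Kb or Vb0
_EVAL_FLOOR = 1e-9


@dataclass(frozen=True)
class MeasurementSet:
    """One patient's sampled concentrations plus fixed clinical quantities.

    SP series: blood concentrations ``z`` at ``t_sp``. MP series: blood
    ``x`` and dialysate ``y`` on the shared grid ``t_mp``. Any modality not
    recorded is left as None.
    """

    patient_id: str
    t_sp: np.ndarray | None = None
    z: np.ndarray | None = None
    t_mp: np.ndarray | None = None
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    Cd0: float | None = None
    Vd0: float | None = None
    Vb0_clinical: float | None = None

    @property
    def modality(self) -> str:
        if self.t_sp is not None and self.t_mp is not None:
            return "both"
        if self.t_sp is not None:
            return "SP"
        if self.t_mp is not None:
            return "MP"
        raise ValueError("measurement set holds no series")

    def __post_init__(self) -> None:
        for t_name, series_names in (("t_sp", ("z",)), ("t_mp", ("x", "y"))):
            t = getattr(self, t_name)
            if t is None:
                continue
            t = np.asarray(t, dtype=float)
            object.__setattr__(self, t_name, t)
            if t[0] != 0:
                raise ValueError(f"{t_name} must include a baseline at t = 0")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{t_name} must be strictly increasing")
            for name in series_names:
                c = getattr(self, name)
                if c is None:
                    raise ValueError(f"{name} required when {t_name} is given")
                c = np.asarray(c, dtype=float)
                object.__setattr__(self, name, c)
                if c.shape != t.shape:
                    raise ValueError(f"{name} and {t_name} length mismatch")
                if np.any(c < 0):
                    raise ValueError(f"{name} holds negative concentrations")


@dataclass(frozen=True)
class FitSpec:
    """Configuration of one estimation run.

    ``sp_free_vb0`` lifts the usual SP convention of pinning Vb0 at the
    clinical measurement; SP data alone cannot identify the volume, so
    freeing it mainly serves identifiability studies.
    """

    mode: str  # "SP" | "MP" | "CP"
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    ftol: float = 1e-10
    xtol: float = 1e-8
    multistart: int = 1
    seed: int | None = None
    sp_free_vb0: bool = False

    def __post_init__(self) -> None:
        if self.mode not in _FREE_PARAMS:
            raise ValueError(f"mode must be one of {set(_FREE_PARAMS)}, got {self.mode!r}")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"infeasible bounds for {name}: ({lo}, {hi})")

    @property
    def free_params(self) -> tuple[str, ...]:
        if self.mode == "SP" and self.sp_free_vb0:
            return ("Ks", "Kb", "Vb0", "z0")
        return _FREE_PARAMS[self.mode]


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one fit."""

    mode: str
    estimates: dict[str, float]  # free parameters plus the implied Cs
    ci_halfwidth: dict[str, float]
    rmse: float
    d: int  # number of series used (1 SP, 2 MP, 3 CP)
    n_total: int
    converged: bool
    preestimate: tuple[float, float] | None  # linear-stage (Ks, Kb)
    nfev: int = 0


@dataclass
class MultistartReport:
    """Outcome of repeated fits from random starting points."""

    best: FitResult
    optima: list[dict[str, float]]  # one representative per cluster
    cluster_sizes: list[int]
    spread: float  # max relative deviation of converged optima from best
    n_failed: int
    results: list[FitResult]


def _require(data: MeasurementSet, mode: str) -> None:
    if mode in ("SP", "CP") and data.t_sp is None:
        raise ValueError(f"mode {mode} needs SP series")
    if mode in ("MP", "CP") and data.t_mp is None:
        raise ValueError(f"mode {mode} needs MP series")
    if mode in ("SP", "CP") and data.Cd0 is None:
        raise ValueError(f"mode {mode} needs the fixed dialysate concentration Cd0")
    if mode in ("MP", "CP") and data.Vd0 is None:
        raise ValueError(f"mode {mode} needs the fixed dialysate volume Vd0")


def _residuals(theta: dict[str, float], data: MeasurementSet, mode: str) -> np.ndarray:
    """Stacked residuals of all series used by ``mode`` at parameters
    ``theta`` (Q = 0 forward models throughout)."""
    Ks = max(theta["Ks"], 0.0)
    Kb = max(theta["Kb"], _EVAL_FLOOR)
    res = []
    if mode in ("SP", "CP"):
        z0 = max(theta["z0"], 0.0)
        if mode == "SP" and "Vb0" not in theta:
            Vb0 = data.Vb0_clinical  # fixed at the clinical measurement
        else:
            Vb0 = max(theta["Vb0"], _EVAL_FLOOR)
        if Vb0 is None:
            raise ValueError("SP fit needs Vb0_clinical")
        if mode == "SP":
            Cs = z0
        else:
            Cs = max(z0, max(theta["x0"], 0.0))
        sp = SPParameters(Ks=Ks, Kb=Kb, Cs=Cs, Vb0=Vb0, x0=z0, Cd0=data.Cd0)
        res.append(sp_concentration(sp, data.t_sp) - data.z)
    if mode in ("MP", "CP"):
        x0 = max(theta["x0"], 0.0)
        Vb0 = max(theta["Vb0"], _EVAL_FLOOR)
        Cs = x0 if mode == "MP" else max(max(theta["z0"], 0.0), x0)
        mp = MPParameters(
            Ks=Ks, Kb=Kb, Cs=Cs, Vb0=Vb0, x0=x0, Vd0=data.Vd0, y0=0.0
        )
        xm, ym = closed_form_Q0(mp, data.t_mp)
        res.append(xm - data.x)
        res.append(ym - data.y)
    return np.concatenate(res)


def rmse_objective(theta: dict[str, float], data: MeasurementSet, mode: str) -> float:
    """Root-mean-square residual over every series used by ``mode``,
    normalized by the total residual count (reduces to the equal-length
    form when all series share one grid)."""
    _require(data, mode)
    r = _residuals(theta, data, mode)
    return float(np.sqrt(np.mean(r**2)))


def linear_preestimate(
    data: MeasurementSet,
    fixed: dict[str, float] | None = None,
    mode: str = "CP",
) -> tuple[float, float]:
    """Trapezoidal-rule linearization: solve the stacked per-interval
    system for (Ks, Kb) by global linear least squares.

    ``fixed`` may override the quantities held fixed during this stage
    (``Vb0``, ``Vd0``, ``Cs``, ``Cd0``); by default they come from the
    measurement set, with Cs taken as the largest baseline measurement.
    """
    _require(data, mode)
    fixed = dict(fixed or {})
    Vb0 = fixed.get("Vb0", data.Vb0_clinical)
    if Vb0 is None:
        raise ValueError("Vb0 must be fixed for the linear pre-estimate")
    baselines = []
    if mode in ("SP", "CP"):
        baselines.append(data.z[0])
    if mode in ("MP", "CP"):
        baselines.append(data.x[0])
    Cs = fixed.get("Cs", max(baselines))

    rows, rhs = [], []
    if mode in ("SP", "CP"):
        zd = fixed.get("Cd0", data.Cd0)
        z, t = data.z, data.t_sp
        zbar = 0.5 * (z[1:] + z[:-1])
        dt = np.diff(t)
        rows.append(np.column_stack([Cs - zbar, zd - zbar]))
        rhs.append(Vb0 * np.diff(z) / dt)
    if mode in ("MP", "CP"):
        Vd0 = fixed.get("Vd0", data.Vd0)
        x, y, t = data.x, data.y, data.t_mp
        xbar = 0.5 * (x[1:] + x[:-1])
        ybar = 0.5 * (y[1:] + y[:-1])
        dt = np.diff(t)
        rows.append(np.column_stack([Cs - xbar, ybar - xbar]))
        rhs.append(Vb0 * np.diff(x) / dt)
        rows.append(np.column_stack([np.zeros_like(xbar), xbar - ybar]))
        rhs.append(Vd0 * np.diff(y) / dt)

    A = np.vstack(rows)
    b = np.concatenate(rhs)
    if A.shape[0] < 2:
        raise ValueError("need at least two intervals for the pre-estimate")
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 2:
        raise np.linalg.LinAlgError(
            "trapezoidal design matrix is rank deficient (measurements carry "
            "no information about one or both rates)"
        )
    return float(sol[0]), float(sol[1])


def _default_start(
    data: MeasurementSet, spec: FitSpec, pre: tuple[float, float] | None
) -> dict[str, float]:
    lo = {k: spec.bounds[k][0] for k in spec.free_params}
    hi = {k: spec.bounds[k][1] for k in spec.free_params}
    mid = {k: 0.5 * (lo[k] + hi[k]) for k in spec.free_params}
    start = dict(mid)
    if pre is not None:
        start["Ks"], start["Kb"] = pre
    if "z0" in start and data.z is not None:
        start["z0"] = float(data.z[0])
    if "x0" in start and data.x is not None:
        start["x0"] = float(data.x[0])
    if "Vb0" in start and data.Vb0_clinical is not None:
        start["Vb0"] = float(data.Vb0_clinical)
    # keep the start strictly inside the box
    for k in start:
        span = hi[k] - lo[k]
        start[k] = float(np.clip(start[k], lo[k] + 1e-6 * span, hi[k] - 1e-6 * span))
    return start


def _implied_cs(estimates: dict[str, float], mode: str) -> float:
    if mode == "SP":
        return estimates["z0"]
    if mode == "MP":
        return estimates["x0"]
    return max(estimates["z0"], estimates["x0"])


def fit(
    data: MeasurementSet,
    spec: FitSpec,
    start: dict[str, float] | None = None,
) -> FitResult:
    """Bounded nonlinear least-squares fit of the Q = 0 models.

    Starts from the trapezoidal pre-estimate for the rates, the first
    measurement for each initial condition, and the clinical volume for
    Vb0, unless an explicit ``start`` overrides it. Non-convergence is
    reported on the result, not raised.
    """
    _require(data, spec.mode)
    names = spec.free_params
    pre: tuple[float, float] | None
    try:
        pre = linear_preestimate(data, mode=spec.mode)
    except (np.linalg.LinAlgError, ValueError):
        pre = None
    theta0 = _default_start(data, spec, pre) if start is None else dict(start)

    lo = np.array([spec.bounds[k][0] for k in names])
    hi = np.array([spec.bounds[k][1] for k in names])
    x_init = np.clip([theta0[k] for k in names], lo, hi)

    nfev = 0

    def resid_vec(vec: np.ndarray) -> np.ndarray:
        nonlocal nfev
        nfev += 1
        return _residuals(dict(zip(names, vec)), data, spec.mode)

    sol = least_squares(
        resid_vec,
        x_init,
        bounds=(lo, hi),
        method="trf",
        ftol=spec.ftol,
        xtol=spec.xtol,
        gtol=1e-12,
        x_scale="jac",
        max_nfev=5000,
    )
    estimates = {k: float(v) for k, v in zip(names, sol.x)}
    estimates["Cs"] = _implied_cs(estimates, spec.mode)
    n_total = sol.fun.size
    d = {"SP": 1, "MP": 2, "CP": 3}[spec.mode]
    result = FitResult(
        mode=spec.mode,
        estimates=estimates,
        ci_halfwidth={},
        rmse=float(np.sqrt(np.mean(sol.fun**2))),
        d=d,
        n_total=n_total,
        converged=bool(sol.status > 0),
        preestimate=pre,
        nfev=nfev,
    )
    result.ci_halfwidth = confidence_intervals(result, data, spec)
    return result


def _rss(vec: np.ndarray, names: tuple[str, ...], data: MeasurementSet, mode: str) -> float:
    r = _residuals(dict(zip(names, vec)), data, mode)
    return float(r @ r)


def fd_hessian(fun, theta: np.ndarray, rel_step: float | None = None) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function.

    Step per coordinate: rel_step * max(|theta_i|, 1), with rel_step
    defaulting to eps**(1/4), the usual second-derivative compromise
    between truncation and roundoff.
    """
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    if rel_step is None:
        rel_step = np.finfo(float).eps ** 0.25
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    f0 = fun(theta)
    H = np.empty((p, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (fun(theta + ei) - 2.0 * f0 + fun(theta - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej)
                - fun(theta + ei - ej)
                - fun(theta - ei + ej)
                + fun(theta - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def hessian_halfwidths(H: np.ndarray, rss: float, n: int, p: int) -> np.ndarray:
    """95% half-widths from the RSS Hessian: cov = 2 s^2 H^-1 with
    s^2 = RSS/(n - p); non-identifiable directions come out as +inf."""
    dof = n - p
    s2 = rss / dof if dof > 0 else np.inf
    try:
        diag = np.diag(2.0 * s2 * np.linalg.inv(H))
    except np.linalg.LinAlgError:
        diag = np.full(p, -1.0)
    if np.any(diag < 0) or not np.all(np.isfinite(diag)):
        warnings.warn(
            "singular or indefinite Hessian: some parameters are not "
            "practically identifiable; reporting infinite half-widths",
            stacklevel=2,
        )
    out = np.full(p, np.inf)
    ok = (diag >= 0) & np.isfinite(diag)
    out[ok] = 1.96 * np.sqrt(diag[ok])
    return out


def confidence_intervals(
    result: FitResult, data: MeasurementSet, spec: FitSpec
) -> dict[str, float]:
    """95% half-widths from the finite-difference Hessian of the residual
    sum of squares at the optimum.

    cov = 2 s^2 H^-1 with s^2 = RSS/(n - p); half-width = 1.96 sqrt(diag).
    A singular (or indefinite) Hessian yields +inf half-widths for the
    affected parameters with a warning — the practical-identifiability
    failure mode.
    """
    names = spec.free_params
    theta = np.array([result.estimates[k] for k in names])
    f0 = _rss(theta, names, data, spec.mode)
    H = fd_hessian(lambda v: _rss(v, names, data, spec.mode), theta)
    half = hessian_halfwidths(H, f0, result.n_total, len(names))
    return {k: float(h) for k, h in zip(names, half)}


def multistart_robustness(
    data: MeasurementSet,
    spec: FitSpec,
    n_starts: int,
    seed: int | None = None,
) -> MultistartReport:
    """Re-fit from ``n_starts`` starting points drawn uniformly inside the
    bounds; cluster the optima at relative tolerance 1e-4."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = spec.free_params
    results: list[FitResult] = []
    n_failed = 0
    for i in range(n_starts):
        if i == 0:
            start = None  # informed start: pre-estimate + clinical values
        else:
            start = {
                k: float(rng.uniform(*spec.bounds[k])) for k in names
            }
        try:
            res = fit(data, spec, start=start)
        except Exception:
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        results.append(res)
    if not results:
        raise RuntimeError("all starts failed")

    best = min(results, key=lambda r: r.rmse)
    best_vec = np.array([best.estimates[k] for k in names])

    def rel_dist(a: np.ndarray, b: np.ndarray) -> float:
        scale = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-8)
        return float(np.max(np.abs(a - b) / scale))

    reps: list[np.ndarray] = []
    sizes: list[int] = []
    for res in results:
        v = np.array([res.estimates[k] for k in names])
        for idx, rep in enumerate(reps):
            if rel_dist(v, rep) < 1e-4:
                sizes[idx] += 1
                break
        else:
            reps.append(v)
            sizes.append(1)
    spread = max(
        rel_dist(np.array([r.estimates[k] for k in names]), best_vec)
        for r in results
    )
    return MultistartReport(
        best=best,
        optima=[dict(zip(names, rep)) for rep in reps],
        cluster_sizes=sizes,
        spread=spread,
        n_failed=n_failed,
        results=results,
    )
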