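import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from phoskin import (
    CohortDesign,
    FitSpec,
    MeasurementSet,
    MPParameters,
    closed_form_Q0,
    fit,
    linear_preestimate,
    multistart_robustness,
    rmse_objective,
    simulate_patient,
    sp_concentration,
)
from phoskin.estimation import DEFAULT_BOUNDS, fd_hessian, hessian_halfwidths
from phoskin.params import SPParameters

TRUTH = MPParameters(
    Ks=6.0, Kb=9.0, Cs=2.0, Vb0=15.0, x0=2.0, Cd0=0.15, Vd0=25.0
)


def patient(noise_sd: float, seed: int = 0) -> MeasurementSet:
    design = CohortDesign(noise_sd=noise_sd)
    return simulate_patient(TRUTH, design, rng=np.random.default_rng(seed))


@pytest.fixture(scope="module")
def clean():
    return patient(0.0)


@pytest.fixture(scope="module")
def noisy():
    return patient(0.05, seed=1)


class TestMeasurementSet:
    def test_baseline_required(self):
        with pytest.raises(ValueError, match="baseline"):
            MeasurementSet(patient_id="p", t_sp=[1.0, 2.0], z=[1.0, 0.9])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            MeasurementSet(patient_id="p", t_sp=[0.0, 1.0], z=[1.0])

    def test_negative_concentration(self):
        with pytest.raises(ValueError):
            MeasurementSet(patient_id="p", t_sp=[0.0, 1.0], z=[1.0, -0.1])

    def test_modality(self, clean):
        assert clean.modality == "both"


class TestRmseObjective:
    def test_exact_data_gives_zero(self, clean):
        theta = dict(Ks=TRUTH.Ks, Kb=TRUTH.Kb, Vb0=TRUTH.Vb0,
                     z0=TRUTH.Cs, x0=TRUTH.Cs)
        assert rmse_objective(theta, clean, "CP") < 1e-12

    def test_hand_residuals(self):
        # two SP points with residuals (0.1, -0.1) -> RMSE exactly 0.1
        theta = dict(Ks=6.0, Kb=9.0, z0=2.0)
        p = SPParameters(Ks=6.0, Kb=9.0, Cs=2.0, Vb0=15.0, x0=2.0, Cd0=0.15)
        model = sp_concentration(p, np.array([0.0, 1.0]))
        data = MeasurementSet(
            patient_id="toy", t_sp=[0.0, 1.0], z=model + [0.1, -0.1],
            Cd0=0.15, Vb0_clinical=15.0,
        )
        assert rmse_objective(theta, data, "SP") == pytest.approx(0.1, rel=1e-12)

    def test_residual_homogeneity(self):
        theta = dict(Ks=6.0, Kb=9.0, z0=2.0)
        p = SPParameters(Ks=6.0, Kb=9.0, Cs=2.0, Vb0=15.0, x0=2.0, Cd0=0.15)
        t = np.arange(0.0, 5.0)
        model = sp_concentration(p, t)
        e = np.array([0.02, -0.01, 0.03, 0.0, -0.02])
        c = 2.5
        d1 = MeasurementSet(patient_id="a", t_sp=t, z=model + e,
                            Cd0=0.15, Vb0_clinical=15.0)
        d2 = MeasurementSet(patient_id="b", t_sp=t, z=model + c * e,
                            Cd0=0.15, Vb0_clinical=15.0)
        assert rmse_objective(theta, d2, "SP") == pytest.approx(
            c * rmse_objective(theta, d1, "SP"), rel=1e-12
        )

    def test_missing_series_rejected(self, clean):
        sp_only = MeasurementSet(patient_id="p", t_sp=clean.t_sp, z=clean.z,
                                 Cd0=0.15, Vb0_clinical=15.0)
        with pytest.raises(ValueError):
            rmse_objective(dict(Ks=1, Kb=1, Vb0=10, x0=2), sp_only, "MP")


class TestLinearPreestimate:
    def test_noiseless_recovery_within_5pct(self):
        # trapezoid error grows like ((Ks+Kb) dt / Vb0)^2, so the 5% claim
        # holds for hourly sampling at moderate relaxation rates
        gentle = MPParameters(Ks=3.0, Kb=5.0, Cs=2.0, Vb0=16.0, x0=2.0,
                              Cd0=0.15, Vd0=25.0)
        data = simulate_patient(gentle, CohortDesign(noise_sd=0.0), rng=0)
        for mode in ("SP", "MP", "CP"):
            ks, kb = linear_preestimate(data, mode=mode)
            assert ks == pytest.approx(gentle.Ks, rel=0.05)
            assert kb == pytest.approx(gentle.Kb, rel=0.05)

    def test_steady_state_data_rank_deficient(self):
        z = np.full(5, 1.5)
        data = MeasurementSet(patient_id="flat", t_sp=np.arange(0.0, 5.0),
                              z=z, Cd0=0.15, Vb0_clinical=15.0)
        with pytest.raises(np.linalg.LinAlgError):
            linear_preestimate(data, fixed={"Cs": 1.5}, mode="SP")

    def test_two_interval_toy_matches_hand_solution(self):
        # hand-built 2x2 normal equations for t = 0, 1, 2
        z = np.array([2.0, 1.5, 1.2])
        Vb0, Cs, zd = 15.0, 2.0, 0.15
        data = MeasurementSet(patient_id="toy", t_sp=[0.0, 1.0, 2.0], z=z,
                              Cd0=zd, Vb0_clinical=Vb0)
        A = np.array(
            [
                [Cs - 0.5 * (z[1] + z[0]), zd - 0.5 * (z[1] + z[0])],
                [Cs - 0.5 * (z[2] + z[1]), zd - 0.5 * (z[2] + z[1])],
            ]
        )
        b = Vb0 * np.diff(z)
        # explicit 2x2 inverse of A^T A
        AtA, Atb = A.T @ A, A.T @ b
        det = AtA[0, 0] * AtA[1, 1] - AtA[0, 1] * AtA[1, 0]
        hand = (
            (AtA[1, 1] * Atb[0] - AtA[0, 1] * Atb[1]) / det,
            (AtA[0, 0] * Atb[1] - AtA[1, 0] * Atb[0]) / det,
        )
        got = linear_preestimate(data, mode="SP")
        assert got[0] == pytest.approx(hand[0], abs=1e-12)
        assert got[1] == pytest.approx(hand[1], abs=1e-12)


class TestFit:
    def test_mp_noiseless_recovery_within_1pct(self, clean):
        r = fit(clean, FitSpec(mode="MP"))
        assert r.converged
        for name, true in (("Ks", TRUTH.Ks), ("Kb", TRUTH.Kb), ("Vb0", TRUTH.Vb0)):
            assert r.estimates[name] == pytest.approx(true, rel=0.01)

    def test_cp_noiseless_recovery_and_rmse(self, clean):
        r_cp = fit(clean, FitSpec(mode="CP"))
        r_sp = fit(clean, FitSpec(mode="SP"))
        r_mp = fit(clean, FitSpec(mode="MP"))
        for name, true in (("Ks", TRUTH.Ks), ("Kb", TRUTH.Kb), ("Vb0", TRUTH.Vb0)):
            assert r_cp.estimates[name] == pytest.approx(true, rel=0.01)
        assert r_cp.rmse <= max(r_sp.rmse, r_mp.rmse) + 1e-9

    def test_estimates_respect_bounds(self, noisy):
        for mode in ("SP", "MP", "CP"):
            r = fit(noisy, FitSpec(mode=mode))
            for name, value in r.estimates.items():
                if name == "Cs":
                    continue
                lo, hi = DEFAULT_BOUNDS[name]
                assert lo <= value <= hi

    def test_objective_identity_at_optimum(self, noisy):
        r = fit(noisy, FitSpec(mode="CP"))
        theta = {k: v for k, v in r.estimates.items() if k != "Cs"}
        assert rmse_objective(theta, noisy, "CP") == pytest.approx(r.rmse, abs=1e-15)

    def test_fit_metadata(self, clean):
        r = fit(clean, FitSpec(mode="CP"))
        assert (r.d, r.n_total) == (3, 5 + 9 + 9)
        assert r.preestimate is not None
        r_mp = fit(clean, FitSpec(mode="MP"))
        assert (r_mp.d, r_mp.n_total) == (2, 18)

    def test_implied_cs_is_largest_baseline(self, noisy):
        r = fit(noisy, FitSpec(mode="CP"))
        assert r.estimates["Cs"] == max(r.estimates["z0"], r.estimates["x0"])

    def test_infeasible_bounds_raise(self):
        bad = dict(DEFAULT_BOUNDS)
        bad["Ks"] = (5.0, 1.0)
        with pytest.raises(ValueError):
            FitSpec(mode="MP", bounds=bad)

    def test_preestimate_start_is_cheaper(self, clean):
        # smoke property: the informed start should not cost more
        # objective evaluations than starting from bound midpoints
        spec = FitSpec(mode="MP")
        r_pre = fit(clean, spec)
        mid = {k: 0.5 * sum(spec.bounds[k]) for k in spec.free_params}
        r_mid = fit(clean, spec, start=mid)
        assert r_pre.nfev <= r_mid.nfev * 1.5


class TestConfidenceIntervals:
    def test_noiseless_halfwidths_vanish(self, clean):
        r = fit(clean, FitSpec(mode="MP"))
        assert all(h < 1e-5 for h in r.ci_halfwidth.values())

    def test_noisy_halfwidths_positive_finite(self, noisy):
        r = fit(noisy, FitSpec(mode="CP"))
        for h in r.ci_halfwidth.values():
            assert 0 < h < 1e3

    def test_one_parameter_exponential_toy_matches_fisher(self):
        # y_i = exp(-k t_i) + eps, known sigma; linearized half-width is
        # 1.96 * sigma / sqrt(sum_i g_i^2), g_i = -t_i exp(-k t_i)
        rng = np.random.default_rng(12)
        k_true, sigma = 0.7, 0.05
        t = np.linspace(0.0, 4.0, 200)
        y = np.exp(-k_true * t) + rng.normal(0, sigma, t.size)

        def rss(vec):
            return float(np.sum((np.exp(-vec[0] * t) - y) ** 2))

        k_hat = minimize_scalar(
            lambda k: rss([k]), bounds=(0.1, 2.0), method="bounded",
            options={"xatol": 1e-12},
        ).x
        H = fd_hessian(rss, np.array([k_hat]))
        half = hessian_halfwidths(H, rss([k_hat]), t.size, 1)[0]
        g = -t * np.exp(-k_hat * t)
        analytic = 1.96 * sigma / np.sqrt(np.sum(g**2))
        assert half == pytest.approx(analytic, rel=0.10)

    def test_vb0_free_sp_inflates_uncertainty(self, noisy):
        fixed = fit(noisy, FitSpec(mode="SP"))
        free = fit(noisy, FitSpec(mode="SP", sp_free_vb0=True))
        assert free.ci_halfwidth["Ks"] > 2.0 * fixed.ci_halfwidth["Ks"]
        assert "Vb0" in free.ci_halfwidth

    def test_singular_hessian_warns_and_reports_inf(self):
        # two identical measurements only at t=0: rates are unidentifiable
        data = MeasurementSet(
            patient_id="flat", t_sp=np.arange(0.0, 5.0), z=np.full(5, 2.0),
            Cd0=0.0, Vb0_clinical=15.0,
        )
        spec = FitSpec(mode="SP")
        with pytest.warns(UserWarning, match="identifiable"):
            r = fit(data, spec, start=dict(Ks=1.0, Kb=0.5, z0=2.0))
        assert np.isinf(r.ci_halfwidth["Ks"]) or np.isinf(r.ci_halfwidth["Kb"])


class TestMultistart:
    def test_deterministic_given_seed(self, noisy):
        spec = FitSpec(mode="MP")
        r1 = multistart_robustness(noisy, spec, 5, seed=9)
        r2 = multistart_robustness(noisy, spec, 5, seed=9)
        assert r1.best.estimates == r2.best.estimates
        assert r1.spread == r2.spread

    def test_single_cluster_on_well_conditioned_patient(self, noisy):
        rep = multistart_robustness(noisy, FitSpec(mode="MP"), 20, seed=3)
        assert len(rep.optima) == 1
        assert rep.spread < 1e-4
        assert rep.n_failed == 0

    def test_one_start_equals_plain_fit(self, noisy):
        spec = FitSpec(mode="MP")
        rep = multistart_robustness(noisy, spec, 1, seed=0)
        plain = fit(noisy, spec)
        assert rep.best.estimates == plain.estimates

    def test_invalid_count(self, noisy):
        with pytest.raises(ValueError):
            multistart_robustness(noisy, FitSpec(mode="MP"), 0, seed=0)


def test_coverage_sanity_small():
    # light version of the coverage study: 60 replicates, wide gate
    hits = 0
    design = CohortDesign(noise_sd=0.05)
    for i in range(60):
        ms = simulate_patient(TRUTH, design, rng=np.random.default_rng(500 + i))
        r = fit(ms, FitSpec(mode="MP"))
        if abs(r.estimates["Ks"] - TRUTH.Ks) <= r.ci_halfwidth["Ks"]:
            hits += 1
    assert 0.75 <= hits / 60 <= 1.0
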