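"""Two-compartment kinetics, Hill pharmacodynamics and the Euler solver."""

import numpy as np
import pytest

from vedolink import (
    DoseEvent,
    PDParameters,
    PKParameters,
    closed_form_two_compartment,
    default_schedule,
    fit_elimination_rate,
    madcam,
    simulate,
)

from .conftest import rk4_two_compartment


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [{"qb": 0.0}, {"v1": -1.0}, {"v2": 0.0}, {"k": -0.01}, {"qb": float("nan")}],
    )
    def test_invalid_pk_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PKParameters(**kwargs)

    def test_zero_elimination_is_a_valid_limit(self):
        assert PKParameters(k=0.0).k == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [{"m0": 0.0}, {"emax": 1.2}, {"emax": -0.1}, {"gamma": 0.0}, {"e50": -1.0}],
    )
    def test_invalid_pd_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PDParameters(**kwargs)

    def test_dose_event_needs_exactly_one_amount(self):
        with pytest.raises(ValueError):
            DoseEvent(time=0.0)
        with pytest.raises(ValueError):
            DoseEvent(time=0.0, dose_mg=300.0, c1_increment=60.0)
        with pytest.raises(ValueError):
            DoseEvent(time=-1.0, dose_mg=300.0)
        with pytest.raises(ValueError):
            DoseEvent(time=0.0, dose_mg=-5.0)

    def test_dose_increment_from_mass(self, pk):
        assert DoseEvent(time=0.0, dose_mg=300.0).increment(pk.v1) == pytest.approx(300.0 / 3.12)
        assert DoseEvent(time=0.0, c1_increment=60.0).increment(pk.v1) == 60.0


class TestMadcam:
    def test_no_drug_gives_baseline(self, pdp):
        assert madcam(0.0, pdp) == pytest.approx(2.23e-2)

    def test_half_maximum_at_e50(self, pdp):
        # M0 * (1 - Emax/2) evaluated at c2 = E50
        assert madcam(0.093, pdp) == pytest.approx(2.23e-2 * (1 - 0.956 / 2), rel=1e-12)
        assert madcam(0.093, pdp) == pytest.approx(1.164e-2, rel=1e-3)

    def test_saturation_asymptote(self, pdp):
        # gamma = 0.3512 makes saturation slow; evaluate far out the tail
        assert madcam(1e30, pdp) == pytest.approx(2.23e-2 * (1 - 0.956), rel=1e-6)
        assert madcam(1e30, pdp) == pytest.approx(9.812e-4, rel=1e-3)

    def test_monotone_nonincreasing_and_bounded(self, pdp):
        c2 = np.linspace(0.0, 5.0, 400)
        m = madcam(c2, pdp)
        assert np.all(np.diff(m) <= 0)
        assert np.all(m <= pdp.m0 + 1e-15)
        assert np.all(m >= pdp.m0 * (1 - pdp.emax) - 1e-15)

    def test_negative_concentration_rejected(self, pdp):
        with pytest.raises(ValueError):
            madcam(-0.1, pdp)


class TestClosedForm:
    def test_initial_condition(self, pk):
        c1, c2 = closed_form_two_compartment(pk, 60.0, 0.0)
        assert c1 == pytest.approx(60.0, abs=1e-10)
        assert c2 == pytest.approx(0.0, abs=1e-10)

    def test_conservative_equilibrium(self):
        pk0 = PKParameters(k=0.0)
        c1, c2 = closed_form_two_compartment(pk0, 60.0, 1e6)
        eq = 60.0 * pk0.v1 / (pk0.v1 + pk0.v2)
        assert c1 == pytest.approx(eq, rel=1e-10)
        assert c2 == pytest.approx(eq, rel=1e-10)

    def test_matches_fine_step_runge_kutta(self, pk):
        """Independent brute-force RK4 oracle agrees to 6 significant digits."""
        c1_rk, c2_rk = rk4_two_compartment(pk, 60.0, t_end=14.0, h=1e-4)
        c1, c2 = closed_form_two_compartment(pk, 60.0, 14.0)
        assert c1 == pytest.approx(c1_rk, rel=1e-6)
        assert c2 == pytest.approx(c2_rk, rel=1e-6)

    def test_exact_conservation_without_elimination(self):
        pk0 = PKParameters(k=0.0)
        t = np.linspace(0.0, 200.0, 50)
        c1, c2 = closed_form_two_compartment(pk0, 60.0, t)
        total = pk0.v1 * c1 + pk0.v2 * c2
        assert np.allclose(total, 60.0 * pk0.v1, rtol=1e-12)

    def test_repeated_eigenvalue_limit_is_finite(self):
        # qb/v1 == qb/v2 + k gives eigenvalue collision territory
        pk_deg = PKParameters(qb=1.0, v1=1.0, v2=1.0, k=0.0)
        c1, c2 = closed_form_two_compartment(pk_deg, 10.0, np.array([0.0, 0.5, 5.0]))
        assert np.all(np.isfinite(c1)) and np.all(np.isfinite(c2))
        assert c1[-1] + c2[-1] == pytest.approx(10.0, rel=1e-9)


class TestSimulate:
    def test_invalid_grid_rejected(self, pk, pdp):
        sched = [DoseEvent(time=0.0, c1_increment=60.0)]
        with pytest.raises(ValueError):
            simulate(pk, pdp, sched, t_end=10.0, h=0.0)
        with pytest.raises(ValueError):
            simulate(pk, pdp, sched, t_end=-1.0, h=0.01)
        with pytest.raises(ValueError):
            simulate(pk, pdp, [DoseEvent(time=20.0, dose_mg=300.0)], t_end=10.0, h=0.01)

    def test_euler_conserves_drug_without_elimination(self, pdp):
        pk0 = PKParameters(k=0.0)
        traj = simulate(pk0, pdp, [DoseEvent(time=0.0, c1_increment=60.0)], t_end=100.0, h=0.01)
        total = pk0.v1 * traj.c1 + pk0.v2 * traj.c2
        # symmetric exchange cancels exactly even in the Euler update
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-12

    def test_single_bolus_matches_closed_form(self, pk, pdp):
        traj = simulate(pk, pdp, [DoseEvent(time=0.0, c1_increment=60.0)], t_end=42.0, h=0.01)
        c1_ref, c2_ref = closed_form_two_compartment(pk, 60.0, traj.times)
        i = np.argmin(np.abs(traj.times - 42.0))
        assert traj.c1[i] == pytest.approx(c1_ref[i], rel=1e-3)
        assert traj.c2[i] == pytest.approx(c2_ref[i], rel=1e-3)

    def test_first_order_convergence(self, pk, pdp):
        """Halving the step at least halves the deviation from the exact solution."""
        errs = []
        for h in (0.08, 0.04, 0.02):
            traj = simulate(pk, pdp, [DoseEvent(time=0.0, c1_increment=60.0)], t_end=56.0, h=h)
            c1_ref, _ = closed_form_two_compartment(pk, 60.0, traj.times)
            errs.append(np.max(np.abs(traj.c1 - c1_ref)))
        assert errs[1] <= 0.6 * errs[0]
        assert errs[2] <= 0.6 * errs[1]

    def test_multidose_peaks_at_dose_times_and_decay_between(self, pk, pdp):
        sched = default_schedule()
        traj = simulate(pk, pdp, sched, t_end=364.0, h=0.01)
        dose_idx = [int(round(ev.time / 0.01)) for ev in sched]
        for idx in dose_idx:
            # local maximum right at the jump
            assert traj.c1[idx] > traj.c1[idx - 1] if idx > 0 else True
            assert traj.c1[idx] > traj.c1[idx + 1]
        # strictly decaying between consecutive doses
        for lo, hi in zip(dose_idx[:-1], dose_idx[1:]):
            seg = traj.c1[lo:hi]
            assert np.all(np.diff(seg) < 0)

    def test_madcam_stays_within_hill_bounds(self, pk, pdp):
        traj = simulate(pk, pdp, default_schedule(), t_end=364.0, h=0.05)
        assert np.all(traj.m <= pdp.m0 + 1e-15)
        assert np.all(traj.m >= pdp.m0 * (1 - pdp.emax) - 1e-15)
        assert np.all(traj.c1 >= 0) and np.all(traj.c2 >= 0)


class TestEliminationRateRecovery:
    def test_recovers_k_from_noisy_decay(self, pk):
        """5% multiplicative noise on weekly samples; K back within 10%."""
        rng = np.random.default_rng(2024)
        times = np.arange(0.0, 364.0, 7.0)
        c1_true, _ = closed_form_two_compartment(pk, 60.0, times)
        observed = c1_true * (1.0 + 0.05 * rng.standard_normal(times.size))
        k_hat = fit_elimination_rate(times, observed, pk, c1_0=60.0)
        assert abs(k_hat - pk.k) / pk.k < 0.10

    def test_exact_data_recovers_k_sharply(self, pk):
        times = np.linspace(0.0, 200.0, 30)
        c1_true, _ = closed_form_two_compartment(pk, 60.0, times)
        k_hat = fit_elimination_rate(times, c1_true, pk, c1_0=60.0)
        assert k_hat == pytest.approx(pk.k, rel=1e-6)
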