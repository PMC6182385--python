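import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frrf import (
    FlashletTrain,
    FrrfTransient,
    PhotophysState,
    calibrate_dose,
    closure_from_fluorescence,
    closure_to_fluorescence,
    induction_closure,
    simulate_induction,
    simulate_relaxation,
)


class TestClosureMapping:
    def test_open_centres_give_F0(self):
        for rho in (0.0, 0.3, 0.6):
            assert closure_to_fluorescence(0.0, 0.2, 1.0, rho) == pytest.approx(0.2)

    def test_full_closure_gives_FM_for_any_rho(self):
        for rho in (0.0, 0.3, 0.6, 0.9):
            assert closure_to_fluorescence(1.0, 0.2, 1.0, rho) == pytest.approx(1.0)

    def test_linear_at_zero_connectivity(self):
        # rho = 0: F is linear in C
        assert closure_to_fluorescence(0.5, 0.2, 1.0, 0.0) == pytest.approx(0.6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            closure_to_fluorescence(1.0, 0.2, 1.0, 1.0)
        with pytest.raises(ValueError):
            closure_to_fluorescence(1.2, 0.2, 1.0, 0.3)

    @given(
        rho=st.floats(0.0, 0.95),
        c=st.floats(0.0, 1.0),
        dc=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_nondecreasing_in_closure(self, rho, c, dc):
        c2 = min(c + dc, 1.0)
        f1 = closure_to_fluorescence(c, 0.2, 1.0, rho)
        f2 = closure_to_fluorescence(c2, 0.2, 1.0, rho)
        assert f2 >= f1 - 1e-12

    @given(rho=st.floats(0.0, 0.9), c=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_inverse_round_trip(self, rho, c):
        f = closure_to_fluorescence(c, 0.2, 1.0, rho)
        assert closure_from_fluorescence(f, 0.2, 1.0, rho) == pytest.approx(c, abs=1e-9)


class TestFlashletTrain:
    def test_timestamps_strictly_increasing(self):
        tr = FlashletTrain(n_flashlets=40, dose_per_flashlet=1e-4)
        ts = tr.timestamps_us()
        assert ts.size == 40
        assert np.all(np.diff(ts) > 0)
        # timestamp of flashlet k is k * (flashlet + gap)
        assert ts[0] == pytest.approx(2.2)
        assert ts[-1] == pytest.approx(88.0)
        assert tr.span_us == pytest.approx(88.0)

    @pytest.mark.parametrize(
        "kw",
        [
            {"n_flashlets": 0},
            {"flashlet_duration_us": 0.0},
            {"gap_duration_us": -1.0},
            {"dose_per_flashlet": 0.0},
        ],
    )
    def test_invariants(self, kw):
        with pytest.raises(ValueError):
            FlashletTrain(**{"dose_per_flashlet": 1e-4, **kw})


class TestPhotophysState:
    @pytest.mark.parametrize(
        "kw",
        [
            {"F0": 1.0, "FM": 0.5},
            {"sigma": -1.0},
            {"rho": 1.0},
            {"tau1": 6000.0},
            {"alpha1": 0.5, "alpha2": 0.2},
        ],
    )
    def test_invariants(self, kw):
        base = dict(F0=0.2, FM=1.0, sigma=400.0)
        with pytest.raises(ValueError):
            PhotophysState(**{**base, **kw})


class TestInduction:
    def test_closed_form_at_zero_rho(self):
        # sigma * dose = 0.1 -> C_k = 1 - 0.9^k
        C = induction_closure(0.1, 0.0, 10)
        assert C[1] == pytest.approx(0.19)
        np.testing.assert_allclose(C, 1.0 - 0.9 ** np.arange(1, 11), rtol=1e-12)

    def test_zero_cross_section_is_flat(self, train):
        C = induction_closure(0.0, 0.3, 40)
        assert np.all(C == 0.0)
        st = PhotophysState(F0=0.2, FM=1.0, sigma=1e-9, rho=0.3)
        tr = simulate_induction(st, train)
        np.testing.assert_allclose(tr.fluorescence, 0.2, rtol=1e-6)

    def test_monotone_and_bounded(self, dark_state, train):
        tr = simulate_induction(dark_state, train)
        assert np.all(np.diff(tr.fluorescence) >= 0)
        assert np.all(tr.fluorescence >= dark_state.F0 - 1e-12)
        assert np.all(tr.fluorescence <= dark_state.FM + 1e-12)
        assert tr.phase == "induction"
        assert tr.n_points == train.n_flashlets

    def test_higher_rho_is_more_sigmoidal(self, train):
        # fixed cumulative dose: first-flashlet fluorescence drops with rho
        firsts = []
        for rho in (0.0, 0.3, 0.6):
            st = PhotophysState(F0=0.2, FM=1.0, sigma=400.0, rho=rho)
            firsts.append(simulate_induction(st, train).fluorescence[0])
        assert firsts[0] > firsts[1] > firsts[2]

    def test_inter_flashlet_relaxation_lowers_closure(self, dark_state, train):
        on = simulate_induction(dark_state, train, relax_between_flashlets=True)
        off = simulate_induction(dark_state, train)
        assert np.all(on.fluorescence <= off.fluorescence + 1e-12)
        assert on.fluorescence[-1] < off.fluorescence[-1]

    def test_fine_step_oracle(self):
        """The per-flashlet recursion matches a 1000-substep brute-force
        integration of the same closure law.  The recursion applies each
        flashlet's dose in one step, so equivalence with the continuum limit
        holds in the small-dose regime; the deviation grows linearly with
        per-flashlet dose (first-order update)."""
        dose = 1e-7  # photons / A^2: sigma*dose <= 6e-5 for the grid
        for sigma in (200.0, 400.0, 600.0):
            for rho in (0.0, 0.3, 0.5):
                C = induction_closure(sigma * dose, rho, 40)
                C_ref = _brute_force_closure(sigma * dose, rho, 40, substeps=1000)
                np.testing.assert_allclose(C, C_ref, rtol=1e-4)
        # convergence order: 100x the dose -> ~100x the relative error
        sigma, rho = 400.0, 0.3
        err = lambda d: np.max(
            np.abs(
                induction_closure(sigma * d, rho, 40)
                / _brute_force_closure(sigma * d, rho, 40, 1000)
                - 1.0
            )
        )
        assert 30.0 < err(1e-5) / err(1e-7) < 300.0

    def test_bad_c_init(self, dark_state, train):
        with pytest.raises(ValueError):
            simulate_induction(dark_state, train, C_init=1.0)


def _brute_force_closure(sigma_dose, rho, n, substeps):
    """Independent oracle: spread each flashlet's dose over many substeps."""
    C = 0.0
    out = []
    for _ in range(n):
        for _ in range(substeps):
            C = min(1.0, C + (sigma_dose / substeps) * (1 - C) / (1 - rho * C))
        out.append(C)
    return np.array(out)


class TestRelaxation:
    def test_initial_condition(self, dark_state):
        t = np.array([0.0, 10.0, 100.0, 1000.0])
        tr = simulate_relaxation(dark_state, 0.8, t)
        expected = closure_to_fluorescence(0.8, 0.2, 1.0, 0.3)
        assert tr.fluorescence[0] == pytest.approx(expected)

    def test_full_reopening(self, dark_state):
        t = np.array([0.0, 1e3, 1e4, 25 * dark_state.tau2])
        tr = simulate_relaxation(dark_state, 1.0, t)
        assert abs(tr.fluorescence[-1] - dark_state.F0) < 1e-6 * (
            dark_state.FM - dark_state.F0
        )

    def test_single_exponential_closed_form(self):
        st = PhotophysState(
            F0=0.2, FM=1.0, sigma=400.0, rho=0.0,
            tau1=500.0, tau2=5000.0, alpha1=1.0, alpha2=0.0,
        )
        tr = simulate_relaxation(st, 0.8, np.array([0.0, 250.0, 500.0, 750.0]))
        assert tr.fluorescence[2] == pytest.approx(0.2 + 0.8 * 0.8 / np.e)

    def test_strictly_decreasing_toward_F0(self, dark_state):
        t = np.linspace(0, 3e4, 50)
        tr = simulate_relaxation(dark_state, 1.0, t)
        assert np.all(np.diff(tr.fluorescence) < 0)
        assert np.all(tr.fluorescence > dark_state.F0)

    def test_phase_label_swap_invariance(self):
        a = PhotophysState(F0=0.2, FM=1.0, sigma=400.0, rho=0.2,
                           tau1=500.0, tau2=5000.0, alpha1=0.7, alpha2=0.3)
        # swapped labels describe the same physical decay only if both
        # (alpha, tau) pairs swap together
        t = np.linspace(0, 2e4, 30)
        fa = simulate_relaxation(a, 0.9, t).fluorescence
        C_b = 0.9 * (0.3 * np.exp(-t / 5000.0) + 0.7 * np.exp(-t / 500.0))
        fb = closure_to_fluorescence(C_b, 0.2, 1.0, 0.2)
        np.testing.assert_allclose(fa, fb, rtol=1e-12)

    def test_bad_c0(self, dark_state):
        with pytest.raises(ValueError):
            simulate_relaxation(dark_state, 0.0, np.array([0.0, 1.0, 2.0, 3.0]))


class TestCalibrateDose:
    def test_closed_form(self):
        dose = calibrate_dose(400.0, 30, 0.98)
        assert dose == pytest.approx(3.05e-4, rel=2e-2)
        # verify by running the recursion: closure at flashlet 30 is exact
        C = induction_closure(400.0 * dose, 0.0, 40)
        assert C[29] == pytest.approx(0.98, rel=1e-10)

    def test_small_closure_limit(self):
        assert calibrate_dose(400.0, 30, 1e-9) < 1e-10

    def test_scaling_symmetry(self):
        assert calibrate_dose(800.0, 30, 0.98) == pytest.approx(
            calibrate_dose(400.0, 30, 0.98) / 2.0
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            calibrate_dose(400.0, 30, 1.0)
        with pytest.raises(ValueError):
            calibrate_dose(400.0, 0, 0.9)


class TestTransientValidation:
    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            FrrfTransient(np.arange(5.0), np.ones(4), "induction")

    def test_too_short(self):
        with pytest.raises(ValueError):
            FrrfTransient(np.arange(3.0), np.ones(3), "induction")

    def test_nonincreasing_times(self):
        with pytest.raises(ValueError):
            FrrfTransient(np.array([0.0, 1.0, 1.0, 2.0]), np.ones(4), "relaxation")

    def test_negative_fluorescence(self):
        with pytest.raises(ValueError):
            FrrfTransient(np.arange(4.0), np.array([1.0, -0.1, 1.0, 1.0]), "induction")

    def test_dark_context_with_par(self):
        with pytest.raises(ValueError):
            FrrfTransient(
                np.arange(4.0), np.ones(4), "induction",
                light_context="dark_1s", actinic_par=100.0,
            )
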