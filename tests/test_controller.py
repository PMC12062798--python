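import math

import numpy as np
import pytest

from respassist.controller import (
    EXPIRATION,
    INSPIRATION,
    ControllerConfig,
    PhaseState,
    check_stability,
    control_current,
    desired_force,
    desired_pressure_profile,
    estimate_phase,
    plan_force,
    supply_pressure_ref,
)
from respassist.lung import MusclePressureProfile
from respassist.transmission import TransmissionModel


def _tm(delta=0.25, alpha=8.09, mu=67.41):
    return TransmissionModel(alpha_t=alpha, mu=mu, delta=delta)


class TestControllerConfig:
    def test_defaults_valid(self):
        cfg = ControllerConfig()
        assert cfg.kP == 2.6 and cfg.kD == 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"assist_gain": 1.5},
            {"B": 0.05},
            {"K": 6.0},
            {"kP": 1.0},  # strict lower bound: stability needs kP > 1
            {"kP": 11.0},
            {"kD": 0.0},
            {"Fmax": 500.0},
            {"Psup_max": 25.0},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ControllerConfig(**kwargs)


class TestPhaseEstimation:
    def test_theta_is_expired_volume_ratio(self):
        st = PhaseState(phase_label=EXPIRATION, vex_cum=0.0, vex_pred=0.8, warm_up=False)
        # accumulate 0.4 L at 1 L/s over 0.4 s
        for _ in range(80):
            estimate_phase(1.0, st, 5e-3, hysteresis=0.01)
        assert st.theta == pytest.approx(0.4 / 0.8, rel=1e-9)

    def test_theta_clamped_at_one(self):
        st = PhaseState(phase_label=EXPIRATION, vex_cum=1.0, vex_pred=0.8, warm_up=False)
        estimate_phase(0.5, st, 5e-3, hysteresis=0.01)
        assert st.theta == 1.0

    def test_expiration_onset_resets_theta(self):
        st = PhaseState(phase_label=INSPIRATION, vex_pred=0.8, warm_up=False)
        estimate_phase(0.5, st, 5e-3, hysteresis=0.01)
        assert st.phase_label == EXPIRATION
        assert st.theta == 0.0 and st.vex_cum == 0.0

    def test_warm_up_pins_theta_to_zero(self):
        st = PhaseState(phase_label=EXPIRATION)
        for _ in range(100):
            estimate_phase(1.0, st, 5e-3, hysteresis=0.01)
        assert st.warm_up and st.theta == 0.0

    def test_prediction_updates_from_completed_breath(self):
        st = PhaseState(phase_label=EXPIRATION)
        for _ in range(100):  # expire 0.5 L
            estimate_phase(1.0, st, 5e-3, hysteresis=0.01)
        estimate_phase(-0.5, st, 5e-3, hysteresis=0.01)  # flip to inspiration
        assert st.phase_label == INSPIRATION
        assert not st.warm_up
        assert st.vex_pred == pytest.approx(0.5, rel=1e-9)

    def test_hysteresis_blocks_small_reversals(self):
        st = PhaseState(phase_label=EXPIRATION, vex_pred=0.8, warm_up=False)
        estimate_phase(-0.005, st, 5e-3, hysteresis=0.01)
        assert st.phase_label == EXPIRATION

    def test_debounce_blocks_early_flip(self):
        st = PhaseState(phase_label=EXPIRATION, vex_pred=0.8, warm_up=False)
        estimate_phase(-1.0, st, 5e-3, hysteresis=0.01, min_phase_samples=10)
        assert st.phase_label == EXPIRATION


class TestDesiredPressure:
    profile = MusclePressureProfile(A_mus=3.1023, phi=-0.51486)

    def test_assistance_off(self):
        cfg = ControllerConfig(assist_gain=0.0)
        assert desired_pressure_profile(0.5, self.profile, cfg) == 0.0

    def test_half_gain_mid_expiration(self):
        cfg = ControllerConfig(assist_gain=0.5)
        assert desired_pressure_profile(0.5, self.profile, cfg) == pytest.approx(
            1.3502, abs=5e-4
        )

    def test_floored_at_zero_early_in_expiration(self):
        cfg = ControllerConfig(assist_gain=1.0)
        # sin(pi*0 + phi) < 0 -> no suction
        assert desired_pressure_profile(0.0, self.profile, cfg) == 0.0

    def test_airway_ceiling_clip(self):
        # predicted Pmus + Pexo_ref would peak at 31; must clip so sum <= 30
        prof = MusclePressureProfile(A_mus=15.5, phi=0.0)
        cfg = ControllerConfig(assist_gain=1.0)
        th = np.linspace(0.0, 1.0, 201)
        total = np.array(
            [prof(t) + desired_pressure_profile(float(t), prof, cfg) for t in th]
        )
        assert total.max() <= 30.0 + 1e-12
        assert total.max() == pytest.approx(30.0, abs=1e-9)

    def test_theta_domain(self):
        with pytest.raises(ValueError):
            desired_pressure_profile(1.2, self.profile, ControllerConfig())


class TestForcePlanning:
    def test_reference_force_division(self):
        assert desired_force(10.0, _tm(0.25), ControllerConfig()) == pytest.approx(40.0)

    def test_reference_force_zero(self):
        assert desired_force(0.0, _tm(0.25), ControllerConfig()) == 0.0

    def test_reference_force_clamped_at_ceiling(self):
        assert desired_force(200.0, _tm(0.25), ControllerConfig()) == 400.0

    def test_plan_passthrough_without_feedback(self):
        assert plan_force(100.0, 0.0, 0.0, ControllerConfig()) == pytest.approx(100.0)

    def test_plan_hand_value(self):
        cfg = ControllerConfig(B=1.0, K=0.5)
        assert plan_force(100.0, 40.0, 10.0, cfg) == pytest.approx(70.0)

    def test_plan_lower_clamp(self):
        cfg = ControllerConfig(B=1.0, K=0.5)
        assert plan_force(10.0, 100.0, 50.0, cfg) == 0.0

    def test_plan_monotone_nonincreasing_in_feedback(self):
        cfg = ControllerConfig(B=1.0, K=0.5)
        fints = np.linspace(0.0, 200.0, 30)
        plans = [plan_force(150.0, f, 0.0, cfg) for f in fints]
        assert np.all(np.diff(plans) <= 1e-12)
        dfs = np.linspace(-100.0, 100.0, 30)
        plans = [plan_force(150.0, 0.0, d, cfg) for d in dfs]
        assert np.all(np.diff(plans) <= 1e-12)


class TestSupplyPressureRef:
    def test_literal_division(self):
        tm = _tm(alpha=8.1, mu=50.0)
        assert supply_pressure_ref(81.0, tm, ControllerConfig()) == pytest.approx(10.0)

    def test_clamped_at_supply_ceiling(self):
        tm = _tm(alpha=8.09)
        assert supply_pressure_ref(400.0, tm, ControllerConfig()) == 20.0

    def test_exact_inverse_cancels_offset(self):
        tm = _tm(alpha=8.09, mu=67.41)
        assert supply_pressure_ref(67.41, tm, ControllerConfig(), exact_inverse=True) == 0.0


class TestControlCurrent:
    def test_feedforward_only(self):
        i, sat = control_current(0.0, 0.0, 0.0, 0.0, ControllerConfig(), 1.0, 1.0, 16.0)
        assert i == pytest.approx(4.0)
        assert not sat

    def test_zero_source_pressure(self):
        i, sat = control_current(0.0, 0.0, 0.0, 0.0, ControllerConfig(), 1.0, 1.0, 0.0)
        assert i == 0.0 and not sat

    def test_negative_radicand_saturates(self):
        cfg = ControllerConfig(kP=2.6, kD=0.5)
        # e = 10 -> radicand 16 - 26 < 0 -> floored, flagged
        i, sat = control_current(10.0, 0.0, 0.0, 0.0, cfg, 1.0, 1.0, 16.0)
        assert i == 0.0 and sat


class TestStability:
    def test_printed_gains_stable(self):
        rep = check_stability(ControllerConfig(kP=2.6, kD=0.5))
        assert rep.stable
        assert rep.margin == pytest.approx(0.5)
        assert rep.lyapunov_nonincreasing

    def test_boundary_gain_rejected(self):
        assert not check_stability(kP=1.0, kD=0.5).stable

    def test_zero_damping_rejected(self):
        assert not check_stability(kP=5.0, kD=0.0).stable

    def test_lyapunov_nonincreasing_for_random_stable_gains(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            kp = rng.uniform(1.01, 10.0)
            kd = rng.uniform(0.01, 1.0)
            x0 = tuple(rng.uniform(-2.0, 2.0, size=2))
            rep = check_stability(kP=kp, kD=kd, x0=x0)
            assert rep.stable
            assert rep.lyapunov_nonincreasing, (kp, kd, rep.max_lyapunov_increase)

    def test_requires_gains(self):
        with pytest.raises(ValueError):
            check_stability()
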