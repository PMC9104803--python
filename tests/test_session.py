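import math
from dataclasses import replace

import numpy as np
import pytest

from fesloop.pid import PIDGains
from fesloop.plant import default_plant
from fesloop.session import (
    SafetyStopError,
    SessionConfig,
    SessionLog,
    SetpointProfile,
    SetpointSegment,
    default_config,
    protocol_setpoints,
    run_session,
    step_response,
    tracking_metrics,
)


class TestProtocolSetpoints:
    def test_segment_sequence_and_references(self):
        profile = protocol_setpoints()
        labels = [s.label for s in profile.segments]
        assert labels == [
            "neutral", "inversion", "eversion", "neutral_2",
            "dorsiflexion", "plantar_flexion",
        ]
        assert profile.refs_at(1.0) == (0.0, 0.0)
        assert profile.refs_at(12.0) == (0.0, 20.0)  # inversion
        assert profile.refs_at(27.0) == (0.0, 0.0)  # second neutral
        assert profile.refs_at(40.0) == (20.0, 0.0)  # dorsiflexion
        assert profile.refs_at(50.0) == (-20.0, 0.0)  # plantar flexion

    def test_eversion_is_negative_and_shorter(self):
        profile = protocol_setpoints()
        ev = next(s for s in profile.segments if s.label == "eversion")
        inv = next(s for s in profile.segments if s.label == "inversion")
        assert ev.frontal_ref_deg == -5.0
        assert (ev.end_s - ev.start_s) < (inv.end_s - inv.start_s)

    def test_profile_must_start_neutral(self):
        with pytest.raises(ValueError, match="neutral"):
            SetpointProfile((SetpointSegment(0.0, 5.0, 10.0, 0.0, "bad"),))

    def test_profile_must_be_contiguous(self):
        with pytest.raises(ValueError, match="contiguous"):
            SetpointProfile(
                (
                    SetpointSegment(0.0, 5.0, 0.0, 0.0, "a"),
                    SetpointSegment(6.0, 10.0, 5.0, 0.0, "b"),
                )
            )

    def test_refs_clamp_past_the_end(self):
        profile = protocol_setpoints()
        assert profile.refs_at(profile.duration_s + 100.0) == (-20.0, 0.0)


class TestSessionConfig:
    def test_default_config_carries_published_limits(self):
        cfg = default_config()
        assert (cfg.pid_sagittal.u_min, cfg.pid_sagittal.u_max) == (-14.0, 10.0)
        assert (cfg.pid_frontal.u_min, cfg.pid_frontal.u_max) == (-12.0, 14.0)
        assert all(s.frequency_hz == 50.0 for s in cfg.stimulation)
        assert all(s.pulse_duration_us == 200.0 for s in cfg.stimulation)
        assert all(s.amplitude_duty_pct == 5.0 for s in cfg.stimulation)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="imu_rate_hz"):
            SessionConfig(imu_rate_hz=0.0)

    def test_channel_reused_across_pairs_rejected(self):
        from fesloop.selector import ChannelPair

        pairs = {
            "sagittal": ChannelPair(0, 1, "sagittal"),
            "frontal": ChannelPair(1, 2, "frontal"),
        }
        with pytest.raises(ValueError, match="assigned to both"):
            SessionConfig(pairs=pairs)


class TestRunSession:
    def test_zero_gains_is_open_loop_at_rest(self, reference_plant):
        zero = PIDGains(kp=0.0, ki=0.0, kd=0.0, u_min=-14.0, u_max=10.0)
        cfg = replace(
            default_config(), pid_sagittal=zero,
            pid_frontal=replace(zero, u_min=-12.0, u_max=14.0),
            duration_s=5.0,
        )
        log = run_session(cfg, reference_plant)
        assert np.all(log.duties_pct == 0.0)
        assert np.all(np.abs(log.true_sagittal_deg) < 1.0)
        assert np.all(np.abs(log.true_frontal_deg) < 1.0)

    def test_every_action_within_its_limits(self, reference_config, reference_plant):
        log = run_session(reference_config, reference_plant)
        assert np.all(log.u_sagittal >= -14.0) and np.all(log.u_sagittal <= 10.0)
        assert np.all(log.u_frontal >= -12.0) and np.all(log.u_frontal <= 14.0)

    def test_selector_mutual_exclusion_in_log(self, reference_config, reference_plant):
        log = run_session(reference_config, reference_plant)
        ids = list(log.channel_ids)
        sag = log.duties_pct[:, [ids.index(0), ids.index(1)]]
        fro = log.duties_pct[:, [ids.index(2), ids.index(3)]]
        assert np.all(np.min(sag, axis=1) == 0.0)
        assert np.all(np.min(fro, axis=1) == 0.0)

    def test_reproducibility(self, reference_config, reference_plant):
        a = run_session(reference_config, reference_plant)
        b = run_session(reference_config, reference_plant)
        assert np.array_equal(a.true_sagittal_deg, b.true_sagittal_deg)
        assert np.array_equal(a.duties_pct, b.duties_pct)

    def test_frontal_setpoints_do_not_perturb_sagittal(self, reference_plant):
        """Noise-free controller independence is exact (bit-identical)."""
        base = default_config(seed=3)
        altered_segments = tuple(
            replace(s, frontal_ref_deg=0.5 * s.frontal_ref_deg)
            for s in base.profile.segments
        )
        altered = replace(base, profile=SetpointProfile(altered_segments))
        log_a = run_session(base, reference_plant)
        log_b = run_session(altered, reference_plant)
        assert np.array_equal(log_a.true_sagittal_deg, log_b.true_sagittal_deg)
        assert np.array_equal(log_a.u_sagittal, log_b.u_sagittal)
        assert not np.array_equal(log_a.true_frontal_deg, log_b.true_frontal_deg)

    def test_safety_ceiling_aborts(self, reference_plant):
        cfg = replace(default_config(), duty_ceiling_pct=5.0)
        with pytest.raises(SafetyStopError):
            run_session(cfg, reference_plant)

    def test_header_records_seed_and_gains(self, reference_config, reference_plant):
        log = run_session(reference_config, reference_plant)
        assert log.header["seed"] == reference_config.seed
        assert log.header["pid_sagittal"]["kp"] == 8.2

    def test_csv_export(self, tmp_path, reference_plant):
        cfg = replace(default_config(), duration_s=1.0)
        log = run_session(cfg, reference_plant)
        path = tmp_path / "log.csv"
        log.to_csv(path)
        text = path.read_text()
        assert text.startswith("# fesloop-session-header:")
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        assert len(df) == len(log)
        assert "duty_ch0_pct" in df.columns


class TestStepResponse:
    def test_zero_step_is_trivial(self, reference_config, reference_plant):
        m = step_response(reference_config, reference_plant, "sagittal", 0.0)
        assert m.rise_time_s == 0.0
        assert m.steady_state_error_deg == 0.0

    def test_step_outside_plant_limits_rejected(self, reference_config, reference_plant):
        with pytest.raises(ValueError, match="outside plant limits"):
            step_response(reference_config, reference_plant, "sagittal", 45.0)

    def test_p_only_steady_state_error_decreases_with_kp(self, reference_plant):
        """Pure-P sweep in the linear recruitment region: higher kp, lower
        offset (the proportional controller's residual error)."""
        errors = []
        for kp in (1.0, 2.0, 3.0):
            gains = PIDGains(kp=kp, ki=0.0, kd=0.0, u_min=-14.0, u_max=10.0)
            cfg = replace(default_config(), pid_sagittal=gains)
            m = step_response(cfg, reference_plant, "sagittal", 4.0)
            errors.append(m.steady_state_error_deg)
        assert errors[0] > errors[1] > errors[2] > 0.0

    def test_pi_removes_steady_state_error(self, reference_config, reference_plant):
        m = step_response(reference_config, reference_plant, "sagittal", 10.0)
        assert abs(m.steady_state_error_deg) < 0.5
        assert m.rise_time_s > 0.0


class TestTrackingMetrics:
    def test_perfect_tracking_log(self):
        """Synthetic log with angles identically equal to the references."""
        profile = protocol_setpoints(hold_s=2.0, eversion_hold_s=1.0)
        n = int(profile.duration_s * 100)
        t = np.arange(n) / 100.0
        refs = np.array([profile.refs_at(tk) for tk in t])
        zeros = np.zeros(n)
        log = SessionLog(
            header={}, profile=profile, channel_ids=(0, 1, 2, 3),
            t_s=t,
            ref_sagittal_deg=refs[:, 0], ref_frontal_deg=refs[:, 1],
            est_sagittal_deg=refs[:, 0], est_frontal_deg=refs[:, 1],
            true_sagittal_deg=refs[:, 0], true_frontal_deg=refs[:, 1],
            u_sagittal=zeros, u_frontal=zeros,
            sat_sagittal=np.zeros(n, dtype=bool), sat_frontal=np.zeros(n, dtype=bool),
            duties_pct=np.zeros((n, 4)),
        )
        for m in tracking_metrics(log, settle_s=0.5):
            assert m["mean_abs_error_deg"] == 0.0
            assert m["frac_saturated"] == 0.0
            if m["dof"] is not None:
                assert m["peak_deg"] == m["reference_deg"]

    def test_zero_duty_log_has_near_zero_peaks(self, reference_plant):
        zero = PIDGains(kp=0.0, ki=0.0, kd=0.0, u_min=-14.0, u_max=10.0)
        cfg = replace(
            default_config(), pid_sagittal=zero,
            pid_frontal=replace(zero, u_min=-12.0, u_max=14.0),
        )
        log = run_session(cfg, reference_plant)
        for m in tracking_metrics(log):
            if m["dof"] is not None:
                assert abs(m["peak_deg"]) < 1.0

    def test_acceptance_style_peaks(self, reference_config, reference_plant):
        log = run_session(reference_config, reference_plant)
        by_label = {m["label"]: m for m in tracking_metrics(log)}
        assert by_label["dorsiflexion"]["peak_deg"] >= 19.0
        assert by_label["plantar_flexion"]["peak_deg"] <= -19.0
        assert by_label["inversion"]["peak_deg"] >= 19.0
        assert by_label["eversion"]["peak_deg"] <= -4.75

    def test_empty_log_rejected(self):
        profile = protocol_setpoints()
        log = SessionLog(
            header={}, profile=profile, channel_ids=(),
            t_s=np.empty(0), ref_sagittal_deg=np.empty(0), ref_frontal_deg=np.empty(0),
            est_sagittal_deg=np.empty(0), est_frontal_deg=np.empty(0),
            true_sagittal_deg=np.empty(0), true_frontal_deg=np.empty(0),
            u_sagittal=np.empty(0), u_frontal=np.empty(0),
            sat_sagittal=np.empty(0, dtype=bool), sat_frontal=np.empty(0, dtype=bool),
            duties_pct=np.empty((0, 0)),
        )
        with pytest.raises(ValueError, match="empty"):
            tracking_metrics(log)
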