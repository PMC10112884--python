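"""Motion processing: jerk, wingbeat filtering, flight epochs, landings,
heading, and foraging-bout segmentation."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal
from scipy.spatial.transform import Rotation

from batforage import motion
from batforage.motion import FlightEpoch, ForagingBout, HeadingSeries, MotionTrack
from batforage.pipeline import broadband_envelope


def _accel_frame(ax, ay, az, fs=100.0):
    n = len(az)
    t = np.arange(n) / fs
    return pd.DataFrame({"t": t, "ax": np.broadcast_to(ax, n), "ay": np.broadcast_to(ay, n), "az": az})


class TestJerk:
    def test_constant_acceleration_gives_zero(self):
        acc = _accel_frame(0.0, 0.0, np.full(100, 9.81))
        assert np.allclose(motion.compute_jerk(acc), 0.0)

    def test_unit_step_gives_fs_spike(self):
        az = np.full(100, 9.81)
        az[50:] += 1.0
        j = motion.compute_jerk(_accel_frame(0.0, 0.0, az))
        assert j.max() == pytest.approx(100.0)
        assert np.count_nonzero(j) == 1

    def test_sinusoid_max_jerk_is_2pi_f_a(self):
        fs, f, a = 1000.0, 5.0, 3.0
        t = np.arange(0, 4, 1 / fs)
        acc = _accel_frame(0.0, 0.0, a * np.sin(2 * np.pi * f * t), fs=fs)
        j = motion.compute_jerk(acc)
        assert j.max() == pytest.approx(2 * np.pi * f * a, rel=0.01)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            motion.compute_jerk(_accel_frame(0.0, 0.0, np.array([9.81])))


class TestWingbeatBandpass:
    def test_dc_fully_rejected(self):
        out = motion.bandpass_wingbeat(np.full(6000, 42.0), 100.0)
        mid = out[2000:4000]
        assert np.abs(mid).max() < 1e-6 * 42.0

    def test_10hz_passed_within_5pc(self):
        t = np.arange(6000) / 100.0
        out = motion.bandpass_wingbeat(np.sin(2 * np.pi * 10 * t), 100.0)
        assert abs(np.abs(out[2000:4000]).max() - 1.0) < 0.05

    def test_50hz_alias_free_region_attenuated_20db(self):
        # 40 Hz (below Nyquist at 100 Hz) must be strongly attenuated
        t = np.arange(6000) / 100.0
        out = motion.bandpass_wingbeat(np.sin(2 * np.pi * 40 * t), 100.0)
        assert np.abs(out[2000:4000]).max() < 0.1  # >= 20 dB down

    def test_zero_phase(self):
        """A band-limited burst and its filtered output peak at the same lag."""
        rng = np.random.default_rng(0)
        t = np.arange(8000) / 100.0
        burst = np.sin(2 * np.pi * 12 * t) * np.exp(-((t - 40.0) ** 2) / 8.0)
        out = motion.bandpass_wingbeat(burst, 100.0)
        xc = signal.correlate(out[1024:-1024], burst[1024:-1024], mode="full")
        lag = np.argmax(xc) - (len(burst) - 2048 - 1)
        assert abs(lag) <= 1

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            motion.bandpass_wingbeat(np.zeros(500), 100.0)


class TestFlightEpochs:
    def test_noise_alone_gives_no_epochs(self):
        rng = np.random.default_rng(0)
        bp = motion.bandpass_wingbeat(rng.normal(0, 0.3, 12000), 100.0)
        assert motion.detect_flight_epochs(bp, 100.0) == []

    @pytest.mark.parametrize(
        "amplitude,expect_epoch",
        [(40.0, True), (20.0, False)],  # rectified means 25.5 vs 12.7 around the 20 threshold
    )
    def test_rectified_mean_threshold_boundary(self, amplitude, expect_epoch):
        t = np.arange(12000) / 100.0
        bp = motion.bandpass_wingbeat(amplitude * np.sin(2 * np.pi * 10 * t), 100.0)
        epochs = motion.detect_flight_epochs(bp, 100.0)
        assert bool(epochs) is expect_epoch

    def test_invariant_to_constant_offset(self):
        t = np.arange(12000) / 100.0
        raw = 40.0 * np.sin(2 * np.pi * 10 * t)
        e1 = motion.detect_flight_epochs(motion.bandpass_wingbeat(raw, 100.0), 100.0)
        e2 = motion.detect_flight_epochs(motion.bandpass_wingbeat(raw + 55.0, 100.0), 100.0)
        assert [(round(a.start), round(a.end)) for a in e1] == [(round(a.start), round(a.end)) for a in e2]


class TestLandings:
    def test_generator_landings_recovered(self, motion_scene):
        _, rec, log = motion_scene
        mt = MotionTrack(accel=rec.accel, mag=rec.mag)
        env = broadband_envelope(rec.audio, rec.audio_fs)
        found = motion.detect_landings(mt, env, 1000.0)
        truth = log.of_kind("landing")["t"].to_numpy()
        assert len(found) == len(truth)
        for tt in truth:
            assert np.min(np.abs(np.asarray(found) - tt)) <= 0.1

    def test_continuous_flight_no_landings(self):
        rng = np.random.default_rng(5)
        n = 12000
        t = np.arange(n) / 100.0
        az = 9.81 + 35 * np.sin(2 * np.pi * 10 * t) + rng.normal(0, 0.3, n)
        acc = pd.DataFrame({"t": t, "ax": rng.normal(0, 0.3, n), "ay": rng.normal(0, 0.3, n), "az": az})
        tm = np.arange(n // 2) / 50.0
        mag = pd.DataFrame({"t": tm, "mx": np.full(n // 2, 0.5), "my": np.zeros(n // 2), "mz": np.full(n // 2, -0.87)})
        env = rng.rayleigh(0.005, int(120 * 1000))
        assert motion.detect_landings(MotionTrack(accel=acc, mag=mag), env, 1000.0) == []

    def test_audio_transient_without_accel_peak_is_not_landing(self):
        rng = np.random.default_rng(6)
        n = 12000
        t = np.arange(n) / 100.0
        az = 9.81 + 35 * np.sin(2 * np.pi * 10 * t) + rng.normal(0, 0.3, n)
        acc = pd.DataFrame({"t": t, "ax": rng.normal(0, 0.3, n), "ay": rng.normal(0, 0.3, n), "az": az})
        mag = pd.DataFrame({"t": t[::2], "mx": 0.5, "my": 0.0, "mz": -0.87})
        env = rng.rayleigh(0.005, int(120 * 1000))
        env[60_000] = 0.9  # loud click at t=60 s with no accelerometer signature
        assert motion.detect_landings(MotionTrack(accel=acc, mag=mag), env, 1000.0) == []


def _orientation_vectors(yaw, pitch, roll):
    """Body-frame accelerometer/magnetometer readings for a given attitude.

    World frame NED; yaw clockwise from north about the down axis, then
    pitch (nose up) about the body left axis, then roll about the body
    forward axis.  Body axes: x forward, y left, z up.
    """

    def rot(axis, ang):
        return Rotation.from_rotvec(np.asarray(axis) / np.linalg.norm(axis) * ang).as_matrix()

    x, y, z = np.array([1.0, 0, 0]), np.array([0, -1.0, 0]), np.array([0, 0, -1.0])
    r1 = rot([0, 0, 1.0], yaw)
    x, y, z = r1 @ x, r1 @ y, r1 @ z
    r2 = rot(y, -pitch)
    x, y, z = r2 @ x, r2 @ y, r2 @ z
    r3 = rot(x, roll)
    x, y, z = r3 @ x, r3 @ y, r3 @ z
    up_w = np.array([0, 0, -1.0])
    field_w = np.array([np.cos(np.radians(60)), 0.0, np.sin(np.radians(60))])
    a = 9.81 * np.array([up_w @ x, up_w @ y, up_w @ z])
    m = np.array([field_w @ x, field_w @ y, field_w @ z])
    return a, m


def _heading_for(yaw, pitch, roll):
    a, m = _orientation_vectors(yaw, pitch, roll)
    n = 400
    acc = pd.DataFrame({"t": np.arange(n) / 100.0, "ax": a[0], "ay": a[1], "az": a[2]})
    mag = pd.DataFrame({"t": np.arange(n // 2) / 50.0, "mx": m[0], "my": m[1], "mz": m[2]})
    h = motion.compute_heading(MotionTrack(accel=acc, mag=mag))
    return float(np.nanmedian(h.heading))


class TestHeading:
    def test_level_north_facing_gives_zero(self):
        assert abs(_heading_for(0.0, 0.0, 0.0)) < np.radians(0.1)

    def test_pure_roll_leaves_heading_unchanged(self):
        assert abs(_heading_for(0.0, 0.0, np.radians(30))) < np.radians(0.1)

    def test_yaw_90_gives_plus_90(self):
        assert _heading_for(np.radians(90), 0.0, 0.0) == pytest.approx(np.radians(90), abs=np.radians(0.1))

    def test_recovery_rms_under_2_degrees(self):
        rng = np.random.default_rng(0)
        errs = []
        for _ in range(100):
            yaw = rng.uniform(-np.pi, np.pi)
            pitch = rng.uniform(-np.pi / 4, np.pi / 4)
            roll = rng.uniform(-np.pi / 4, np.pi / 4)
            est = _heading_for(yaw, pitch, roll)
            errs.append(np.degrees(np.angle(np.exp(1j * (est - yaw)))))
        assert np.sqrt(np.mean(np.square(errs))) < 2.0

    def test_free_fall_masked(self):
        n = 400
        acc = pd.DataFrame({"t": np.arange(n) / 100.0, "ax": 0.0, "ay": 0.0, "az": 0.01})
        mag = pd.DataFrame({"t": np.arange(n // 2) / 50.0, "mx": 0.5, "my": 0.0, "mz": -0.87})
        h = motion.compute_heading(MotionTrack(accel=acc, mag=mag))
        assert np.isnan(h.heading).all()


class TestForagingBouts:
    def test_constant_heading_gives_no_bouts(self):
        rng = np.random.default_rng(0)
        n = 50 * 600
        h = HeadingSeries(t=np.arange(n) / 50.0, heading=rng.normal(0.3, 0.005, n), pitch=np.zeros(n), roll=np.zeros(n))
        assert motion.detect_foraging_bouts(h, 50.0) == []

    def test_generator_bout_recovered(self, motion_scene):
        cfg, rec, log = motion_scene
        mt = MotionTrack(accel=rec.accel, mag=rec.mag)
        h = motion.compute_heading(mt)
        bouts = motion.detect_foraging_bouts(h, mt.mag_fs)
        truth = (cfg.duration / 3, 2 * cfg.duration / 3)
        assert len(bouts) == 1
        b = bouts[0]
        overlap = min(b.end, truth[1]) - max(b.start, truth[0])
        assert overlap / (truth[1] - truth[0]) >= 0.8
        # boundaries within one running-mean window of truth
        assert abs(b.start - truth[0]) <= 50.0 and abs(b.end - truth[1]) <= 50.0

    def test_escalation_reduces_switches(self):
        rng = np.random.default_rng(2)
        fs = 50.0
        segs = []
        for k in range(16):  # 15 alternations of medium/quiet variation
            sd = 0.15 if k % 2 == 0 else 0.003
            segs.append(rng.normal(0.0, sd, int(60 * fs)))
        h = HeadingSeries(t=np.arange(16 * int(60 * fs)) / fs, heading=np.concatenate(segs), pitch=None, roll=None)
        env = motion.heading_variation(h, fs)
        low_switches = int(np.sum(np.abs(np.diff((env > 0.05).astype(int)))))
        assert low_switches > 10  # the 0.05 threshold over-segments this night
        bouts = motion.detect_foraging_bouts(h, fs)
        switches = 2 * len(bouts)
        assert switches <= 10  # recomputed at the escalated 0.3 threshold

    def test_fully_masked_heading_rejected(self):
        n = 1000
        h = HeadingSeries(t=np.arange(n) / 50.0, heading=np.full(n, np.nan), pitch=None, roll=None)
        with pytest.raises(ValueError):
            motion.detect_foraging_bouts(h, 50.0)


class TestFilterBouts:
    def test_only_bouts_with_attacks_kept(self):
        bouts = [ForagingBout(0, 100), ForagingBout(100, 200), ForagingBout(200, 300)]
        kept = motion.filter_bouts(bouts, np.array([150.0, 160.0]))
        assert [(b.start, b.end, b.n_attacks) for b in kept] == [(100, 200, 2)]

    def test_boundary_attack_assigned_half_open(self):
        bouts = [ForagingBout(0, 100), ForagingBout(100, 200)]
        kept = motion.filter_bouts(bouts, np.array([100.0]))
        assert [(b.start, b.end) for b in kept] == [(100, 200)]

    def test_no_attacks_empty(self):
        assert motion.filter_bouts([ForagingBout(0, 100)], np.array([])) == []
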