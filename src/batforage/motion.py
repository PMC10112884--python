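"""Accelerometer/magnetometer processing.

Flight is detected from the wingbeat oscillation on the heave axis: the
signal is band-passed 5–25 Hz with a symmetric (zero-phase) FIR filter,
rectified, and averaged over a 50 s running window; epochs above
20 m/s^2 are flight.  Landings show as a jerk peak coincident with a
broadband audio transient followed by a flattening of the accelerometer.
Heading is computed by gimballing the 3 Hz low-passed magnetic field with
pitch and roll estimated from the 3 Hz low-passed accelerometer, and
foraging bouts are intervals of high heading variation (envelope of the
circular residual about a 50 s running circular mean above a threshold).

Body axes: x = surge (forward), y = sway (left), z = heave (up); a tag at
rest reads +g on z.  Heading is clockwise-positive from magnetic north.
Running means are centered with shrinking windows at the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

GRAVITY = 9.81
FLIGHT_THRESHOLD = 20.0  # m/s^2, rectified band-passed running mean
FLIGHT_WINDOW_S = 50.0
BOUT_THRESHOLD = 0.05  # rad, heading-variation envelope
BOUT_THRESHOLD_ESCALATED = 0.3
MAX_MODE_SWITCHES = 10

__all__ = [
    "MotionTrack",
    "FlightEpoch",
    "ForagingBout",
    "HeadingSeries",
    "compute_jerk",
    "bandpass_wingbeat",
    "detect_flight_epochs",
    "detect_landings",
    "compute_heading",
    "detect_foraging_bouts",
    "filter_bouts",
]


@dataclass
class MotionTrack:
    accel: pd.DataFrame  # t, ax, ay, az
    mag: pd.DataFrame  # t, mx, my, mz

    @property
    def accel_fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.accel["t"].to_numpy())))

    @property
    def mag_fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.mag["t"].to_numpy())))


@dataclass
class FlightEpoch:
    start: float
    end: float


@dataclass
class ForagingBout:
    start: float
    end: float
    mode: str = "foraging"  # 'foraging' | 'commuting'
    n_attacks: int = 0


@dataclass
class HeadingSeries:
    t: np.ndarray
    heading: np.ndarray  # rad, (-pi, pi], NaN where undefined
    pitch: np.ndarray
    roll: np.ndarray


def compute_jerk(accel: pd.DataFrame) -> np.ndarray:
    """Norm of the per-axis first difference times the sample rate (m/s^3).

    Output length is n - 1.
    """
    if len(accel) < 2:
        raise ValueError("jerk needs at least two samples")
    t = accel["t"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    d = np.diff(accel[["ax", "ay", "az"]].to_numpy(), axis=0) * fs
    return np.linalg.norm(d, axis=1)


def bandpass_wingbeat(
    az: np.ndarray,
    fs: float,
    band: tuple[float, float] = (5.0, 25.0),
    numtaps: int = 1024,
) -> np.ndarray:
    """Zero-phase FIR band-pass of the heave axis (5–25 Hz, 1024 taps).

    Input is resampled to 100 Hz if needed.  The symmetric FIR is applied
    centered, so the output has no group delay.
    """
    az = np.asarray(az, dtype=float)
    if fs != 100.0:
        n_out = int(round(len(az) * 100.0 / fs))
        az = signal.resample_poly(az, 100, int(round(fs))) if float(fs).is_integer() else signal.resample(az, n_out)
        fs = 100.0
    if len(az) <= numtaps:
        raise ValueError(f"input ({len(az)} samples) shorter than the {numtaps}-tap filter")
    # odd tap count -> exactly symmetric impulse response, so centered
    # convolution is delay-free; removing the tap mean pins an exact null
    # at DC (gravity offsets cannot leak into the wingbeat band)
    n = numtaps + 1 if numtaps % 2 == 0 else numtaps
    taps = signal.firwin(n, band, pass_zero=False, fs=fs)
    taps -= taps.mean()
    return signal.fftconvolve(az, taps, mode="same")


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with shrinking windows at the edges."""
    window = max(1, int(window))
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _mask_to_intervals(mask: np.ndarray, t: np.ndarray) -> list[tuple[float, float]]:
    if not mask.any():
        return []
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return [(float(t[i]), float(t[j - 1]) + float(t[1] - t[0])) for i, j in zip(starts, ends)]


def detect_flight_epochs(
    bp: np.ndarray,
    fs: float,
    threshold: float = FLIGHT_THRESHOLD,
    window_s: float = FLIGHT_WINDOW_S,
    min_epoch_s: float = 5.0,
    merge_gap_s: float = 1.0,
) -> list[FlightEpoch]:
    """Flight epochs: 50 s running mean of the rectified band-passed heave
    signal above 20 m/s^2.  Fragments from threshold flicker are merged
    (gaps < 1 s) and epochs shorter than ``min_epoch_s`` dropped — the
    long averaging window exists precisely to suppress few-wingbeat
    "flights"."""
    rect = np.abs(np.asarray(bp, dtype=float))
    m = running_mean(rect, int(round(window_s * fs)))
    t = np.arange(len(m)) / fs
    raw = _mask_to_intervals(m > threshold, t)
    merged: list[list[float]] = []
    for a, b in raw:
        if merged and a - merged[-1][1] < merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [FlightEpoch(a, b) for a, b in merged if b - a >= min_epoch_s]


def detect_landings(
    motion: MotionTrack,
    audio_env: np.ndarray,
    env_fs: float,
    coincidence_s: float = 0.05,
    quiet_s: float = 2.0,
    quiet_fraction: float = 0.25,
    refractory_s: float = 1.0,
) -> list[float]:
    """Landing times: jerk peak coincident (+-50 ms) with a broadband audio
    transient, followed by 2 s of flattened accelerometer.

    ``audio_env`` is a broadband audio envelope sampled at ``env_fs``.
    The flattening test compares the post-event standard deviation of the
    band-passed heave signal with the median flight-epoch level.
    """
    accel = motion.accel
    fs = motion.accel_fs
    jerk = compute_jerk(accel)
    tj = accel["t"].to_numpy()[:-1]

    def robust_peaks(x, rate, min_gap, mads):
        med = np.median(x)
        mad = np.median(np.abs(x - med)) + 1e-12
        peaks, _ = signal.find_peaks(x, height=med + mads * mad, distance=max(1, int(min_gap * rate)))
        return peaks

    jp = robust_peaks(jerk, fs, refractory_s, 6.0)
    ap = robust_peaks(np.asarray(audio_env, dtype=float), env_fs, refractory_s, 8.0)
    if len(jp) == 0 or len(ap) == 0:
        return []
    audio_t = ap / env_fs

    bp = bandpass_wingbeat(accel["az"].to_numpy(), fs)
    epochs = detect_flight_epochs(bp, 100.0)
    if epochs:
        flight_sds = []
        for e in epochs:
            seg = bp[int(e.start * 100) : int(e.end * 100)]
            if len(seg) > 10:
                flight_sds.append(np.std(seg))
        ref_sd = np.median(flight_sds) if flight_sds else np.std(bp)
    else:
        ref_sd = np.std(bp)

    landings = []
    for j in jp:
        tpk = tj[j]
        if not np.any(np.abs(audio_t - tpk) <= coincidence_s):
            continue
        q0, q1 = int((tpk + 0.05) * 100), int((tpk + 0.05 + quiet_s) * 100)
        seg = bp[q0:q1]
        if len(seg) < 10:
            continue
        if np.std(seg) < quiet_fraction * ref_sd:
            if not landings or tpk - landings[-1] > refractory_s:
                landings.append(float(tpk))
    return landings


def _lowpass3(x: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(4, 3.0, "lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def compute_heading(motion: MotionTrack) -> HeadingSeries:
    """Tilt-corrected compass heading from gimballed magnetometer data.

    Pitch and roll come from the gravity direction of the 3 Hz low-passed
    accelerometer (interpolated onto the magnetometer time base); the
    heading is the planar angle of the tilt-corrected horizontal field
    component, clockwise-positive from magnetic north.  Samples in
    near-free-fall (|a| < g/2) have undefined heading (NaN).
    """
    am, tm = motion.accel, motion.mag["t"].to_numpy()
    fs_a = motion.accel_fs
    fs_m = motion.mag_fs
    ta = am["t"].to_numpy()
    acc = np.column_stack([_lowpass3(am[c].to_numpy(), fs_a) for c in ("ax", "ay", "az")])
    acc_m = np.column_stack([np.interp(tm, ta, acc[:, k]) for k in range(3)])
    mag = np.column_stack([_lowpass3(motion.mag[c].to_numpy(), fs_m) for c in ("mx", "my", "mz")])

    norm = np.linalg.norm(acc_m, axis=1)
    bad = norm < 0.5 * GRAVITY
    norm_safe = np.where(norm > 1e-9, norm, 1.0)
    up = acc_m / norm_safe[:, None]  # at rest the accelerometer reads +g "up"
    down = -up

    pitch = np.arcsin(np.clip(up[:, 0], -1, 1))
    roll = np.arctan2(-up[:, 1], up[:, 2])

    # horizontal frame: e1 = forward axis projected to horizontal,
    # e2 = down x e1; heading = atan2(-m.e2, m.e1)
    xhat = np.zeros_like(up)
    xhat[:, 0] = 1.0
    proj = xhat - (np.sum(xhat * down, axis=1))[:, None] * down
    e1 = proj / np.maximum(np.linalg.norm(proj, axis=1), 1e-12)[:, None]
    e2 = np.cross(down, e1)
    heading = np.arctan2(-np.sum(mag * e2, axis=1), np.sum(mag * e1, axis=1))
    heading[bad] = np.nan
    pitch[bad] = np.nan
    roll[bad] = np.nan
    return HeadingSeries(t=tm, heading=heading, pitch=pitch, roll=roll)


def _circular_running_mean(h: np.ndarray, window: int) -> np.ndarray:
    return np.arctan2(running_mean(np.sin(h), window), running_mean(np.cos(h), window))


def heading_variation(h: HeadingSeries, fs: float, window_s: float = FLIGHT_WINDOW_S) -> np.ndarray:
    """Heading-variation signal: smoothed magnitude of the analytic signal
    of the circular residual about the 50 s running circular mean (rad)."""
    x = np.asarray(h.heading, dtype=float)
    valid = np.isfinite(x)
    if not valid.any():
        raise ValueError("heading is fully undefined")
    xi = x.copy()
    xi[~valid] = np.interp(np.flatnonzero(~valid), np.flatnonzero(valid), x[valid])
    w = int(round(window_s * fs))
    cm = _circular_running_mean(xi, w)
    resid = np.angle(np.exp(1j * (xi - cm)))
    env = np.abs(signal.hilbert(resid))
    return running_mean(env, w)


def detect_foraging_bouts(
    h: HeadingSeries,
    fs: float,
    threshold: float = BOUT_THRESHOLD,
    escalated_threshold: float = BOUT_THRESHOLD_ESCALATED,
    max_switches: int = MAX_MODE_SWITCHES,
    window_s: float = FLIGHT_WINDOW_S,
    epochs: list[FlightEpoch] | None = None,
) -> list[ForagingBout]:
    """Foraging bouts: intervals where the heading-variation envelope
    exceeds the threshold.  If the segmentation produces more than
    ``max_switches`` foraging/commuting transitions, the threshold is
    raised to 0.3 and the segmentation recomputed.
    """
    env = heading_variation(h, fs, window_s)
    t = np.asarray(h.t, dtype=float)

    def segment(thr):
        mask = env > thr
        if epochs is not None:
            in_flight = np.zeros_like(mask)
            for e in epochs:
                in_flight |= (t >= e.start) & (t < e.end)
            mask &= in_flight
        switches = int(np.sum(np.abs(np.diff(mask.astype(np.int8)))))
        return mask, switches

    mask, switches = segment(threshold)
    if switches > max_switches:
        mask, switches = segment(escalated_threshold)
    return [ForagingBout(a, b, "foraging") for a, b in _mask_to_intervals(mask, t)]


def filter_bouts(bouts: list[ForagingBout], attack_times: np.ndarray) -> list[ForagingBout]:
    """Keep bouts containing at least one attack (half-open [start, end))
    and populate their attack counts."""
    attack_times = np.asarray(attack_times, dtype=float)
    kept = []
    for b in bouts:
        n = int(np.sum((attack_times >= b.start) & (attack_times < b.end)))
        if n >= 1:
            kept.append(ForagingBout(b.start, b.end, b.mode, n_attacks=n))
    return kept
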