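"""Seeded synthetic tag data with ground truth.

Emulates an animal-borne sound-and-movement tag on a foraging bat:

- ultrasonic audio with echolocation call trains (search / approach / buzz
  inter-call-interval structure), post-capture mastication transients near
  7 kHz, broadband landing transients, and Gaussian sensor noise;
- triaxial accelerometer with gravity, wingbeat oscillation on the heave
  axis, landing spikes on sway+heave and post-landing flattening;
- triaxial magnetometer encoding a heading trajectory (stable during
  commuting, random-walking during foraging bouts);
- GPS tracks alternating near-straight commuting with area-restricted
  search confined to a patch.

Every generated event is recorded in a truth log so downstream detectors
can be scored against known ground truth.  Identical seed + config gives
bit-identical output.

Axis and orientation conventions
--------------------------------
Body axes are x = surge (forward), y = sway (left), z = heave (up); a tag
at rest reads ``(0, 0, +g)`` on the accelerometer.  Compass heading is
clockwise-positive from magnetic north.  The synthetic magnetic field has
unit magnitude with 60 deg inclination (down-positive), representative of
the mid-latitude study region.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from batforage import geo

GRAVITY = 9.81
ACCEL_CLIP = 78.5  # 8 g clip level, m/s^2
FIELD_INCLINATION_RAD = np.radians(60.0)

__all__ = [
    "CallParams",
    "ChewParams",
    "WingbeatParams",
    "MovementParams",
    "NoiseParams",
    "AttackSpec",
    "SynthConfig",
    "TagRecording",
    "TruthLog",
    "generate_scene",
    "generate_track",
    "make_schedule",
    "write_fixture",
    "read_fixture",
]


@dataclass
class CallParams:
    """Echolocation call synthesis parameters.

    Calls are linear downward FM sweeps; the sweep top is capped below the
    audio Nyquist at generation time.  Inter-call intervals (ICI): 80 ms in
    search phase, ramping 30 -> 10 ms in approach, and a terminal buzz of
    ``n_buzz_intervals`` intervals at ``buzz_ici_ms`` (< 8 ms, so a buzz
    detector requiring more than six consecutive short intervals fires).
    """

    sweep_start_hz: float = 100_000.0
    sweep_end_hz: float = 25_000.0
    duration_ms: float = 2.0
    amplitude: float = 0.4
    search_ici_ms: float = 80.0
    approach_ici_start_ms: float = 30.0
    approach_ici_end_ms: float = 10.0
    n_approach_intervals: int = 12
    buzz_ici_ms: float = 6.0
    n_buzz_intervals: int = 10
    quiet_amplitude_scale: float = 0.05  # pre-gleaning passive-listening calls


@dataclass
class ChewParams:
    """Mastication transient parameters.

    Chews are exponentially damped sinusoids at ~7 kHz placed midway
    between consecutive post-capture echolocation calls.  Per-capture chew
    counts are lognormal with medians 75 (ground prey) and 23 (aerial
    prey); the log-sigmas reproduce the observed interquartile spread.
    """

    peak_hz: float = 7000.0
    duration_ms: float = 8.0
    decay_ms: float = 2.0
    amplitude: float = 0.6
    count_median: dict = field(default_factory=lambda: {"ground": 75.0, "aerial": 23.0})
    count_sigma: dict = field(default_factory=lambda: {"ground": 0.79, "aerial": 0.96})


@dataclass
class WingbeatParams:
    """Wingbeat oscillation on the heave axis during flight.

    10 Hz at 35 m/s^2 gives a rectified band-passed running mean of
    2*35/pi ~ 22 m/s^2, above the 20 m/s^2 flight threshold.
    """

    freq_hz: float = 10.0
    amplitude: float = 35.0


@dataclass
class MovementParams:
    cruise_speed: float = 8.0  # m/s, commuting
    ars_speed: float = 3.0  # m/s inside a search patch
    commute_heading_noise: float = 0.01  # rad, white jitter per sample
    foraging_heading_sigma: float = 0.05  # rad/sample random walk (50 Hz)
    ars_turn_sigma: float = 0.6  # rad/s heading walk inside patch
    patch_radius_m: float = 100.0
    gps_noise_sigma: float = 5.0  # m


@dataclass
class NoiseParams:
    audio_snr_db: float = 38.0  # call amplitude over noise sigma
    accel_noise: float = 0.3  # m/s^2
    mag_noise: float = 0.005  # unit-field


@dataclass
class AttackSpec:
    time: float
    strategy: str  # 'glean' | 'hawk'
    success: bool | None = None  # None -> drawn from p_success


@dataclass
class SynthConfig:
    seed: int = 0
    duration: float = 120.0
    audio_fs: float = 187_500.0
    accel_fs: float = 100.0
    mag_fs: float = 50.0
    gps_dt: float = 15.0
    duty_cycle: float = 1.0
    call_params: CallParams = field(default_factory=CallParams)
    chew_params: ChewParams = field(default_factory=ChewParams)
    wingbeat_params: WingbeatParams = field(default_factory=WingbeatParams)
    movement_params: MovementParams = field(default_factory=MovementParams)
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    schedule: list = field(default_factory=list)  # list[AttackSpec]
    # nightly capture-success probability per strategy (field means)
    p_success: dict = field(default_factory=lambda: {"glean": 0.30, "hawk": 0.76})
    # foraging bouts (heading random walk); None -> middle third if attacks
    bouts: list | None = None
    # GPS phase plan for generate_track: list of (kind, duration_s),
    # kind in {'commute', 'ars'}; None -> commute / ars / commute thirds
    track_phases: list | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = [dataclasses.asdict(a) for a in self.schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["call_params"] = CallParams(**d.get("call_params", {}))
        d["chew_params"] = ChewParams(**d.get("chew_params", {}))
        d["wingbeat_params"] = WingbeatParams(**d.get("wingbeat_params", {}))
        d["movement_params"] = MovementParams(**d.get("movement_params", {}))
        d["noise_params"] = NoiseParams(**d.get("noise_params", {}))
        d["schedule"] = [AttackSpec(**a) for a in d.get("schedule", [])]
        if d.get("bouts") is not None:
            d["bouts"] = [tuple(b) for b in d["bouts"]]
        if d.get("track_phases") is not None:
            d["track_phases"] = [tuple(p) for p in d["track_phases"]]
        return cls(**d)


@dataclass
class TagRecording:
    audio: np.ndarray  # float, [-1, 1]
    audio_fs: float
    accel: pd.DataFrame  # t, ax, ay, az (m/s^2)
    mag: pd.DataFrame  # t, mx, my, mz (unit field)
    gps: pd.DataFrame | None = None  # t, lat, lon
    duty_cycle: float = 1.0
    config: SynthConfig | None = None


@dataclass
class TruthLog:
    """Ground-truth event log: one row per generated event.

    Columns: t (s), kind in {call, buzz, attack, chew, landing, bout_start,
    bout_end, segment_change}, strategy, success, prey_class.
    """

    events: pd.DataFrame

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind].reset_index(drop=True)


def make_schedule(
    n_glean: int,
    n_hawk: int,
    duration: float,
    rng: np.random.Generator,
    p_success: dict | None = None,
    spacing: float | None = None,
) -> list[AttackSpec]:
    """Evenly interleave glean/hawk attacks over ``duration`` and draw
    success flags from the per-strategy capture probabilities."""
    p = p_success or {"glean": 0.30, "hawk": 0.76}
    n = n_glean + n_hawk
    if n == 0:
        return []
    strategies = ["glean"] * n_glean + ["hawk"] * n_hawk
    rng.shuffle(strategies)
    t0, t1 = 5.0, duration - 5.0
    if spacing is not None:
        times = t0 + spacing * np.arange(n)
        if times[-1] > t1:
            raise ValueError("schedule does not fit in duration at requested spacing")
    else:
        times = np.linspace(t0, t1, n)
    return [
        AttackSpec(float(t), s, bool(rng.random() < p[s]))
        for t, s in zip(times, strategies)
    ]


# ---------------------------------------------------------------------------
# scene generation


def _validate_schedule(cfg: SynthConfig) -> list[AttackSpec]:
    sched = sorted(cfg.schedule, key=lambda a: a.time)
    for a in sched:
        if a.strategy not in ("glean", "hawk"):
            raise ValueError(f"unknown strategy {a.strategy!r}")
        if not (0.0 < a.time < cfg.duration):
            raise ValueError(
                f"attack at t={a.time:g} s lies outside the recording (duration {cfg.duration:g} s)"
            )
    for a, b in zip(sched, sched[1:]):
        if b.time - a.time < 2.0:
            raise ValueError(
                f"attacks at {a.time:g} and {b.time:g} s are closer than 2 s; scene cannot fit the call-train structure"
            )
    return sched


def _call_waveform(fs: float, p: CallParams) -> np.ndarray:
    n = max(8, int(round(p.duration_ms * 1e-3 * fs)))
    t = np.arange(n) / fs
    f0 = min(p.sweep_start_hz, 0.45 * fs)
    f1 = min(p.sweep_end_hz, 0.4 * fs)
    sweep = (f1 - f0) / t[-1]
    phase = 2 * np.pi * (f0 * t + 0.5 * sweep * t**2)
    return np.sin(phase) * np.hanning(n)


def _chew_waveform(fs: float, p: ChewParams) -> np.ndarray:
    n = max(8, int(round(p.duration_ms * 1e-3 * fs)))
    t = np.arange(n) / fs
    w = np.exp(-t / (p.decay_ms * 1e-3)) * np.sin(2 * np.pi * p.peak_hz * t)
    # soften onset/offset to limit spectral splatter
    edge = max(2, n // 16)
    env = np.ones(n)
    env[:edge] = np.linspace(0, 1, edge)
    env[-edge:] = np.linspace(1, 0, edge)
    return w * env


def _landing_click(fs: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(0.005 * fs))
    return rng.standard_normal(n) * np.hanning(n)


def _build_call_plan(cfg: SynthConfig, sched: list[AttackSpec]):
    """Lay out call times over the scene.

    Returns (call_times, call_amp_scale, buzz_truth, rest_windows) where
    rest_windows are the post-landing intervals without flight.
    """
    p = cfg.call_params
    search_ici = p.search_ici_ms * 1e-3
    approach = np.linspace(p.approach_ici_start_ms, p.approach_ici_end_ms, p.n_approach_intervals) * 1e-3
    buzz_icis = np.full(p.n_buzz_intervals, p.buzz_ici_ms * 1e-3)
    hawk_zone = float(approach.sum() + buzz_icis.sum())

    quiet_pre = 2.0  # passive-listening window before a gleaning attack
    rest_after = 2.5  # on-ground handling before take-off

    # zones that replace or silence the base search-call grid
    blocked = []  # (t0, t1)
    for a in sched:
        if a.strategy == "hawk":
            blocked.append((a.time - hawk_zone - 0.02, a.time + 0.1))
        else:
            blocked.append((a.time, a.time + rest_after))

    def in_blocked(t):
        return any(t0 <= t < t1 for t0, t1 in blocked)

    times, scales = [], []
    t = 0.2
    while t < cfg.duration - 0.01:
        if not in_blocked(t):
            scale = 1.0
            for a in sched:
                if a.strategy == "glean" and a.time - quiet_pre <= t < a.time:
                    scale = p.quiet_amplitude_scale
                    break
            times.append(t)
            scales.append(scale)
        t += search_ici

    buzz_truth = []
    for a in sched:
        if a.strategy != "hawk":
            continue
        seq = [a.time - hawk_zone]
        for ici in np.concatenate([approach, buzz_icis]):
            seq.append(seq[-1] + ici)
        seq = [s for s in seq if 0 < s < cfg.duration]
        times.extend(seq)
        scales.extend([1.0] * len(seq))
        buzz_truth.append(a.time - float(buzz_icis.sum()))

    order = np.argsort(times)
    call_times = np.asarray(times, dtype=float)[order]
    call_scales = np.asarray(scales, dtype=float)[order]
    rest_windows = [(a.time, a.time + rest_after) for a in sched if a.strategy == "glean"]
    return call_times, call_scales, buzz_truth, rest_windows


def generate_scene(cfg: SynthConfig) -> tuple[TagRecording, TruthLog]:
    """Generate a synthetic tag scene (audio + motion) with truth log.

    Raises ``ValueError`` for an inconsistent schedule (attack outside the
    recording, or attacks too close to carry the call-train structure).
    """
    if cfg.duration < 10:
        raise ValueError("duration must be >= 10 s")
    if min(cfg.audio_fs, cfg.accel_fs, cfg.mag_fs) <= 0:
        raise ValueError("sample rates must be positive")
    sched = _validate_schedule(cfg)
    rng = np.random.default_rng(cfg.seed)

    call_times, call_scales, buzz_truth, rest_windows = _build_call_plan(cfg, sched)

    # -------------------- audio --------------------
    fs = cfg.audio_fs
    n_audio = int(round(cfg.duration * fs))
    sigma = cfg.call_params.amplitude / 10 ** (cfg.noise_params.audio_snr_db / 20)
    audio = rng.normal(0.0, sigma, n_audio)

    call_wf = _call_waveform(fs, cfg.call_params)
    amp = cfg.call_params.amplitude
    for t, s in zip(call_times, call_scales):
        i = int(round(t * fs))
        j = min(i + len(call_wf), n_audio)
        if i < n_audio:
            audio[i:j] += amp * s * call_wf[: j - i]

    # chew trains after successful attacks, midway between post-capture calls
    chew_wf = _chew_waveform(fs, cfg.chew_params)
    chew_rows = []
    for k, a in enumerate(sched):
        success = a.success
        if success is None:
            success = bool(rng.random() < cfg.p_success[a.strategy])
            a.success = success
        if not success:
            continue
        prey = "ground" if a.strategy == "glean" else "aerial"
        med = cfg.chew_params.count_median[prey]
        sig = cfg.chew_params.count_sigma[prey]
        count = max(1, int(round(rng.lognormal(np.log(med), sig))))
        t_next = sched[k + 1].time if k + 1 < len(sched) else cfg.duration
        window_end = min(t_next - 0.3, a.time + 100.0, cfg.duration - 0.05)
        resume = a.time + (2.6 if a.strategy == "glean" else 0.1)
        idx = np.searchsorted(call_times, resume)
        placed = 0
        while placed < count and idx + 1 < len(call_times):
            c0, c1 = call_times[idx], call_times[idx + 1]
            if c1 > window_end:
                break
            if c1 - c0 > 0.03:  # only proper inter-call gaps
                tc = 0.5 * (c0 + c1)
                i = int(round(tc * fs))
                j = min(i + len(chew_wf), n_audio)
                if i < n_audio:
                    audio[i:j] += cfg.chew_params.amplitude * chew_wf[: j - i]
                chew_rows.append((tc, a.strategy, prey))
                placed += 1
            idx += 1

    # landing transients for gleaning attacks
    for a in sched:
        if a.strategy == "glean":
            click = _landing_click(fs, rng)
            i = int(round(a.time * fs))
            j = min(i + len(click), n_audio)
            audio[i:j] += 0.5 * click[: j - i]

    np.clip(audio, -1.0, 1.0, out=audio)

    # -------------------- accelerometer --------------------
    afs = cfg.accel_fs
    n_acc = int(round(cfg.duration * afs))
    ta = np.arange(n_acc) / afs
    noise = cfg.noise_params.accel_noise
    ax = rng.normal(0.0, noise, n_acc)
    ay = rng.normal(0.0, noise, n_acc)
    az = GRAVITY + rng.normal(0.0, noise, n_acc)
    wing = cfg.wingbeat_params.amplitude * np.sin(2 * np.pi * cfg.wingbeat_params.freq_hz * ta)
    flying = np.ones(n_acc, dtype=bool)
    for t0, t1 in rest_windows:
        flying[(ta >= t0) & (ta < t1)] = False
    az += np.where(flying, wing, 0.0)

    for a in sched:
        if a.strategy != "glean":
            continue
        # sharp sway/heave impact spike (opposite signs) at ground contact
        n_sp = max(2, int(round(0.01 * afs)))
        i = int(round(a.time * afs))
        j = min(i + n_sp, n_acc)
        spike = 45.0 * np.sin(np.pi * np.arange(j - i) / n_sp)
        ay[i:j] += spike
        az[i:j] -= spike

    np.clip(ax, -ACCEL_CLIP, ACCEL_CLIP, out=ax)
    np.clip(ay, -ACCEL_CLIP, ACCEL_CLIP, out=ay)
    np.clip(az, -ACCEL_CLIP, ACCEL_CLIP, out=az)
    accel = pd.DataFrame({"t": ta, "ax": ax, "ay": ay, "az": az})

    # -------------------- magnetometer / heading --------------------
    mfs = cfg.mag_fs
    n_mag = int(round(cfg.duration * mfs))
    tm = np.arange(n_mag) / mfs
    bouts = cfg.bouts
    if bouts is None:
        bouts = [(cfg.duration / 3, 2 * cfg.duration / 3)] if sched else []
    heading = np.full(n_mag, 0.3)
    heading += rng.normal(0.0, cfg.movement_params.commute_heading_noise, n_mag)
    for b0, b1 in bouts:
        m = (tm >= b0) & (tm < b1)
        nb = int(m.sum())
        if nb < 2:
            continue
        # Brownian bridge: tortuous search flight that rejoins the commute
        # heading continuously at both bout boundaries
        walk = np.cumsum(rng.normal(0.0, cfg.movement_params.foraging_heading_sigma, nb))
        walk -= np.linspace(0.0, walk[-1], nb)
        heading[m] += walk
    heading = np.angle(np.exp(1j * heading))

    f_n, f_d = np.cos(FIELD_INCLINATION_RAD), np.sin(FIELD_INCLINATION_RAD)
    mgn = cfg.noise_params.mag_noise
    mag = pd.DataFrame(
        {
            "t": tm,
            "mx": f_n * np.cos(heading) + rng.normal(0, mgn, n_mag),
            "my": f_n * np.sin(heading) + rng.normal(0, mgn, n_mag),
            "mz": -f_d + rng.normal(0, mgn, n_mag),
        }
    )

    # -------------------- truth log --------------------
    rows = []
    for t, s in zip(call_times, call_scales):
        rows.append((t, "call", "", None, ""))
    for t in buzz_truth:
        rows.append((t, "buzz", "hawk", None, "aerial"))
    for a in sched:
        prey = "ground" if a.strategy == "glean" else "aerial"
        rows.append((a.time, "attack", a.strategy, bool(a.success), prey))
        if a.strategy == "glean":
            rows.append((a.time, "landing", "glean", None, "ground"))
    for tc, strat, prey in chew_rows:
        rows.append((tc, "chew", strat, None, prey))
    for b0, b1 in bouts:
        rows.append((b0, "bout_start", "", None, ""))
        rows.append((min(b1, cfg.duration), "bout_end", "", None, ""))
    truth = pd.DataFrame(rows, columns=["t", "kind", "strategy", "success", "prey_class"])
    truth = truth.sort_values(["t", "kind"], kind="mergesort").reset_index(drop=True)

    rec = TagRecording(audio=audio, audio_fs=fs, accel=accel, mag=mag, duty_cycle=cfg.duty_cycle, config=cfg)
    return rec, TruthLog(truth)


# ---------------------------------------------------------------------------
# GPS track generation


def generate_track(cfg: SynthConfig) -> tuple[pd.DataFrame, TruthLog]:
    """Generate a GPS fix table (t, lat, lon) alternating commuting and
    area-restricted search, plus a truth log of segment boundaries.

    Commuting is a near-straight correlated walk at cruise speed; ARS
    confines a slower, tortuous walk within the configured patch radius.
    """
    mp = cfg.movement_params
    if mp.patch_radius_m <= 0:
        raise ValueError("patch radius must be > 0")
    if cfg.duration < 10 * cfg.gps_dt:
        raise ValueError("duration must be >= 10 GPS intervals")
    rng = np.random.default_rng(cfg.seed + 1)

    phases = cfg.track_phases
    if phases is None:
        # commute to the grounds, then ~5 min search patches separated by
        # shorter commutes (bout durations of a few minutes, as observed)
        if cfg.duration >= 900:
            phases = [("commute", 300.0)]
            t_acc = 300.0
            while t_acc < cfg.duration:
                d = min(300.0, cfg.duration - t_acc)
                phases.append(("ars", d))
                t_acc += d
                if t_acc < cfg.duration:
                    d = min(200.0, cfg.duration - t_acc)
                    phases.append(("commute", d))
                    t_acc += d
        else:
            third = cfg.duration / 3
            phases = [("commute", third), ("ars", third), ("commute", third)]

    dt = 1.0  # integrate at 1 Hz, then sample fixes at gps_dt
    pos = np.zeros(2)
    heading = rng.uniform(-np.pi, np.pi)
    xs, ys, ts, seg_changes = [], [], [], []
    t = 0.0
    for kind, dur in phases:
        if kind not in ("commute", "ars"):
            raise ValueError(f"unknown phase kind {kind!r}")
        if ts:
            seg_changes.append((t, kind))
        n = int(round(dur / dt))
        if kind == "commute":
            center = None
        else:
            center = pos.copy()
        for _ in range(n):
            if kind == "commute":
                heading += rng.normal(0, 0.01)
                speed = mp.cruise_speed
            else:
                heading += rng.normal(0, mp.ars_turn_sigma)
                speed = mp.ars_speed
            step = np.array([np.sin(heading), np.cos(heading)]) * speed * dt
            new = pos + step
            if center is not None:
                r = np.linalg.norm(new - center)
                if r > mp.patch_radius_m:
                    # fold back inside the patch and turn toward its center
                    new = center + (new - center) * (2 * mp.patch_radius_m / r - 1)
                    back = center - new
                    heading = np.arctan2(back[0], back[1]) + rng.normal(0, 0.3)
            pos = new
            ts.append(t)
            xs.append(pos[0])
            ys.append(pos[1])
            t += dt

    ts = np.asarray(ts)
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    keep = np.arange(0, len(ts), int(round(cfg.gps_dt / dt)))
    tsf, xf, yf = ts[keep], xs[keep], ys[keep]
    xf = xf + rng.normal(0, mp.gps_noise_sigma, len(keep))
    yf = yf + rng.normal(0, mp.gps_noise_sigma, len(keep))

    lat0, lon0 = 43.622, 25.865  # NE Bulgaria study region
    lat, lon = geo.unproject(xf, yf, lat0, lon0)
    gps = pd.DataFrame({"t": tsf, "lat": lat, "lon": lon})

    rows = [(0.0, "segment_change", phases[0][0], None, "")]
    rows += [(tc, "segment_change", kind, None, "") for tc, kind in seg_changes]
    truth = TruthLog(pd.DataFrame(rows, columns=["t", "kind", "strategy", "success", "prey_class"]))
    return gps, truth


# ---------------------------------------------------------------------------
# fixture I/O


def _duty_blocks(duration: float, duty: float, block: float = 30.0):
    """On/off recording blocks for duty-cycled tags (30 s on / 30 s off)."""
    if duty == 1.0:
        return [(0.0, duration, True)]
    blocks = []
    t = 0.0
    on = True
    while t < duration:
        blocks.append((t, min(t + block, duration), on))
        t += block
        on = not on
    return blocks


def write_fixture(rec: TagRecording, log: TruthLog, out_dir: str | Path) -> dict:
    """Write a scene to disk: WAV audio, CSV sensor tables, events CSV and
    a JSON config echo.  For duty-cycled tags the off-blocks are blanked
    (audio) or dropped (sensor rows, events) and flagged in coverage.csv.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = _duty_blocks(len(rec.audio) / rec.audio_fs, rec.duty_cycle)

    audio = rec.audio
    accel, mag, events = rec.accel, rec.mag, log.events
    if rec.duty_cycle != 1.0:
        audio = audio.copy()
        keep_a = np.zeros(len(accel), dtype=bool)
        keep_m = np.zeros(len(mag), dtype=bool)
        keep_e = np.zeros(len(events), dtype=bool)
        for t0, t1, on in blocks:
            if on:
                keep_a |= (accel["t"] >= t0) & (accel["t"] < t1)
                keep_m |= (mag["t"] >= t0) & (mag["t"] < t1)
                keep_e |= (events["t"] >= t0) & (events["t"] < t1)
            else:
                i0, i1 = int(t0 * rec.audio_fs), int(t1 * rec.audio_fs)
                audio[i0:i1] = 0.0
        accel, mag, events = accel[keep_a], mag[keep_m], events[keep_e]

    pcm = np.clip(np.round(audio * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(out / "audio.wav", int(rec.audio_fs), pcm)
    accel.to_csv(out / "accel.csv", index=False)
    mag.to_csv(out / "mag.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    if rec.gps is not None:
        rec.gps.to_csv(out / "gps.csv", index=False)
    pd.DataFrame(blocks, columns=["start", "end", "on"]).to_csv(out / "coverage.csv", index=False)
    cfg = rec.config.to_dict() if rec.config is not None else {}
    cfg["audio_fs"] = rec.audio_fs
    cfg["duty_cycle"] = rec.duty_cycle
    (out / "config.json").write_text(json.dumps(cfg, indent=1, default=float))
    return {
        "audio": out / "audio.wav",
        "accel": out / "accel.csv",
        "mag": out / "mag.csv",
        "events": out / "events.csv",
        "config": out / "config.json",
    }


def read_fixture(in_dir: str | Path) -> tuple[TagRecording, TruthLog]:
    """Read a fixture written by :func:`write_fixture`."""
    p = Path(in_dir)
    fs, pcm = wavfile.read(p / "audio.wav")
    audio = pcm.astype(np.float64) / 32767.0
    accel = pd.read_csv(p / "accel.csv")
    mag = pd.read_csv(p / "mag.csv")
    gps = pd.read_csv(p / "gps.csv") if (p / "gps.csv").exists() else None
    cfg = json.loads((p / "config.json").read_text())
    events = pd.read_csv(p / "events.csv")
    events["strategy"] = events["strategy"].fillna("")
    events["prey_class"] = events["prey_class"].fillna("")
    rec = TagRecording(
        audio=audio,
        audio_fs=float(fs),
        accel=accel,
        mag=mag,
        gps=gps,
        duty_cycle=float(cfg.get("duty_cycle", 1.0)),
    )
    return rec, TruthLog(events)
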