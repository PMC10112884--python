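"""End-to-end orchestration: fixture -> events -> night summary.

Runs motion (flight epochs, landings, heading bouts), acoustics (calls,
buzzes, mastication, success classification), GPS segmentation when a
track is present, duty-cycle correction for 50% duty tags, and the energy
model, producing one NightSummary per recording.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from batforage import acoustics, energetics, motion, trackseg
from batforage.acoustics import AttackEvent
from batforage.synth import read_fixture

__all__ = ["NightSummary", "duty_cycle_correct", "summarize_night", "run_pipeline"]


@dataclass
class NightSummary:
    bat_id: str = "synthetic"
    night: str = "0"
    attacks: dict = field(default_factory=dict)  # strategy -> count
    successes: dict = field(default_factory=dict)
    success_ratio: dict = field(default_factory=dict)  # NaN where attacks <= min threshold
    median_time_between_attacks: dict = field(default_factory=dict)
    median_handling_time: dict = field(default_factory=dict)
    n_bouts: int = 0
    intake_kj: tuple = (np.nan, np.nan)  # (lower, higher) aerial-mass estimate
    assimilated_kj: tuple = (np.nan, np.nan)  # (intake_low*0.50, intake_high*0.82)
    profitability_j_s: dict = field(default_factory=dict)  # strategy -> (lower, higher)
    dominant_strategy_ratio: float = np.nan  # gleaning attacks / total attacks

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def duty_cycle_correct(counts: dict, duty: float) -> dict:
    """Scale event counts for duty-cycled recording (e.g. x2 at 50% duty)."""
    if duty not in (1.0, 0.5):
        raise ValueError(f"unsupported duty cycle {duty!r}; expected 1.0 or 0.5")
    return {k: v / duty for k, v in counts.items()}


def summarize_night(
    attacks: list[AttackEvent],
    chew_trains: list,
    bouts: list,
    cfg: energetics.EnergyConfig | None = None,
    duty: float = 1.0,
    min_attacks_for_ratio: int = 1,
    bat_id: str = "synthetic",
) -> NightSummary:
    """Aggregate per-strategy attack statistics, energy and profitability.

    Success ratios are reported only for strategies with more than
    ``min_attacks_for_ratio`` attacks.  Counts are duty-cycle corrected
    before energy arithmetic.
    """
    cfg = cfg or energetics.EnergyConfig()
    s = NightSummary(bat_id=bat_id)
    strategies = ("glean", "hawk")
    handling_by = {st: [] for st in strategies}
    for ct in chew_trains:
        st = _strategy_of_train(ct, attacks)
        if st:
            handling_by[st].append(ct.handling_time)

    for st in strategies:
        ev = sorted([a for a in attacks if a.strategy == st], key=lambda a: a.time)
        n = len(ev)
        k = sum(1 for a in ev if a.success)
        s.attacks[st] = n
        s.successes[st] = k
        s.success_ratio[st] = (k / n) if n > min_attacks_for_ratio else np.nan
        iai = np.diff([a.time for a in ev])
        s.median_time_between_attacks[st] = float(np.median(iai)) if len(iai) else np.nan
        s.median_handling_time[st] = float(np.median(handling_by[st])) if handling_by[st] else np.nan

    s.n_bouts = len(bouts)
    total = s.attacks["glean"] + s.attacks["hawk"]
    s.dominant_strategy_ratio = s.attacks["glean"] / total if total else np.nan

    corrected = duty_cycle_correct({"glean": s.successes["glean"], "hawk": s.successes["hawk"]}, duty)
    lo, hi = energetics.nightly_intake(corrected, cfg)
    s.intake_kj = (lo, hi)
    s.assimilated_kj = (
        energetics.assimilated_energy(lo, cfg.assimilation[0]),
        energetics.assimilated_energy(hi, cfg.assimilation[1]),
    )

    ground_j = energetics.caloric_value(cfg.ground_mass_mg, "ground", cfg)
    aerial_j = {e: energetics.caloric_value(cfg.aerial_mass_mg[e], "aerial", cfg) for e in ("lower", "higher")}
    for st in strategies:
        ratio = s.success_ratio[st]
        handling = s.median_handling_time[st]
        between = s.median_time_between_attacks[st]
        if np.isnan(ratio) or np.isnan(between):
            s.profitability_j_s[st] = (np.nan, np.nan)
            continue
        h = 0.0 if np.isnan(handling) else handling
        if st == "glean":
            cal = {"lower": ground_j, "higher": ground_j}
        else:
            cal = aerial_j
        s.profitability_j_s[st] = tuple(
            energetics.profitability(
                energetics.ProfitabilityInputs(cal[e], h, between, ratio)
            )
            for e in ("lower", "higher")
        )
    return s


def _strategy_of_train(train, attacks: list[AttackEvent]) -> str | None:
    for a in attacks:
        if abs(a.time - train.attack_time) < 1e-6:
            return a.strategy
    return None


def broadband_envelope(audio: np.ndarray, fs: float, out_fs: float = 1000.0) -> np.ndarray:
    """Broadband audio envelope decimated to ``out_fs`` for landing checks."""
    n = len(audio)
    step = max(1, int(round(fs / out_fs)))
    trimmed = audio[: (n // step) * step]
    return np.abs(trimmed.astype(np.float32)).reshape(-1, step).max(axis=1)


def run_pipeline(fixture_dir: str | Path, out_dir: str | Path, cfg: energetics.EnergyConfig | None = None) -> dict:
    """Run all stages on a fixture directory and write a report.

    Stages: motion -> acoustics -> trackseg (if gps.csv present) ->
    energetics -> summary.  Attack times and strategies come from the
    events file (the field workflow's annotations); success is classified
    automatically from mastication sounds.
    """
    fixture_dir = Path(fixture_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def logmsg(msg):
        log.append(msg)

    t_start = time.time()
    rec, truth = read_fixture(fixture_dir)
    logmsg(f"loaded fixture {fixture_dir} (audio {len(rec.audio)/rec.audio_fs:.1f} s @ {rec.audio_fs:g} Hz)")

    stage = "motion"
    try:
        mt = motion.MotionTrack(accel=rec.accel, mag=rec.mag)
        bp = motion.bandpass_wingbeat(rec.accel["az"].to_numpy(), mt.accel_fs)
        epochs = motion.detect_flight_epochs(bp, 100.0)
        env = broadband_envelope(rec.audio, rec.audio_fs)
        landings = motion.detect_landings(mt, env, 1000.0)
        heading = motion.compute_heading(mt)
        bouts = motion.detect_foraging_bouts(heading, mt.mag_fs, epochs=epochs)
        logmsg(f"motion: {len(epochs)} flight epochs, {len(landings)} landings, {len(bouts)} heading bouts")

        stage = "acoustics"
        calls = acoustics.detect_calls(rec.audio, rec.audio_fs)
        buzzes = acoustics.detect_buzzes(calls)
        buzzes = acoustics.exclude_landing_buzzes(buzzes, landings, epochs)
        ev = truth.events if hasattr(truth, "events") else truth
        att = ev[ev["kind"] == "attack"]
        attacks = [AttackEvent(float(r.t), str(r.strategy), source="annotation") for r in att.itertuples()]
        attacks, trains = acoustics.analyze_attacks(rec.audio, rec.audio_fs, calls, attacks)
        bouts = motion.filter_bouts(bouts, np.array([a.time for a in attacks]))
        logmsg(f"acoustics: {len(calls)} calls, {len(buzzes)} flight buzzes, {len(attacks)} attacks analyzed")

        stage = "trackseg"
        track_report = None
        if rec.gps is not None:
            tracks = trackseg.regularize_track(rec.gps)
            track = max(tracks, key=len)
            profile = trackseg.fpt_variance_profile(track)
            d = trackseg.step_distances(track)
            seg = trackseg.lavielle_segment(d)
            try:
                thr, _ = trackseg.ars_threshold(d)
            except ValueError:
                thr = float(np.median(d))
                logmsg("trackseg: mixture threshold degenerate; fell back to median step distance")
            seg_table = trackseg.classify_track(track, seg, thr)
            seg_table.to_csv(out / "segments.csv", index=False)
            pd.DataFrame({"radius_m": profile.radii, "var_log_fpt": profile.var_log_fpt}).to_csv(
                out / "fpt_profile.csv", index=False
            )
            track_report = {"operating_scale_m": profile.operating_scale, "K": seg.K, "threshold_m": thr}
            logmsg(f"trackseg: scale {profile.operating_scale:g} m, K={seg.K}, threshold {thr:.1f} m/step")
        else:
            logmsg("trackseg: skipped (no GPS in fixture)")

        stage = "energetics/summary"
        summary = summarize_night(attacks, trains, bouts, cfg, duty=rec.duty_cycle)
    except Exception as err:  # pragma: no cover - error path
        (out / "pipeline.log").write_text("\n".join(log + [f"FAILED at stage {stage}: {err}"]))
        raise RuntimeError(f"pipeline failed at stage {stage}: {err}") from err

    pd.DataFrame(
        [
            {"t": a.time, "strategy": a.strategy, "success": a.success, "source": a.source}
            for a in attacks
        ]
    ).to_csv(out / "events.csv", index=False)
    pd.DataFrame(
        [
            {
                "attack_t": tr.attack_time,
                "count": tr.count,
                "onset": tr.onset,
                "duration": tr.duration,
                "handling_time": tr.handling_time,
            }
            for tr in trains
        ]
    ).to_csv(out / "chews.csv", index=False)
    report = {
        "summary": _jsonable(summary.to_dict()),
        "trackseg": track_report,
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    logmsg(f"done in {report['elapsed_s']} s")
    (out / "pipeline.log").write_text("\n".join(log))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
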