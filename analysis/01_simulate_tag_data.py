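"""Generate the synthetic tag night used by the rest of the analysis.

Writes a fixture (WAV audio, accelerometer/magnetometer/GPS CSVs, truth
events, config echo) for one 420 s sound-and-movement scene with five
gleaning and five hawking attacks, plus a 30 min GPS track alternating
commuting with 100 m area-restricted-search patches.

Run:  python analysis/01_simulate_tag_data.py
Output: results/fixture/
"""

from pathlib import Path

import numpy as np

from batforage import synth

OUT = Path("results/fixture")
SEED = 3


def main():
    rng = np.random.default_rng(SEED)
    cfg = synth.SynthConfig(seed=SEED, duration=420.0, audio_fs=94000.0)
    cfg.schedule = synth.make_schedule(5, 5, cfg.duration, rng)
    rec, log = synth.generate_scene(cfg)
    rec.gps, track_truth = synth.generate_track(synth.SynthConfig(seed=SEED, duration=1800.0))
    files = synth.write_fixture(rec, log, OUT)
    track_truth.events.to_csv(OUT / "track_truth.csv", index=False)

    attacks = log.of_kind("attack")
    print(f"scene: {cfg.duration:.0f} s audio @ {cfg.audio_fs:.0f} Hz, seed {SEED}")
    print(f"scheduled attacks: {len(attacks)} "
          f"({(attacks['strategy'] == 'glean').sum()} glean / {(attacks['strategy'] == 'hawk').sum()} hawk), "
          f"{int(attacks['success'].sum())} successful")
    print(f"truth events: {len(log.events)} rows -> {files['events']}")
    print(f"GPS fixes: {len(rec.gps)} @ {cfg.gps_dt:.0f} s -> {OUT/'gps.csv'}")


if __name__ == "__main__":
    main()
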