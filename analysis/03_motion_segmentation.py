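"""Motion analysis of the simulated night: flight, landings, bouts.

Band-passes the heave axis to find wingbeat flight epochs, detects
landings (jerk peak + audio transient + post-event flattening), computes
tilt-corrected heading, segments foraging bouts from heading variation,
and keeps only bouts that contain prey attacks.

Run after 01_simulate_tag_data.py.
Output: results/motion/{epochs,landings,bouts}.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from batforage import motion, synth
from batforage.pipeline import broadband_envelope

FIX = Path("results/fixture")
OUT = Path("results/motion")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rec, truth = synth.read_fixture(FIX)
    mt = motion.MotionTrack(accel=rec.accel, mag=rec.mag)

    bp = motion.bandpass_wingbeat(rec.accel["az"].to_numpy(), mt.accel_fs)
    epochs = motion.detect_flight_epochs(bp, 100.0)
    pd.DataFrame([(e.start, e.end) for e in epochs], columns=["start", "end"]).to_csv(
        OUT / "epochs.csv", index=False
    )
    print(f"flight epochs: {[(round(e.start,1), round(e.end,1)) for e in epochs]}")

    env = broadband_envelope(rec.audio, rec.audio_fs)
    landings = motion.detect_landings(mt, env, 1000.0)
    pd.DataFrame({"t": landings}).to_csv(OUT / "landings.csv", index=False)
    truth_landings = truth.events.loc[truth.events["kind"] == "landing", "t"].tolist()
    print(f"landings: detected {[round(t,2) for t in landings]} vs truth {truth_landings}")

    heading = motion.compute_heading(mt)
    bouts = motion.detect_foraging_bouts(heading, mt.mag_fs, epochs=epochs)
    attacks = truth.events.loc[truth.events["kind"] == "attack", "t"].to_numpy()
    bouts = motion.filter_bouts(bouts, attacks)
    pd.DataFrame(
        [(b.start, b.end, b.mode, b.n_attacks) for b in bouts],
        columns=["start", "end", "mode", "n_attacks"],
    ).to_csv(OUT / "bouts.csv", index=False)
    print(f"foraging bouts with attacks: "
          f"{[(round(b.start,1), round(b.end,1), b.n_attacks) for b in bouts]}")


if __name__ == "__main__":
    main()
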