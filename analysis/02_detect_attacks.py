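"""Acoustic analysis of the simulated night: calls, buzzes, chewing.

Detects echolocation calls and feeding buzzes, classifies every annotated
prey attack as successful or failed from post-capture mastication sounds,
characterizes the chew trains (count, onset, duration, handling time),
and scores the classifier against the generator's truth log.

Run after 01_simulate_tag_data.py.
Output: results/acoustics/{events,chews,detector_evaluation}.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from batforage import acoustics, synth

FIX = Path("results/fixture")
OUT = Path("results/acoustics")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rec, truth = synth.read_fixture(FIX)

    calls = acoustics.detect_calls(rec.audio, rec.audio_fs)
    buzzes = acoustics.detect_buzzes(calls)
    print(f"{len(calls)} calls, {len(buzzes)} buzzes detected")

    att_truth = truth.events[truth.events["kind"] == "attack"]
    attacks = [acoustics.AttackEvent(float(r.t), str(r.strategy)) for r in att_truth.itertuples()]
    attacks, trains = acoustics.analyze_attacks(rec.audio, rec.audio_fs, calls, attacks)

    pd.DataFrame(
        [(a.time, a.strategy, a.success, a.source) for a in attacks],
        columns=["t", "strategy", "success", "source"],
    ).to_csv(OUT / "events.csv", index=False)
    chews = pd.DataFrame(
        [(t.attack_time, t.count, t.onset, t.duration, t.handling_time) for t in trains],
        columns=["attack_t", "count", "onset", "duration", "handling_time"],
    )
    chews.to_csv(OUT / "chews.csv", index=False)

    truth_attacks = [
        acoustics.AttackEvent(float(r.t), str(r.strategy), bool(r.success), source="truth")
        for r in att_truth.itertuples()
    ]
    rows = []
    for strat, ev in acoustics.evaluate_by_strategy(attacks, truth_attacks).items():
        rows.append({"strategy": strat, "tp": ev.tp, "fp": ev.fp, "fn": ev.fn, "tn": ev.tn,
                     "ppv": ev.ppv, "fnr": ev.fnr})
        print(f"{strat}: PPV={ev.ppv if not np.isnan(ev.ppv) else float('nan'):.3f} "
              f"FNR={ev.fnr:.3f} (TP{ev.tp} FP{ev.fp} FN{ev.fn} TN{ev.tn})")
    pd.DataFrame(rows).to_csv(OUT / "detector_evaluation.csv", index=False)

    if len(chews):
        print(f"chew trains: counts {chews['count'].tolist()}, "
              f"median handling {chews['handling_time'].median():.1f} s")


if __name__ == "__main__":
    main()
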