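"""Energy budget and prey profitability for the simulated night.

Combines the classified attacks and chew trains with the energy model:
prey caloric values (ground 67.5 mg dry at 25.4 kJ/g; aerial 3.0 or
21.2 mg at 21.3 kJ/g), nightly ingested energy for both aerial-mass
estimates, the 50-82% assimilation window, the allometric field metabolic
rate of a 30 g bat, and the per-strategy profitability index
P = calories / (handling + time between attacks) * success ratio.

Run after 02_detect_attacks.py.
Output: results/energetics/night_summary.json
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from batforage import energetics as en
from batforage import pipeline
from batforage.acoustics import AttackEvent, ChewTrain

EVENTS = Path("results/acoustics/events.csv")
CHEWS = Path("results/acoustics/chews.csv")
OUT = Path("results/energetics")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ev = pd.read_csv(EVENTS)
    ch = pd.read_csv(CHEWS)
    attacks = [AttackEvent(float(r.t), str(r.strategy), bool(r.success)) for r in ev.itertuples()]
    trains = [
        ChewTrain(float(r.attack_t), np.array([]), int(r.count), float(r.onset),
                  float(r.duration), float(r.handling_time))
        for r in ch.itertuples()
    ]
    cfg = en.EnergyConfig()
    s = pipeline.summarize_night(attacks, trains, [], cfg)

    print(f"attacks: {s.attacks}, successes: {s.successes}")
    print(f"success ratios: { {k: (None if np.isnan(v) else round(v,2)) for k,v in s.success_ratio.items()} }")
    print(f"ingested energy: {s.intake_kj[0]:.2f} kJ (lower aerial mass) - {s.intake_kj[1]:.2f} kJ (higher)")
    print(f"assimilated: {s.assimilated_kj[0]:.2f} - {s.assimilated_kj[1]:.2f} kJ (50-82% efficiency)")

    fmr = en.fmr_allometric(45.8, 18.0, 30.0)
    print(f"allometric FMR of a 30 g bat (from 45.8 kJ/day at 18 g): {fmr:.1f} kJ/day")

    for st, p in s.profitability_j_s.items():
        lo = "NA" if np.isnan(p[0]) else f"{p[0]:.2f}"
        hi = "NA" if np.isnan(p[1]) else f"{p[1]:.2f}"
        print(f"profitability {st}: {lo} - {hi} J/s")

    (OUT / "night_summary.json").write_text(json.dumps(pipeline._jsonable(s.to_dict()), indent=1))
    print(f"wrote {OUT/'night_summary.json'}")


if __name__ == "__main__":
    main()
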