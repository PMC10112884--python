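"""Large-scale validation of the success classifier and ratio recovery.

Pools hundreds of seeded post-attack windows with balanced truth to
measure the chewing-based success classifier's positive predictive value
and false-negative rate, then recovers the per-strategy nightly success
ratios (defaults: 76% aerial hawking, 30% ground gleaning) from full
synthetic nights of >= 500 attacks per strategy.

This is the slowest analysis step (a few minutes of audio synthesis and
detection).
Output: results/validation/summary.json
"""

import json
from pathlib import Path

from batforage import evaluation

OUT = Path("results/validation")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ev = evaluation.evaluate_success_classifier(n_windows=200, seed=1)
    n = ev.tp + ev.fp + ev.fn + ev.tn
    print(f"success classifier on {n} windows: PPV={ev.ppv:.4f}, FNR={ev.fnr:.4f}")

    hawk, n_hawk = evaluation.recover_success_ratio("hawk", n_attacks=500, seed=1)
    glean, n_glean = evaluation.recover_success_ratio("glean", n_attacks=500, seed=1)
    print(f"recovered aerial-hawking success ratio: {hawk:.1f} % ({n_hawk} attacks; generator p=0.76)")
    print(f"recovered gleaning success ratio: {glean:.1f} % ({n_glean} attacks; generator p=0.30)")

    (OUT / "summary.json").write_text(
        json.dumps(
            {
                "ppv": ev.ppv,
                "fnr": ev.fnr,
                "n_windows": int(n),
                "hawk_success_pct": hawk,
                "glean_success_pct": glean,
            },
            indent=1,
        )
    )
    print(f"wrote {OUT/'summary.json'}")


if __name__ == "__main__":
    main()
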