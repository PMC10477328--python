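"""Wide-field pipeline on a synthetic cortical stack.

Generates a stack with a planted frontal-cortex suppression that deepens
across three stimulation blocks, runs motion correction, per-trial DF/F,
region z-scoring, and the sustained-suppression score.  Writes
results/widefield_suppression.csv.
"""

from pathlib import Path

import numpy as np

from dbsrecruit import synth, widefield as wf

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rng = np.random.default_rng(1)
    shifts = np.zeros((0, 2), dtype=int)
    stack_data, masks, tt, rate = synth.generate_widefield_stack(
        n_blocks=3, n_trials=3, suppression_depth=(0.1, 0.25, 0.5), seed=1,
    )
    st = wf.WidefieldStack(stack_data, rate, tt, masks)
    corrected, applied = wf.motion_correct_rigid(st)
    print(f"motion correction: max |shift| = {np.abs(applied).max()} px "
          "(static stack, as expected)")

    d = wf.dff(corrected)
    curves = wf.region_zscore_curves(d)
    scores = wf.sustained_suppression(curves, tt, rate, window_s=10.0)
    scores.to_csv(ROOT / "widefield_suppression.csv", index=False)
    print("\nsustained suppression score (mean z, last 10 s of DBS):")
    print(scores.pivot(index="region", columns="block", values="score").round(2).to_string())
    fc = scores[scores.region == "FC"].sort_values("block")["score"].to_numpy()
    print(f"\nFC deepens dose-dependently ({fc.round(2).tolist()}); "
          "other regions stay near zero.")


if __name__ == "__main__":
    main()
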