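"""Classify DBS-recruited neurons and build dose-response / E-I summaries.

Reads the session written by 02_simulate_session.py, z-scores, aligns
trials on DBS onset, classifies every neuron per block
(transient/sustained x excited/inhibited), and compares the detected
dose-response curve with the planted ground truth.  Writes
results/labels.csv and results/dose_response.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dbsrecruit import recruitment as rc
from dbsrecruit.session import align_trials, read_session, zscore_traces

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "session"


def main() -> None:
    session = read_session(SCRATCH)
    gt = json.loads((SCRATCH / "ground_truth.json").read_text())
    planted = np.array(gt["neuron_class"])

    z = zscore_traces(session)
    tensor = align_trials(z)
    labels = rc.classify_session(tensor, excluded_neurons=z.excluded_neurons)
    labels.to_csv(ROOT / "labels.csv", index=False)

    dose = rc.dose_response(labels)
    dose.to_csv(ROOT / "dose_response.csv", index=False)
    wide = dose[dose.klass == "any"][["block", "count", "fraction"]]
    print("recruited neurons per block (detected vs planted):")
    for _, row in wide.iterrows():
        b = int(row["block"])
        n_planted = int((planted[:, b] != "none").sum())
        print(f"  block {b}: detected {int(row['count']):3d} "
              f"({row['fraction']:.0%}), planted {n_planted}")

    print("\nexcited/inhibited balance among recruited neurons:")
    for b in tensor.blocks:
        n_exc, n_inh, p = rc.ei_balance(labels, b)
        tag = "" if np.isnan(p) else f" (binomial p={p:.3f})"
        print(f"  block {b}: {n_exc} excited vs {n_inh} inhibited{tag}")


if __name__ == "__main__":
    main()
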