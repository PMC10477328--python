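"""Current-spread model: activation-sphere size across the stimulation range.

Solves I = I0 + K r^2 for the sphere of activation around the electrode
tip at the currents used in the dose-response design (0-300 uA) and
prints the low/high-intensity diameters.  Writes
results/current_spread.csv.
"""

from pathlib import Path

import pandas as pd

from dbsrecruit import stim

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for current in (50, 100, 150, 200, 250, 300):
        res = stim.activation_radius(stim.StimParams(float(current)))
        rows.append(
            {"current_uA": current, "radius_mm": round(res.radius_mm, 4),
             "diameter_mm": round(res.diameter_mm, 2)}
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "current_spread.csv", index=False)
    print(table.to_string(index=False))
    low = table[table.current_uA == 100]["diameter_mm"].iloc[0]
    high = table[table.current_uA == 300]["diameter_mm"].iloc[0]
    print(f"\nActivation sphere grows from {low} mm (100 uA) to {high} mm (300 uA):")
    print("low-intensity stimulation stays within the internal capsule, while")
    print("high-intensity stimulation approaches a 1-mm sphere around the tip.")


if __name__ == "__main__":
    main()
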