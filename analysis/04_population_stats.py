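"""Population-level bootstrap statistics on the classified session.

Computes consistency of modulation across blocks, overlap of recruited
populations between consecutive stimulation intensities, the spatial
clustering test, the cell-activity index (no-DBS vs high-intensity
block), and the distance-correlation curve.  Writes
results/population_stats.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dbsrecruit import network as nw
from dbsrecruit import recruitment as rc
from dbsrecruit import resampling as rs
from dbsrecruit.session import read_session, zscore_traces

ROOT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "session"
SEED = 1
N_BOOT = 1000


def main() -> None:
    session = read_session(SCRATCH)
    labels = pd.read_csv(ROOT / "labels.csv")
    z = zscore_traces(session)
    universe = np.array([i for i in range(session.n_neurons) if i not in z.excluded_neurons])
    by_block = rc.labels_by_block(labels)
    out: dict = {}

    cons = rs.consistency_of_modulation(by_block, universe, n_boot=N_BOOT, seed=SEED)
    out["consistency"] = {}
    print("consistency of modulation (observed vs chance):")
    for cluster, rec in cons.items():
        name = f"{cluster[0]}_{cluster[1]}"
        if rec["result"] is None:
            print(f"  {name}: empty cluster")
            continue
        r = rec["result"]
        out["consistency"][name] = r.to_dict()
        print(f"  {name}: {rec['observed']:.2f} vs null "
              f"{np.mean(r.null_samples):.2f} (p={r.p:.3f}, Delta={r.effect_size:.2f})")

    out["overlap"] = {}
    blocks = sorted(by_block)
    print("\noverlap of recruited populations between intensities:")
    for a, b in zip(blocks, blocks[1:]):
        r = rs.population_overlap(list(by_block[a]), list(by_block[b]), universe,
                                  n_boot=N_BOOT, seed=SEED)
        out["overlap"][f"{a}->{b}"] = r.to_dict()
        print(f"  block {a} -> {b}: P(B|A)={r.observed:.2f} "
              f"(chance {np.mean(r.null_samples):.2f}, p={r.p:.3f})")

    top = blocks[-1]
    rec_ids = np.array(sorted(by_block[top]))
    sp = nw.clustering_test(session.centroids, rec_ids, universe, n_boot=N_BOOT, seed=SEED)
    out["clustering"] = {
        "observed_nn_distance": sp.observed_nn_distance,
        "n_recruited": sp.n_recruited,
        "p_clustered": sp.p_clustered,
        "p_dispersed": sp.p_dispersed,
    }
    print(f"\nspatial clustering (block {top}, {sp.n_recruited} recruited): "
          f"mean NN distance {sp.observed_nn_distance:.1f} px, "
          f"p_clustered={sp.p_clustered:.3f}, p_dispersed={sp.p_dispersed:.3f}")

    first = blocks[0] if 0 not in blocks else 0
    cai0 = nw.cell_activity_index(session.events, session.block_frames(0), session.frame_rate_hz)
    cai1 = nw.cell_activity_index(session.events, session.block_frames(top), session.frame_rate_hz)
    out["cell_activity_index"] = {"no_dbs": cai0.index, "high_dbs": cai1.index}
    print(f"\ncell-activity index: {cai0.index:.2f} (no DBS) vs {cai1.index:.2f} (high DBS)")

    b0, b1 = session.block_frames(0)
    _, curve = nw.spatiotemporal_correlation(z.traces[universe], session.centroids[universe],
                                             slice(b0, b1))
    out["correlation_curve"] = curve.to_dict(orient="records")

    (ROOT / "population_stats.json").write_text(json.dumps(out, indent=1))
    print(f"\nwritten to {ROOT / 'population_stats.json'}")


if __name__ == "__main__":
    main()
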