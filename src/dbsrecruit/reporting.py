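"""Summary tables and end-to-end pipeline orchestration.

``run_pipeline`` executes the full analysis chain on a synthetic
session and collects every statistic into one JSON-serialisable
manifest: recruitment labels and dose-response, E/I balance,
consistency of modulation, between-block population overlap, spatial
clustering, cell-activity index, spatiotemporal-correlation curves,
behavior association and its crossing with recruitment, grooming
outcomes, and the current-spread model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dbsrecruit import behavior as bh
from dbsrecruit import network as nw
from dbsrecruit import recruitment as rc
from dbsrecruit import resampling as rs
from dbsrecruit import stim
from dbsrecruit import synth
from dbsrecruit.session import align_trials, zscore_traces

BUBBLE_CAP = 10.0


def summary_bubble_table(results: list[dict]) -> pd.DataFrame:
    """Tidy bubble-plot table: one row per (experiment, region) with the
    measured effect, its p-value, and a bubble size of -log10(p) capped
    (smaller p = bigger bubble)."""
    rows = []
    for rec in results:
        p = float(rec["p"])
        size = BUBBLE_CAP if p <= 0 else min(-np.log10(p), BUBBLE_CAP)
        rows.append(
            {
                "experiment": rec["experiment"],
                "region": rec["region"],
                "effect": float(rec["effect"]),
                "p": p,
                "bubble_size": size,
            }
        )
    return pd.DataFrame(rows, columns=["experiment", "region", "effect", "p", "bubble_size"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def run_pipeline(
    config: synth.SynthConfig,
    outdir: str | Path | None = None,
    n_boot: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Run the full analysis on one synthetic session; return the manifest."""
    session, gt = synth.generate_session(config)
    z = zscore_traces(session)
    tensor = align_trials(z)
    labels = rc.classify_session(tensor, alpha=alpha, excluded_neurons=z.excluded_neurons)
    dose = rc.dose_response(labels)

    manifest: dict = {
        "seed": config.seed,
        "n_neurons": config.n_neurons,
        "n_blocks": config.n_blocks,
        "anesthetized": config.anesthetized,
        "dose_response": dose,
        "n_dropped_trials": tensor.n_dropped_trials,
    }

    manifest["ei_balance"] = {}
    for b in tensor.blocks:
        n_exc, n_inh, p = rc.ei_balance(labels, b)
        manifest["ei_balance"][b] = {"n_excited": n_exc, "n_inhibited": n_inh, "p": p}

    by_block = rc.labels_by_block(labels)
    universe = np.array(
        [i for i in range(session.n_neurons) if i not in z.excluded_neurons]
    )
    if len(by_block) >= 2:
        cons = rs.consistency_of_modulation(
            by_block, universe, n_boot=n_boot, seed=config.seed
        )
        manifest["consistency"] = {
            f"{k[0]}_{k[1]}": {
                "observed": v["observed"],
                **({} if v["result"] is None else v["result"].to_dict()),
            }
            for k, v in cons.items()
        }

    # overlap of recruited populations between consecutive blocks
    manifest["overlap"] = {}
    blocks_with = [b for b in tensor.blocks if by_block.get(b)]
    for a, b in zip(blocks_with, blocks_with[1:]):
        res = rs.population_overlap(
            list(by_block[a]), list(by_block[b]), universe, n_boot=n_boot, seed=config.seed
        )
        manifest["overlap"][f"{a}->{b}"] = res.to_dict()

    # spatial clustering in the highest block with >= 2 recruited neurons
    for b in reversed(tensor.blocks):
        rec_ids = np.array(sorted(by_block.get(b, {})))
        if rec_ids.size >= 2:
            sp = nw.clustering_test(
                session.centroids, rec_ids, universe, n_boot=n_boot, seed=config.seed
            )
            manifest["clustering"] = {
                "block": b,
                "observed_nn_distance": sp.observed_nn_distance,
                "n_recruited": sp.n_recruited,
                "p_clustered": sp.p_clustered,
                "p_dispersed": sp.p_dispersed,
            }
            break

    # cell-activity index: no-DBS block vs highest block
    first, last = tensor.blocks[0], tensor.blocks[-1]
    cai0 = nw.cell_activity_index(session.events, session.block_frames(first), session.frame_rate_hz)
    cai1 = nw.cell_activity_index(session.events, session.block_frames(last), session.frame_rate_hz)
    manifest["cell_activity_index"] = {
        "no_dbs": cai0.index,
        "high_dbs": cai1.index,
        "difference": cai1.index - cai0.index,
    }

    # spatiotemporal correlation: no-DBS block frames
    b0, b1 = session.block_frames(first)
    _, curve = nw.spatiotemporal_correlation(
        z.traces[universe], session.centroids[universe], slice(b0, b1)
    )
    manifest["correlation_curve"] = curve

    # behavior association
    if session.behavior is not None:
        bins = bh.build_behavior_bins(
            session.events,
            session.behavior["grooming"].to_numpy(),
            session.behavior["locomotion"].to_numpy(),
            session.frame_rate_hz,
        )
        blabels = bh.classify_all_neurons(bins, alpha=alpha)
        manifest["behavior_labels"] = blabels[["neuron", "label", "bayes_factor", "p_omnibus"]]
        counts, overlap = bh.behavior_dbs_cross(blabels, labels, n_boot=n_boot, seed=config.seed)
        manifest["behavior_dbs_cross"] = counts
        manifest["behavior_dbs_overlap"] = {k: v.to_dict() for k, v in overlap.items()}

        outcome = stim.grooming_change(
            session.behavior["grooming"].to_numpy(), session.trial_table, session.frame_rate_hz
        )
        manifest["grooming"] = outcome.per_block

    manifest["activation_sphere"] = {
        "low_100uA_diameter_mm": stim.activation_radius(stim.StimParams(100.0)).diameter_mm,
        "high_300uA_diameter_mm": stim.activation_radius(stim.StimParams(300.0)).diameter_mm,
    }

    # ground-truth recovery summary
    planted = gt.neuron_class[:, -1] != "none"
    detected = labels[(labels["block"] == last) & labels["klass"].isin(["transient", "sustained"])]
    manifest["recovery"] = {
        "n_planted_last_block": int(planted.sum()),
        "n_detected_last_block": int(len(detected)),
    }

    manifest = _jsonable(manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        labels.to_csv(outdir / "labels.csv", index=False)
        dose.to_csv(outdir / "dose_response.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
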