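"""Resting-state activity, spatiotemporal correlation structure, and the
nearest-recruited-neighbor spatial clustering test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from dbsrecruit.resampling import BootstrapResult, summarize_bootstrap, DEFAULT_N_BOOT

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# cell-activity index


@dataclass
class CellActivityIndex:
    """Per-block resting-activity summary.

    ``per_neuron`` is the mean (over one-minute bins) of the summed
    deconvolved event amplitudes per bin, one value per neuron;
    ``index`` averages it across neurons.  Trailing partial bins are
    excluded.
    """

    per_neuron: np.ndarray
    index: float
    n_bins: int

    def __post_init__(self):
        assert self.index >= 0 or np.isnan(self.index)


def cell_activity_index(
    events: np.ndarray,
    block_frames: tuple[int, int],
    frame_rate_hz: float,
) -> CellActivityIndex:
    """Cell-activity index for one block.

    Per neuron the event amplitudes in each full 60-s bin of the block
    are summed and the bin values averaged; the block index is the mean
    across neurons.
    """
    start, stop = block_frames
    fpb = int(round(60.0 * frame_rate_hz))
    n_bins = (stop - start) // fpb
    if n_bins < 1:
        raise ValueError("block spans less than one full minute")
    seg = events[:, start : start + n_bins * fpb]
    per_bin = seg.reshape(events.shape[0], n_bins, fpb).sum(axis=2)
    per_neuron = per_bin.mean(axis=1)
    return CellActivityIndex(per_neuron=per_neuron, index=float(per_neuron.mean()), n_bins=n_bins)


def event_amplitude_cdf(events: np.ndarray, block_frames: tuple[int, int], n_grid: int = 100):
    """Empirical CDF of nonzero event amplitudes within a block,
    evaluated on a common amplitude grid (companion to the index)."""
    start, stop = block_frames
    amps = events[:, start:stop]
    amps = amps[amps > 0]
    if amps.size == 0:
        return np.array([]), np.array([])
    grid = np.linspace(0, amps.max(), n_grid)
    cdf = np.searchsorted(np.sort(amps), grid, side="right") / amps.size
    return grid, cdf


# ---------------------------------------------------------------------------
# spatiotemporal correlation


def spatiotemporal_correlation(
    traces: np.ndarray,
    centroids: np.ndarray,
    frames: np.ndarray | slice,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise centroid distance vs temporal activity correlation.

    Returns (pairs, curve): ``pairs`` holds every usable neuron pair's
    Euclidean distance and Pearson correlation over the given frames
    (pairs with a constant trace in the window are skipped and logged);
    ``curve`` is the mean correlation per log-spaced distance bin
    (log-spacing is the field's display convention; the underlying
    distances stay linear).
    """
    if traces.shape[0] < 2:
        raise ValueError("need >= 2 neurons")
    seg = traces[:, frames]
    sd = seg.std(axis=1)
    ok = sd > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("spatiotemporal_correlation: %d constant traces skipped", n_skipped)

    idx = np.flatnonzero(ok)
    corr = np.corrcoef(seg[idx])
    dist = squareform(pdist(centroids[idx]))
    iu = np.triu_indices(len(idx), k=1)
    pairs = pd.DataFrame(
        {
            "neuron_i": idx[iu[0]],
            "neuron_j": idx[iu[1]],
            "distance": dist[iu],
            "correlation": corr[iu],
        }
    )
    curve = _bin_curve(pairs, n_bins)
    return pairs, curve


def _bin_curve(pairs: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    d = pairs["distance"].to_numpy()
    pos = d[d > 0]
    if pos.size == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "mean_corr", "n_pairs"])
    edges = np.geomspace(pos.min(), d.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "mean_corr": float(pairs["correlation"][sel].mean()) if sel.any() else np.nan,
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def correlation_curve_difference(
    traces: np.ndarray,
    centroids: np.ndarray,
    frames_a: np.ndarray | slice,
    frames_b: np.ndarray | slice,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-bin difference of correlation curves between two frame sets
    (e.g. DBS-on vs no-DBS), binned on the pooled distance grid."""
    pairs_a, _ = spatiotemporal_correlation(traces, centroids, frames_a, n_bins)
    pairs_b, _ = spatiotemporal_correlation(traces, centroids, frames_b, n_bins)
    merged = pairs_a.merge(
        pairs_b, on=["neuron_i", "neuron_j"], suffixes=("_a", "_b")
    )
    merged["distance"] = merged["distance_a"]
    merged["correlation"] = merged["correlation_a"] - merged["correlation_b"]
    curve = _bin_curve(merged[["distance", "correlation"]], n_bins)
    return curve.rename(columns={"mean_corr": "mean_corr_diff"})


# ---------------------------------------------------------------------------
# spatial clustering of recruited neurons


@dataclass
class SpatialTestResult:
    observed_nn_distance: float
    n_recruited: int
    p_clustered: float
    p_dispersed: float
    clustered: BootstrapResult
    dispersed: BootstrapResult


def mean_nearest_neighbor_distance(points: np.ndarray) -> float:
    """Mean over points of the distance to the closest other point."""
    if len(points) < 2:
        raise ValueError("need >= 2 points")
    d = squareform(pdist(points))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def clustering_test(
    centroids: np.ndarray,
    recruited_ids: np.ndarray,
    all_ids: np.ndarray | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> SpatialTestResult:
    """Nearest-recruited-neighbor clustering test.

    Observed statistic: mean, over recruited neurons, of the distance to
    the closest *other recruited* neuron (closest-neighbor rather than
    all-pairs distances, so short clustered distances are not averaged
    out by long ones).  Null: draw |recruited| neurons at random from
    all recorded neurons and recompute, ``n_boot`` times.  Both tails
    are reported: ``p_clustered`` (observed short relative to null) and
    ``p_dispersed`` (observed long).
    """
    recruited_ids = np.asarray(recruited_ids)
    if recruited_ids.size < 2:
        raise ValueError("need >= 2 recruited neurons")
    if all_ids is None:
        all_ids = np.arange(len(centroids))
    all_ids = np.asarray(all_ids)

    observed = mean_nearest_neighbor_distance(centroids[recruited_ids])

    rng = np.random.default_rng(seed)
    k = recruited_ids.size
    # vectorised null: precompute the full distance matrix once
    d = squareform(pdist(centroids[all_ids]))
    np.fill_diagonal(d, np.inf)
    null = np.empty(n_boot)
    n_all = all_ids.size
    for rep in range(n_boot):
        sub = rng.choice(n_all, size=k, replace=False)
        null[rep] = d[np.ix_(sub, sub)].min(axis=1).mean()

    clustered = summarize_bootstrap(observed, null, side="less", seed=seed)
    dispersed = summarize_bootstrap(observed, null, side="greater", seed=seed)
    return SpatialTestResult(
        observed_nn_distance=observed,
        n_recruited=int(k),
        p_clustered=clustered.p,
        p_dispersed=dispersed.p,
        clustered=clustered,
        dispersed=dispersed,
    )
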