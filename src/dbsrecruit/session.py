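"""Session data model, I/O, trial alignment and normalisation.

A session is a continuous miniscope recording with a block x trial DBS
structure: each trial holds a pre-stimulation baseline, a DBS-on period
and a post-stimulation tail.  Downstream stages consume either the raw
session (behavior association, resting-state metrics) or a trial-aligned
tensor cut around DBS onset (recruitment classification).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = [
    "block",
    "trial",
    "intensity_label",
    "dbs_on_frame",
    "dbs_off_frame",
]


@dataclass
class Session:
    """A single imaging session.

    Parameters
    ----------
    traces : ndarray, shape (n_neurons, n_frames)
        DF/F fluorescence traces.
    events : ndarray, shape (n_neurons, n_frames)
        Nonnegative deconvolved event amplitudes.
    centroids : ndarray, shape (n_neurons, 2)
        Neuron centroid (x, y) in pixels.
    trial_table : DataFrame
        One row per trial with columns ``block``, ``trial``,
        ``intensity_label``, ``dbs_on_frame``, ``dbs_off_frame``
        (half-open frame windows, 0-based).
    frame_rate_hz : float
        Acquisition rate.
    behavior : DataFrame, optional
        Frame-indexed streams; columns ``grooming`` (binary) and
        ``locomotion`` (nonnegative speed).
    """

    traces: np.ndarray
    events: np.ndarray
    centroids: np.ndarray
    trial_table: pd.DataFrame
    frame_rate_hz: float
    behavior: pd.DataFrame | None = None
    brain_region: str = ""
    genotype: str = ""
    um_per_px: float | None = None
    excluded_neurons: list[int] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def validate(self) -> None:
        if self.traces.shape != self.events.shape:
            raise ValueError("traces and events shapes differ")
        if np.any(self.events < 0):
            raise ValueError("events must be nonnegative")
        if self.centroids.shape != (self.n_neurons, 2):
            raise ValueError("centroids must be (n_neurons, 2)")
        tt = self.trial_table
        if len(tt):
            if tt["dbs_off_frame"].max() > self.n_frames:
                raise ValueError("trial frames exceed recording length")
            on = tt["dbs_on_frame"].to_numpy()
            off = tt["dbs_off_frame"].to_numpy()
            if np.any(off < on):
                raise ValueError("trial windows must satisfy off >= on")
            if np.any(np.diff(on) <= 0):
                raise ValueError("trials must be time-ordered")
            if np.any(on[1:] < off[:-1]):
                raise ValueError("trials overlap")

    def block_frames(self, block: int) -> tuple[int, int]:
        """Half-open frame span covered by a block's trials (incl. pre/post roll)."""
        rows = self.trial_table[self.trial_table["block"] == block]
        if rows.empty:
            raise ValueError(f"no trials in block {block}")
        pre = int(round(10 * self.frame_rate_hz))
        start = max(0, int(rows["dbs_on_frame"].min()) - pre)
        stop = min(self.n_frames, int(rows["dbs_off_frame"].max()) + pre)
        return start, stop


@dataclass
class TrialTensor:
    """Trial-aligned values cut around DBS onset.

    ``values`` has shape (n_neurons, n_trials, n_within_frames) where the
    within-trial axis runs from 10 s before DBS onset to 10 s after DBS
    offset.  ``period_windows`` maps period name to a half-open
    (start, stop) frame range on the within-trial axis:
    baseline (-10..0 s), early (0..20 s), middle (20..40 s),
    late (40..60 s), post (60..70 s for the default 60-s DBS layout).
    """

    values: np.ndarray
    trial_table: pd.DataFrame
    period_windows: dict[str, tuple[int, int]]
    frame_rate_hz: float
    n_dropped_trials: int = 0

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    def block_trials(self, block: int) -> np.ndarray:
        """values restricted to one block: (n_neurons, n_block_trials, frames)."""
        idx = np.flatnonzero((self.trial_table["block"] == block).to_numpy())
        if idx.size == 0:
            raise ValueError(f"no trials in block {block}")
        return self.values[:, idx, :]

    @property
    def blocks(self) -> list[int]:
        return sorted(self.trial_table["block"].unique().tolist())


class ZeroVarianceError(ValueError):
    """A neuron trace has no variance and cannot be z-scored."""


def zscore_traces(session: Session) -> Session:
    """Z-score each neuron's trace over the whole session (population SD).

    Z = (x - mu) / sigma per neuron.  Zero-variance neurons cannot be
    normalised; they are flagged in ``excluded_neurons`` and their rows
    set to NaN so downstream classification skips them explicitly rather
    than treating silently zeroed traces as data.
    """
    mu = session.traces.mean(axis=1, keepdims=True)
    sd = session.traces.std(axis=1, keepdims=True)  # ddof=0, as the formula reads
    flat = np.flatnonzero(sd.ravel() == 0)
    sd_safe = np.where(sd == 0, np.nan, sd)
    z = (session.traces - mu) / sd_safe
    if flat.size:
        logger.warning("zscore_traces: %d zero-variance neurons excluded", flat.size)
    excluded = sorted(set(session.excluded_neurons) | set(flat.tolist()))
    return replace(session, traces=z, excluded_neurons=excluded)


def align_trials(session: Session, pre_s: float = 10.0, post_s: float = 10.0) -> TrialTensor:
    """Cut per-trial windows aligned on DBS onset.

    Each trial window spans ``dbs_on_frame - pre_s`` to
    ``dbs_off_frame + post_s``.  Trials whose window would run past the
    recording bounds are dropped (and counted).  Periods follow the
    baseline / early / middle / late split of the stimulation epoch with
    a trailing post window.
    """
    tt = session.trial_table
    if tt.empty:
        raise ValueError("empty trial table")
    rate = session.frame_rate_hz
    pre = int(round(pre_s * rate))
    post = int(round(post_s * rate))

    dbs_len = (tt["dbs_off_frame"] - tt["dbs_on_frame"]).to_numpy()
    if len(np.unique(dbs_len)) != 1:
        raise ValueError("trials have unequal DBS durations; cannot align")
    n_dbs = int(dbs_len[0])
    width = pre + n_dbs + post

    starts = tt["dbs_on_frame"].to_numpy() - pre
    keep = (starts >= 0) & (starts + width <= session.n_frames)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("align_trials: dropped %d truncated trials", n_dropped)
    kept = tt[keep].reset_index(drop=True)
    if kept.empty:
        raise ValueError("no trials fit within the recording")

    idx = starts[keep][:, None] + np.arange(width)[None, :]
    values = session.traces[:, idx]  # (n_neurons, n_trials, width)

    third = n_dbs // 3
    period_windows = {
        "baseline": (0, pre),
        "early": (pre, pre + third),
        "middle": (pre + third, pre + 2 * third),
        "late": (pre + 2 * third, pre + n_dbs),
        "post": (pre + n_dbs, width),
    }
    return TrialTensor(
        values=values,
        trial_table=kept,
        period_windows=period_windows,
        frame_rate_hz=rate,
        n_dropped_trials=n_dropped,
    )


def bin_stream(
    stream: np.ndarray,
    bin_s: float,
    frame_rate_hz: float,
    agg: str = "mean",
) -> np.ndarray:
    """Bin a frame-indexed stream into fixed-duration bins.

    The bin width in frames is ``floor(bin_s * frame_rate_hz)`` (333 ms at
    15 Hz is exactly 5 frames).  The trailing partial bin is aggregated
    over its available frames.  ``agg`` is one of mean / sum / fraction
    (fraction = mean of a binary stream).
    """
    stream = np.asarray(stream, dtype=float)
    if stream.size == 0:
        raise ValueError("empty stream")
    fpb = int(np.floor(bin_s * frame_rate_hz))
    if fpb < 1:
        raise ValueError("bin shorter than one frame")
    n_bins = int(np.ceil(stream.size / fpb))
    out = np.empty(n_bins)
    for b in range(n_bins):
        chunk = stream[b * fpb : (b + 1) * fpb]
        if agg == "sum":
            out[b] = chunk.sum()
        elif agg in ("mean", "fraction"):
            out[b] = chunk.mean()
        else:
            raise ValueError(f"unknown agg {agg!r}")
    return out


# ---------------------------------------------------------------------------
# CSV/JSON session container


def write_session(session: Session, outdir: str | Path) -> Path:
    """Write a session to a directory of CSV files plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "traces.csv", session.traces, delimiter=",")
    np.savetxt(outdir / "events.csv", session.events, delimiter=",")
    np.savetxt(outdir / "centroids.csv", session.centroids, delimiter=",", header="x,y", comments="")
    session.trial_table.to_csv(outdir / "trials.csv", index=False)
    if session.behavior is not None:
        session.behavior.to_csv(outdir / "behavior.csv", index=False)
    meta = {
        "frame_rate_hz": session.frame_rate_hz,
        "brain_region": session.brain_region,
        "genotype": session.genotype,
        "um_per_px": session.um_per_px,
        "excluded_neurons": session.excluded_neurons,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    return outdir


def read_session(indir: str | Path) -> Session:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    behavior = None
    if (indir / "behavior.csv").exists():
        behavior = pd.read_csv(indir / "behavior.csv")
    traces = np.loadtxt(indir / "traces.csv", delimiter=",", ndmin=2)
    events = np.loadtxt(indir / "events.csv", delimiter=",", ndmin=2)
    centroids = np.loadtxt(indir / "centroids.csv", delimiter=",", skiprows=1, ndmin=2)
    session = Session(
        traces=traces,
        events=events,
        centroids=centroids,
        trial_table=pd.read_csv(indir / "trials.csv"),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        behavior=behavior,
        brain_region=meta.get("brain_region", ""),
        genotype=meta.get("genotype", ""),
        um_per_px=meta.get("um_per_px"),
        excluded_neurons=list(meta.get("excluded_neurons", [])),
    )
    session.validate()
    return session
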