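"""Wide-field calcium-imaging stack preprocessing.

The pipeline mirrors a standard head-fixed wide-field workflow: rigid
motion correction against the first frame (2D cross-correlation,
integer-pixel shifts), per-trial per-pixel DF/F against a 0.5-s baseline
window 9 to 8.5 s before DBS onset, Gaussian spatial smoothing
(sigma = 2 px), region-mask averaging, whole-recording z-scoring per
region, and a sustained-suppression score over the last 30 s of each
DBS period.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import stats
from scipy.ndimage import gaussian_filter
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


@dataclass
class WidefieldStack:
    data: np.ndarray  # (n_frames, H, W)
    frame_rate_hz: float
    trial_table: pd.DataFrame  # block, trial, dbs_on_frame, dbs_off_frame
    region_masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("stack must be (frames, H, W)")
        if len(self.trial_table) and self.trial_table["dbs_off_frame"].max() > self.n_frames:
            raise ValueError("trial timing exceeds stack length")
        shape = self.data.shape[1:]
        taken = np.zeros(shape, dtype=int)
        for name, mask in self.region_masks.items():
            if mask.shape != shape:
                raise ValueError(f"mask {name} shape mismatch")
            taken += mask.astype(int)
        if np.any(taken > 1):
            logger.warning("region masks overlap")


def read_stack(path: str | Path, frame_rate_hz: float, trial_table: pd.DataFrame,
               masks: dict[str, np.ndarray] | None = None) -> WidefieldStack:
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    return WidefieldStack(data, frame_rate_hz, trial_table, masks or {})


def write_stack(stack: WidefieldStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.data.astype(np.float32))


def write_masks_json(masks: dict[str, np.ndarray], path: str | Path) -> None:
    """Masks as run-length encoded JSON (rows of (start, stop) runs)."""
    out = {}
    for name, mask in masks.items():
        runs = []
        for r, row in enumerate(mask):
            d = np.diff(np.r_[0, row.astype(int), 0])
            starts = np.flatnonzero(d == 1)
            stops = np.flatnonzero(d == -1)
            runs.extend([[r, int(a), int(b)] for a, b in zip(starts, stops)])
        out[name] = {"shape": list(mask.shape), "runs": runs}
    Path(path).write_text(json.dumps(out))


def read_masks_json(path: str | Path) -> dict[str, np.ndarray]:
    raw = json.loads(Path(path).read_text())
    masks = {}
    for name, rec in raw.items():
        m = np.zeros(rec["shape"], dtype=bool)
        for r, a, b in rec["runs"]:
            m[r, a:b] = True
        masks[name] = m
    return masks


# ---------------------------------------------------------------------------
# operations


def motion_correct_rigid(stack: WidefieldStack) -> tuple[WidefieldStack, np.ndarray]:
    """Integer-pixel rigid registration to the first frame.

    The shift of each frame is the argmax of its 2D cross-correlation
    with frame 0 (computed via FFT, circular boundary); frames are
    rolled back by that shift.  Returns the corrected stack and the
    (n_frames, 2) array of applied (dy, dx) corrections.
    """
    data = stack.data
    ref = data[0]
    if not np.any(ref):
        raise ValueError("all-zero reference frame")
    h, w = ref.shape
    f_ref = np.fft.rfft2(ref)
    shifts = np.zeros((data.shape[0], 2), dtype=int)
    out = data.copy()
    for t in range(1, data.shape[0]):
        if not np.any(data[t]):
            raise ValueError(f"all-zero frame {t}")
        xc = np.fft.irfft2(np.fft.rfft2(data[t]) * np.conj(f_ref), s=ref.shape)
        peak = np.unravel_index(np.argmax(xc), xc.shape)
        dy = peak[0] if peak[0] <= h // 2 else peak[0] - h
        dx = peak[1] if peak[1] <= w // 2 else peak[1] - w
        shifts[t] = (dy, dx)
        out[t] = np.roll(data[t], (-dy, -dx), axis=(0, 1))
    return WidefieldStack(out, stack.frame_rate_hz, stack.trial_table, stack.region_masks), shifts


def dff(
    stack: WidefieldStack,
    baseline_start_s: float = 9.0,
    baseline_len_s: float = 0.5,
) -> WidefieldStack:
    """Per-trial per-pixel DF/F.

    F is the pixel's mean over the 0.5-s window starting
    ``baseline_start_s`` before DBS onset.  The recording is partitioned
    into per-trial segments (each trial's segment runs from its baseline
    window start to the next trial's; the leading frames join the first
    trial) and every frame becomes (F_t - F)/F against its trial's F.
    Pixels with F = 0 are masked to NaN and counted.
    """
    rate = stack.frame_rate_hz
    off0 = int(round(baseline_start_s * rate))
    blen = int(round(baseline_len_s * rate))
    if blen < 1:
        raise ValueError("baseline window shorter than one frame")
    out = stack.data.astype(float).copy()
    n_masked = 0
    onsets = stack.trial_table["dbs_on_frame"].astype(int).to_numpy()
    starts = onsets - off0
    if np.any(starts < 0):
        raise ValueError("baseline window precedes recording start")
    seg_bounds = np.r_[0, starts[1:], stack.n_frames]
    for i, on in enumerate(onsets):
        b0 = on - off0
        f0 = stack.data[b0 : b0 + blen].mean(axis=0)
        zero = f0 == 0
        n_masked += int(zero.sum())
        f0 = np.where(zero, np.nan, f0)
        s0, s1 = (0 if i == 0 else seg_bounds[i]), seg_bounds[i + 1]
        out[s0:s1] = (stack.data[s0:s1] - f0) / f0
    if n_masked:
        logger.warning("dff: %d zero-baseline pixels masked", n_masked)
    return WidefieldStack(out, rate, stack.trial_table, stack.region_masks)


def region_zscore_curves(
    stack: WidefieldStack,
    masks: dict[str, np.ndarray] | None = None,
    smooth_sigma_px: float = 2.0,
) -> pd.DataFrame:
    """Smoothed, mask-averaged, whole-recording z-scored region curves.

    Frames are Gaussian-smoothed spatially (sigma in pixels), averaged
    within each region mask, then z-scored per region over the entire
    recording.  Returns a (region x frame) DataFrame.
    """
    masks = masks if masks is not None else stack.region_masks
    if not masks:
        raise ValueError("no region masks")
    smoothed = gaussian_filter(stack.data, sigma=(0, smooth_sigma_px, smooth_sigma_px))
    curves = {}
    for name, mask in masks.items():
        if not mask.any():
            raise ValueError(f"empty mask {name}")
        series = np.nanmean(smoothed[:, mask], axis=1)
        mu, sd = np.nanmean(series), np.nanstd(series)
        if sd == 0:
            raise ValueError(f"region {name} has zero variance")
        curves[name] = (series - mu) / sd
    return pd.DataFrame(curves).T


def sustained_suppression(
    curves: pd.DataFrame,
    trial_table: pd.DataFrame,
    frame_rate_hz: float,
    window_s: float = 30.0,
) -> pd.DataFrame:
    """Mean region z over the last ``window_s`` seconds of each DBS
    period, averaged per block.  Requires DBS periods >= window_s."""
    n_win = int(round(window_s * frame_rate_hz))
    rows = []
    for _, row in trial_table.iterrows():
        on, off = int(row["dbs_on_frame"]), int(row["dbs_off_frame"])
        if off - on < n_win:
            raise ValueError("DBS period shorter than the scoring window")
        for region in curves.index:
            seg = curves.loc[region].to_numpy()[off - n_win : off]
            rows.append(
                {
                    "region": region,
                    "block": int(row["block"]),
                    "trial": int(row["trial"]),
                    "score": float(np.nanmean(seg)),
                }
            )
    per_trial = pd.DataFrame(rows)
    return (
        per_trial.groupby(["region", "block"])["score"].mean().reset_index()
    )


def compare_regions(per_trial_scores: pd.DataFrame, alpha: float = 0.05):
    """One-way comparison of suppression scores across regions with
    Tukey post-hoc.  Input needs columns region and score."""
    groups = [g["score"].to_numpy() for _, g in per_trial_scores.groupby("region")]
    if len(groups) < 2:
        raise ValueError("need >= 2 regions")
    f, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(
        per_trial_scores["score"].to_numpy(),
        per_trial_scores["region"].to_numpy(),
        alpha=alpha,
    )
    return float(f), float(p), tk
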