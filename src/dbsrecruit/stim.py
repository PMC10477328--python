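"""Electrode current-spread model and grooming outcome metrics.

The sphere of activation around a DBS electrode tip follows the
threshold-current relation I = I0 + K * r^2: an axon at distance r from
the tip is activated when the applied current I exceeds the threshold.
I0 (7-22 uA) is the current needed to excite an axon touching the
electrode and K (1292 uA/mm^2) sets how quickly the threshold grows with
distance; both come from classic microstimulation measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class StimParams:
    current_uA: float
    pulse_width_us: float = 80.0
    frequency_hz: float = 130.0
    I0_uA: float = 7.0
    K_uA_per_mm2: float = 1292.0

    def __post_init__(self):
        if min(self.current_uA, self.pulse_width_us, self.frequency_hz,
               self.I0_uA, self.K_uA_per_mm2) <= 0:
            raise ValueError("stimulation parameters must be positive")


@dataclass
class ActivationResult:
    radius_mm: float
    diameter_mm: float
    activated: bool


def activation_radius(params: StimParams) -> ActivationResult:
    """Radius (and diameter) of the activation sphere.

    Solves I = I0 + K r^2 for r.  Currents below I0 activate nothing
    (zero radius, flagged).  With the defaults, 100 uA gives a 0.54-mm
    diameter and 300 uA gives 0.95 mm.
    """
    if params.current_uA < params.I0_uA:
        logger.warning("current %.1f uA below threshold I0=%.1f uA", params.current_uA, params.I0_uA)
        return ActivationResult(0.0, 0.0, False)
    r = float(np.sqrt((params.current_uA - params.I0_uA) / params.K_uA_per_mm2))
    return ActivationResult(r, 2 * r, True)


# ---------------------------------------------------------------------------
# grooming outcomes


@dataclass
class GroomingOutcome:
    per_block: pd.DataFrame  # block, pct_pre, pct_during, pct_post, relative_change
    per_trial: pd.DataFrame  # block, trial, pct_pre, pct_during, pct_post


def grooming_change(
    grooming_stream: np.ndarray,
    trial_table: pd.DataFrame,
    frame_rate_hz: float,
    pre_s: float = 10.0,
    post_s: float = 10.0,
) -> GroomingOutcome:
    """Percent time grooming before / during / after DBS, per trial and
    per block, plus the relative change (during/pre x 100 - 100).

    Pre pools the ``pre_s`` seconds before each onset, during the full
    DBS period, post the ``post_s`` seconds after offset.  A block with
    zero pre-DBS grooming has an undefined relative change (NaN,
    logged).
    """
    g = np.asarray(grooming_stream, dtype=float)
    rate = frame_rate_hz
    n_pre = int(round(pre_s * rate))
    n_post = int(round(post_s * rate))
    rows = []
    for _, row in trial_table.iterrows():
        on, off = int(row["dbs_on_frame"]), int(row["dbs_off_frame"])
        if on - n_pre < 0 or off + n_post > g.size:
            raise ValueError("stream does not cover trial windows")
        rows.append(
            {
                "block": int(row["block"]),
                "trial": int(row["trial"]),
                "pct_pre": 100 * g[on - n_pre : on].mean(),
                "pct_during": 100 * g[on:off].mean(),
                "pct_post": 100 * g[off : off + n_post].mean(),
            }
        )
    per_trial = pd.DataFrame(rows)
    blocks = []
    for block, grp in per_trial.groupby("block"):
        pre, dur, post = grp["pct_pre"].mean(), grp["pct_during"].mean(), grp["pct_post"].mean()
        if pre == 0:
            logger.warning("grooming_change: block %s has no pre-DBS grooming", block)
            rel = float("nan")
        else:
            rel = dur / pre * 100 - 100
        blocks.append(
            {"block": int(block), "pct_pre": pre, "pct_during": dur, "pct_post": post,
             "relative_change": rel}
        )
    return GroomingOutcome(per_block=pd.DataFrame(blocks), per_trial=per_trial)


def paired_pre_during_test(outcome: GroomingOutcome, block: int) -> tuple[float, float]:
    """Paired t-test of per-trial grooming percentage, pre vs during DBS."""
    grp = outcome.per_trial[outcome.per_trial["block"] == block]
    res = stats.ttest_rel(grp["pct_during"], grp["pct_pre"])
    return float(res.statistic), float(res.pvalue)


def electrode_outcome_correlation(
    electrode_ap_mm: np.ndarray,
    electrode_dv_mm: np.ndarray,
    relative_change: np.ndarray,
) -> dict:
    """Correlate per-animal electrode position (AP x DV product) with the
    relative grooming change; report Pearson r, its p-value, and a
    BIC-approximated Bayes factor for the null (BF01 > 3 = substantial
    evidence of no location effect)."""
    x = np.asarray(electrode_ap_mm, dtype=float) * np.asarray(electrode_dv_mm, dtype=float)
    y = np.asarray(relative_change, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 animals")
    if np.all(x == x[0]):
        raise ValueError("constant predictor")
    r, p = stats.pearsonr(x, y)
    n = x.size
    # BIC1 - BIC0 = n ln(1 - r^2) + ln(n) for the one-predictor regression
    log_bf01 = 0.5 * (n * np.log(max(1 - r**2, 1e-300)) + np.log(n))
    return {
        "r": float(r),
        "p": float(p),
        "bf01": float(np.exp(np.clip(log_bf01, -700, 700))),
        "n": int(n),
    }
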