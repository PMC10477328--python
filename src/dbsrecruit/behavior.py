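"""Behavior-association classification of neurons.

Deconvolved events and behavior streams are binned into 333-ms bins;
each bin gets exactly one behavior category (grooming, stationary, or
locomotion).  Per neuron a one-way ANOVA with a BIC-approximated Bayes
factor decides whether binned event amplitudes differ across
categories; Tukey-HSD post-hoc comparisons then map the difference
pattern onto grooming- / locomotion- / both- / not-associated labels.
BF > 3 counts as substantial evidence for an effect, BF < 1/3 for its
absence; everything between (or a post-hoc pattern outside the four
rules) is indeterminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from dbsrecruit.resampling import population_overlap, BootstrapResult

logger = logging.getLogger(__name__)

CATEGORIES = ("grooming", "stationary", "locomotion")


@dataclass
class BehaviorBins:
    """Binned events and per-bin behavior categories.

    ``events`` is (n_neurons, n_bins) of summed event amplitudes;
    ``category`` assigns each bin exactly one of grooming / stationary /
    locomotion.  Grooming wins a bin if any of its frames is grooming
    (and the locomotion stream was zeroed over grooming frames before
    the median split, so no bin is both).
    """

    events: np.ndarray
    category: np.ndarray
    frames_per_bin: int
    locomotion_median: float


@dataclass
class BehaviorClass:
    neuron_id: int
    label: str  # grooming | locomotion | grooming_and_locomotion | not_associated | indeterminate
    bayes_factor: float
    p_omnibus: float
    posthoc: dict[str, bool]  # pair -> rejected (unequal)


def build_behavior_bins(
    events: np.ndarray,
    grooming_stream: np.ndarray,
    locomotion_stream: np.ndarray,
    frame_rate_hz: float,
    bin_s: float = 1.0 / 3.0,
) -> BehaviorBins:
    """Bin events and behavior into 333-ms bins and categorise each bin.

    Locomotion is forced to zero on grooming frames first.  Bins
    containing any grooming frame are grooming; the remaining bins are
    split at the median of their binned locomotion values - at or below
    the median is stationary, above is locomotion.
    """
    grooming_stream = np.asarray(grooming_stream, dtype=float)
    locomotion = np.asarray(locomotion_stream, dtype=float).copy()
    locomotion[grooming_stream > 0] = 0.0

    fpb = int(np.floor(bin_s * frame_rate_hz))
    if fpb < 1:
        raise ValueError("bin shorter than one frame")
    n_frames = events.shape[1]
    n_bins = n_frames // fpb  # behavior categories need full bins
    if n_bins < 2:
        raise ValueError("too few frames to bin")

    ev = events[:, : n_bins * fpb].reshape(events.shape[0], n_bins, fpb).sum(axis=2)
    groom_bins = (
        grooming_stream[: n_bins * fpb].reshape(n_bins, fpb).max(axis=1) > 0
    )
    loco_binned = locomotion[: n_bins * fpb].reshape(n_bins, fpb).mean(axis=1)

    non_groom = ~groom_bins
    if not non_groom.any():
        raise ValueError("all bins are grooming; locomotion median undefined")
    median = float(np.median(loco_binned[non_groom]))

    category = np.where(
        groom_bins, "grooming", np.where(loco_binned > median, "locomotion", "stationary")
    ).astype(object)
    return BehaviorBins(
        events=ev, category=category, frames_per_bin=fpb, locomotion_median=median
    )


def anova_with_bic_bayes_factor(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA p-value plus a BIC-approximated Bayes factor BF10.

    BF10 = exp((BIC0 - BIC1) / 2) where model 1 has a separate mean per
    group and model 0 a grand mean; with Gaussian likelihoods
    BIC1 - BIC0 = n ln(SSE1/SSE0) + (k-1) ln n.  The approximation
    corresponds to a unit-information prior and is monotone in the
    classical F statistic.
    """
    cats = np.unique(groups)
    samples = [values[groups == c] for c in cats]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every category needs >= 2 bins")
    n = values.size
    k = cats.size
    grand = values.mean()
    sse0 = float(np.sum((values - grand) ** 2))
    sse1 = float(sum(np.sum((s - s.mean()) ** 2) for s in samples))
    if sse1 == 0 or sse0 == 0:
        # degenerate: no within-group variance (perfect separation) or no
        # variance at all
        if sse0 == 0:
            return 1.0, 0.0
        return 0.0, float("inf")
    p = float(stats.f_oneway(*samples).pvalue)
    log_bf10 = -0.5 * (n * np.log(sse1 / sse0) + (k - 1) * np.log(n))
    return p, float(np.exp(np.clip(log_bf10, -700, 700)))


def classify_behavior_neuron(
    bins: BehaviorBins,
    neuron_id: int,
    alpha: float = 0.05,
    bf_threshold: float = 3.0,
) -> BehaviorClass:
    """Label one neuron by its behavior-binned activity pattern.

    Labels follow the post-hoc comparison rules: grooming-associated =
    grooming != stationary and stationary = locomotion; locomotion-
    associated = locomotion != stationary and stationary = grooming;
    both = grooming != stationary, locomotion != stationary, grooming =
    locomotion; not-associated = non-significant omnibus with BF < 1/3.
    Anything else is indeterminate.
    """
    values = bins.events[neuron_id]
    groups = bins.category
    p, bf = anova_with_bic_bayes_factor(values, groups)

    posthoc: dict[str, bool] = {}
    label = "indeterminate"
    if p < alpha and bf > bf_threshold:
        tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
        for (g1, g2), rej in zip(combinations(tk.groupsunique, 2), tk.reject):
            posthoc[f"{g1}|{g2}"] = bool(rej)
        gs = posthoc.get("grooming|stationary", posthoc.get("stationary|grooming", False))
        ls = posthoc.get("locomotion|stationary", posthoc.get("stationary|locomotion", False))
        gl = posthoc.get("grooming|locomotion", posthoc.get("locomotion|grooming", False))
        if gs and not ls:
            label = "grooming"
        elif ls and not gs:
            label = "locomotion"
        elif gs and ls and not gl:
            label = "grooming_and_locomotion"
        else:
            label = "indeterminate"
    elif p >= alpha and bf < 1.0 / bf_threshold:
        label = "not_associated"
    return BehaviorClass(
        neuron_id=neuron_id, label=label, bayes_factor=bf, p_omnibus=p, posthoc=posthoc
    )


def classify_all_neurons(bins: BehaviorBins, alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for i in range(bins.events.shape[0]):
        bc = classify_behavior_neuron(bins, i, alpha=alpha)
        rows.append(
            {
                "neuron": i,
                "label": bc.label,
                "bayes_factor": bc.bayes_factor,
                "p_omnibus": bc.p_omnibus,
                "posthoc": ";".join(k for k, v in bc.posthoc.items() if v),
            }
        )
    return pd.DataFrame(rows)


def behavior_dbs_cross(
    behavior_labels: pd.DataFrame,
    recruitment_labels: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, BootstrapResult]]:
    """Cross behavior classes with DBS recruitment.

    Per block, counts how many neurons of each behavior label are
    recruited; per block, tests the overlap of the recruited set with
    the grooming-associated set against the resampling null.
    """
    universe = behavior_labels["neuron"].to_numpy()
    counts = []
    overlap: dict[int, BootstrapResult] = {}
    groom_set = set(behavior_labels.loc[behavior_labels["label"] == "grooming", "neuron"])
    rec = recruitment_labels[recruitment_labels["klass"].isin(["transient", "sustained"])]
    for block, grp in rec.groupby("block"):
        rec_set = set(grp["neuron"].astype(int))
        for label, lgrp in behavior_labels.groupby("label"):
            n = len(set(lgrp["neuron"]) & rec_set)
            counts.append({"block": int(block), "label": label, "n_recruited": n})
        if rec_set and groom_set:
            overlap[int(block)] = population_overlap(
                rec_set, groom_set, universe, n_boot=n_boot, seed=seed + int(block)
            )
    return pd.DataFrame(counts), overlap
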