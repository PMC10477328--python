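"""Per-neuron recruitment classification and population summaries.

A neuron is a responder in a block if its activity during DBS differs
from its pre-DBS baseline (paired t-test across trials on per-trial
period means).  The stimulation epoch is split into early / middle /
late 20-s periods; a transient neuron differs from baseline only in the
early period, a sustained neuron in all three.  Patterns outside those
two definitions (e.g. middle-only, or mixed response signs) are kept as
``other`` rather than silently forced into a class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dbsrecruit.resampling import holm_bonferroni
from dbsrecruit.session import TrialTensor

logger = logging.getLogger(__name__)

PERIODS = ("early", "middle", "late")


@dataclass
class RecruitmentLabel:
    neuron_id: int
    block_id: int
    klass: str  # transient | sustained | none | other
    sign: str  # excited | inhibited | n/a
    p_values: dict[str, float]
    mean_diffs: dict[str, float]

    @property
    def recruited(self) -> bool:
        return self.klass in ("transient", "sustained")


def classify_neuron(
    trial_values: np.ndarray,
    windows: dict[str, tuple[int, int]],
    alpha: float = 0.05,
) -> tuple[str, str, dict[str, float], dict[str, float]]:
    """Classify one neuron's block response from (n_trials, n_frames) values.

    Per period the per-trial means are compared with the per-trial
    baseline means by a paired t-test; the three period p-values are
    Holm-Bonferroni corrected within the neuron.  Returns
    (klass, sign, p_values, mean_diffs).
    """
    if trial_values.ndim != 2 or trial_values.shape[0] < 2:
        raise ValueError("need a (n_trials >= 2, n_frames) array")
    b0, b1 = windows["baseline"]
    baseline = trial_values[:, b0:b1].mean(axis=1)

    p_values: dict[str, float] = {}
    mean_diffs: dict[str, float] = {}
    for period in PERIODS:
        w0, w1 = windows[period]
        means = trial_values[:, w0:w1].mean(axis=1)
        diffs = means - baseline
        mean_diffs[period] = float(diffs.mean())
        if np.all(diffs == diffs[0]):
            # degenerate paired t (zero-variance differences): treat as
            # non-significant rather than raising inside a batch run
            logger.debug("degenerate paired t-test; marking non-significant")
            p_values[period] = 1.0
        else:
            p_values[period] = float(stats.ttest_rel(means, baseline).pvalue)

    reject = holm_bonferroni([p_values[p] for p in PERIODS], alpha=alpha)
    sig = {p: bool(r) for p, r in zip(PERIODS, reject)}

    if not any(sig.values()):
        return "none", "n/a", p_values, mean_diffs
    sig_signs = {np.sign(mean_diffs[p]) for p in PERIODS if sig[p]}
    if len(sig_signs) != 1 or 0 in sig_signs:
        return "other", "n/a", p_values, mean_diffs
    sign = "excited" if sig_signs.pop() > 0 else "inhibited"
    if all(sig.values()):
        return "sustained", sign, p_values, mean_diffs
    if sig["early"] and not sig["middle"] and not sig["late"]:
        return "transient", sign, p_values, mean_diffs
    return "other", sign, p_values, mean_diffs


def classify_session(
    tensor: TrialTensor,
    alpha: float = 0.05,
    excluded_neurons: list[int] | None = None,
) -> pd.DataFrame:
    """Classify every neuron in every block.

    Returns a tidy frame (neuron, block, klass, sign, p_early/mid/late,
    d_early/mid/late).  Neurons listed in ``excluded_neurons`` (e.g.
    zero-variance traces) get klass ``excluded``.
    """
    excluded = set(excluded_neurons or [])
    rows = []
    for block in tensor.blocks:
        vals = tensor.block_trials(block)
        for i in range(tensor.n_neurons):
            if i in excluded or np.any(np.isnan(vals[i])):
                rows.append(
                    {
                        "neuron": i, "block": block, "klass": "excluded", "sign": "n/a",
                        "p_early": np.nan, "p_mid": np.nan, "p_late": np.nan,
                        "d_early": np.nan, "d_mid": np.nan, "d_late": np.nan,
                    }
                )
                continue
            klass, sign, pv, dv = classify_neuron(vals[i], tensor.period_windows, alpha)
            rows.append(
                {
                    "neuron": i, "block": block, "klass": klass, "sign": sign,
                    "p_early": pv["early"], "p_mid": pv["middle"], "p_late": pv["late"],
                    "d_early": dv["early"], "d_mid": dv["middle"], "d_late": dv["late"],
                }
            )
    return pd.DataFrame(rows)


def dose_response(labels: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of each klass x sign per block.

    Fractions are over all classifiable neurons in the block.
    Monotonicity across blocks is a finding, not a constraint.
    """
    out = []
    for block, grp in labels.groupby("block"):
        grp = grp[grp["klass"] != "excluded"]
        total = len(grp)
        for klass in ("transient", "sustained"):
            for sign in ("excited", "inhibited"):
                n = int(((grp["klass"] == klass) & (grp["sign"] == sign)).sum())
                out.append(
                    {
                        "block": block,
                        "klass": klass,
                        "sign": sign,
                        "count": n,
                        "fraction": n / total if total else np.nan,
                        "total": total,
                    }
                )
        n_rec = int(grp["klass"].isin(["transient", "sustained"]).sum())
        out.append(
            {
                "block": block, "klass": "any", "sign": "any",
                "count": n_rec,
                "fraction": n_rec / total if total else np.nan,
                "total": total,
            }
        )
    return pd.DataFrame(out)


def ei_balance(labels: pd.DataFrame, block_id: int) -> tuple[int, int, float]:
    """Excited vs inhibited counts among recruited neurons in a block.

    Balance is tested with a two-sided exact binomial test against 0.5.
    With no recruited neurons the p-value is undefined (NaN).
    """
    grp = labels[(labels["block"] == block_id) & labels["klass"].isin(["transient", "sustained"])]
    n_exc = int((grp["sign"] == "excited").sum())
    n_inh = int((grp["sign"] == "inhibited").sum())
    total = n_exc + n_inh
    if total == 0:
        logger.warning("ei_balance: no recruited neurons in block %s", block_id)
        return 0, 0, float("nan")
    p = stats.binomtest(n_exc, total, 0.5, alternative="two-sided").pvalue
    return n_exc, n_inh, float(p)


def labels_by_block(labels: pd.DataFrame) -> dict[int, dict[int, tuple[str, str]]]:
    """Reshape a label frame into {block: {neuron: (klass, sign)}} for
    the bootstrap consumers, keeping recruited neurons only."""
    out: dict[int, dict[int, tuple[str, str]]] = {}
    rec = labels[labels["klass"].isin(["transient", "sustained"])]
    for block, grp in rec.groupby("block"):
        out[int(block)] = {
            int(r["neuron"]): (r["klass"], r["sign"]) for _, r in grp.iterrows()
        }
    return out
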