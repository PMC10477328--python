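"""Bootstrap statistics for population-level claims.

All null distributions resample neuron identities from the recorded
population (without replacement), mirroring how chance levels are built
for overlap, consistency-of-modulation and spatial statistics.  The
bootstrap p-value is (1 + X) / (N + 1) where X counts null samples at
least as extreme as the observed statistic and N is the number of
bootstrap draws; the effect size is Glass's Delta, standardised by the
null distribution's SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 1000

CLUSTERS = (
    ("transient", "excited"),
    ("transient", "inhibited"),
    ("sustained", "excited"),
    ("sustained", "inhibited"),
)


@dataclass
class BootstrapResult:
    observed: float
    null_samples: np.ndarray
    p: float
    effect_size: float
    ci95: tuple[float, float]
    n_boot: int
    seed: int | None = None
    side: str = "greater"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p": self.p,
            "effect_size": self.effect_size,
            "ci95": list(self.ci95),
            "null_mean": float(np.mean(self.null_samples)),
            "null_sd": float(np.std(self.null_samples, ddof=1)),
            "n_boot": self.n_boot,
            "seed": self.seed,
            "side": self.side,
            **self.extra,
        }


def bootstrap_p(x_overlap_count: int, n_boot: int) -> float:
    """p = (1 + X) / (N + 1) for X extreme null samples out of N draws."""
    if not 0 <= x_overlap_count <= n_boot:
        raise ValueError("need 0 <= X <= N")
    return (1 + x_overlap_count) / (n_boot + 1)


def glass_delta(true_mean: float, null_mean: float, null_sd: float) -> float:
    """Glass's Delta: (observed - null mean) / null SD."""
    if null_sd <= 0:
        raise ValueError("null SD must be positive")
    return (true_mean - null_mean) / null_sd


def summarize_bootstrap(
    observed: float,
    null_samples: np.ndarray,
    side: str = "greater",
    seed: int | None = None,
    **extra,
) -> BootstrapResult:
    """Assemble a full bootstrap record from an observed value and null draws."""
    null_samples = np.asarray(null_samples, dtype=float)
    n = null_samples.size
    if side == "greater":
        x = int(np.sum(null_samples >= observed))
    elif side == "less":
        x = int(np.sum(null_samples <= observed))
    else:
        raise ValueError("side must be 'greater' or 'less'")
    p = bootstrap_p(x, n)
    sd = float(np.std(null_samples, ddof=1))
    delta = glass_delta(observed, float(null_samples.mean()), sd) if sd > 0 else float("nan")
    ci = tuple(np.percentile(null_samples, [2.5, 97.5]))
    return BootstrapResult(
        observed=float(observed),
        null_samples=null_samples,
        p=p,
        effect_size=delta,
        ci95=(float(ci[0]), float(ci[1])),
        n_boot=n,
        seed=seed,
        side=side,
        extra=extra,
    )


# ---------------------------------------------------------------------------
# consistency of modulation


def consistency_statistic(
    labels_by_block: dict[int, dict[int, tuple[str, str]]],
    pool_signs: bool = False,
) -> dict[tuple[str, str] | str, float]:
    """Per-cluster consistency of modulation.

    A functional cluster is a (duration, sign) pair.  For cluster c, the
    denominator counts neurons appearing in c in any block; the
    numerator counts those never appearing in a *different* cluster in
    any block.  Empty clusters yield NaN (undefined, flagged by the
    caller).  With ``pool_signs`` the clusters are duration-only.
    """
    membership: dict[int, set] = {}
    for block_labels in labels_by_block.values():
        for neuron, (klass, sign) in block_labels.items():
            key = klass if pool_signs else (klass, sign)
            membership.setdefault(neuron, set()).add(key)

    clusters = ("transient", "sustained") if pool_signs else CLUSTERS
    out: dict = {}
    for c in clusters:
        members = [n for n, ks in membership.items() if c in ks]
        if not members:
            out[c] = float("nan")
            continue
        pure = [n for n in members if membership[n] == {c}]
        out[c] = len(pure) / len(members)
    return out


def consistency_of_modulation(
    labels_by_block: dict[int, dict[int, tuple[str, str]]],
    universe: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    pool_signs: bool = False,
) -> dict:
    """Observed per-cluster consistency plus its bootstrap null.

    The null preserves, per block, the number of neurons in each cluster
    but draws their identities at random (without replacement within a
    block) from all recorded neurons, then recomputes consistency;
    repeated ``n_boot`` times.
    """
    if len(labels_by_block) < 2:
        raise ValueError("need labels from >= 2 blocks")
    universe = np.asarray(universe)
    rng = np.random.default_rng(seed)
    observed = consistency_statistic(labels_by_block, pool_signs=pool_signs)

    # per block: cluster sizes to preserve under relabeling
    block_sizes = []
    for block, labels in sorted(labels_by_block.items()):
        sizes = {}
        for klass, sign in labels.values():
            key = (klass, sign)
            sizes[key] = sizes.get(key, 0) + 1
        block_sizes.append(sizes)

    clusters = ("transient", "sustained") if pool_signs else CLUSTERS
    null = {c: np.empty(n_boot) for c in clusters}
    for rep in range(n_boot):
        fake: dict[int, dict[int, tuple[str, str]]] = {}
        for bi, sizes in enumerate(block_sizes):
            total = sum(sizes.values())
            drawn = rng.choice(universe, size=total, replace=False)
            fake_labels: dict[int, tuple[str, str]] = {}
            pos = 0
            for key, k in sizes.items():
                for neuron in drawn[pos : pos + k]:
                    fake_labels[int(neuron)] = key
                pos += k
            fake[bi] = fake_labels
        stat = consistency_statistic(fake, pool_signs=pool_signs)
        for c in clusters:
            null[c][rep] = stat[c]

    results = {}
    for c in clusters:
        obs = observed[c]
        if np.isnan(obs):
            logger.warning("consistency: empty cluster %s", c)
            results[c] = {"observed": float("nan"), "result": None}
            continue
        nsamp = null[c][~np.isnan(null[c])]
        if nsamp.size == 0:
            results[c] = {"observed": obs, "result": None}
            continue
        results[c] = {
            "observed": obs,
            "result": summarize_bootstrap(obs, nsamp, side="greater", seed=seed),
        }
    return results


# ---------------------------------------------------------------------------
# population overlap


def population_overlap(
    set_a,
    set_b,
    universe,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> BootstrapResult:
    """Conditional overlap P(B|A) = |A n B| / |A| against a resampling null.

    The null redraws sets of sizes |A| and |B| uniformly without
    replacement from the recorded universe and recomputes the overlap;
    the p-value counts null overlaps at least as large as observed.
    """
    set_a, set_b = set(set_a), set(set_b)
    universe = np.asarray(sorted(set(universe)))
    if not set_a:
        raise ValueError("set_a must be nonempty")
    if not set_a <= set(universe.tolist()) or not set_b <= set(universe.tolist()):
        raise ValueError("sets must be subsets of the universe")
    observed = len(set_a & set_b) / len(set_a)

    rng = np.random.default_rng(seed)
    na, nb = len(set_a), len(set_b)
    null = np.empty(n_boot)
    for rep in range(n_boot):
        a = rng.choice(universe, size=na, replace=False)
        b = rng.choice(universe, size=nb, replace=False)
        null[rep] = len(set(a.tolist()) & set(b.tolist())) / na
    return summarize_bootstrap(observed, null, side="greater", seed=seed)


# ---------------------------------------------------------------------------
# multiple-comparison correction


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down procedure; returns a boolean reject array.

    Sorted p-values p(1) <= ... <= p(m) are compared with
    alpha / (m - i + 1); testing stops at the first failure.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject
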