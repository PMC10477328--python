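"""Synthetic miniscope/wide-field sessions with ground-truth labels.

The generator emulates the experimental layout of block-structured
internal-capsule DBS during single-cell calcium imaging: sessions of
four stimulation blocks (e.g. 0/100/200/300 uA) of eight 80-s trials,
with 60 s of DBS per trial starting 10 s in and ending 10 s before the
trial end, recorded at 15 Hz.  Neurons are planted as transient or
sustained responders, excited or inhibited, with dose-dependent
per-block fractions; behavior streams carry grooming bouts (suppressed
during DBS) and a locomotion speed signal; neuron event trains can be
tuned to grooming and/or locomotion.

Everything is reproducible from a single integer seed, and every
generated session comes with a :class:`GroundTruth` record for
parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from dbsrecruit.session import Session, write_session

RECRUIT_CLASSES = (
    "sustained_excited",
    "sustained_inhibited",
    "transient_excited",
    "transient_inhibited",
)
SPATIAL_PATTERNS = (
    "random",
    "single_cluster",
    "multi_cluster",
    "small_clusters",
    "ring",
    "dispersed",
)


@dataclass
class BehaviorParams:
    """Bout-process parameters for the synthetic behavior streams.

    Grooming is a two-state renewal process: bout and inter-bout
    durations are geometric with the stated means; bouts shorter than
    ``min_bout_frames`` are extended to that length (the upstream
    classifier enforces a 10-frame minimum bout).  The default means
    (3 s bouts, 12 s gaps) put the baseline grooming fraction near 20%
    of the session, matching a compulsive-grooming phenotype.  During
    DBS-on frames each bout survives with probability
    ``dbs_groom_suppression`` (1.0 = no effect, 0.0 = full suppression).
    """

    groom_bout_mean_s: float = 3.0
    groom_interbout_mean_s: float = 12.0
    min_bout_frames: int = 10
    dbs_groom_suppression: float = 0.5
    locomotion_ar: float = 0.97
    locomotion_scale: float = 5.0
    tuned_fractions: dict[str, float] = field(
        default_factory=lambda: {"grooming": 0.10, "locomotion": 0.10, "both": 0.05}
    )
    tuning_gain: float = 8.0


@dataclass
class SynthConfig:
    """Full specification of a synthetic session.

    ``class_fractions`` maps a recruitment class to its per-block
    fraction of all neurons (dose-dependent recruitment); per block the
    fractions must sum to <= 1, the remainder being unmodulated neurons.
    Default fractions ramp from zero in the no-DBS block to roughly a
    quarter of all neurons recruited in the highest-intensity block.
    ``effect_amplitude`` is the evoked DF/F step of a recruited neuron
    (strong evoked transients are of order 1 DF/F).
    """

    n_neurons: int = 100
    frame_rate_hz: float = 15.0
    n_blocks: int = 4
    trials_per_block: int = 8
    trial_len_s: float = 80.0
    dbs_onset_s: float = 10.0
    dbs_len_s: float = 60.0
    iti_s: float = 10.0
    interblock_s: float = 30.0
    class_fractions: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "sustained_excited": (0.0, 0.04, 0.08, 0.12),
            "transient_excited": (0.0, 0.02, 0.04, 0.06),
            "sustained_inhibited": (0.0, 0.02, 0.03, 0.05),
            "transient_inhibited": (0.0, 0.01, 0.02, 0.03),
        }
    )
    effect_amplitude: float = 1.0
    transient_len_s: float = 20.0
    baseline_event_rate_hz: float = 0.1
    event_amp_distribution: tuple[str, dict] = ("exponential", {"scale": 1.0})
    calcium_tau_s: float = 1.5
    noise_sd: float = 0.2
    spatial_pattern: str = "random"
    fov_size_px: float = 400.0
    behavior_params: BehaviorParams = field(default_factory=BehaviorParams)
    anesthetized: bool = False
    control_blocks: tuple[int, ...] | None = None  # None: block 0 iff n_blocks > 1
    seed: int = 0

    def resolved_control_blocks(self) -> tuple[int, ...]:
        """Blocks with the stimulator at zero current (no behavioral
        suppression).  By default the first block of a multi-block
        session is the no-DBS control."""
        if self.control_blocks is not None:
            return self.control_blocks
        return (0,) if self.n_blocks > 1 else ()

    def validate(self) -> None:
        if self.n_neurons < 1 or self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("counts must be positive")
        for name, val in [
            ("frame_rate_hz", self.frame_rate_hz),
            ("trial_len_s", self.trial_len_s),
            ("dbs_len_s", self.dbs_len_s),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_event_rate_hz < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be nonnegative")
        if self.dbs_onset_s + self.dbs_len_s > self.trial_len_s:
            raise ValueError("DBS window exceeds trial length")
        if self.spatial_pattern not in SPATIAL_PATTERNS:
            raise ValueError(f"unknown spatial pattern {self.spatial_pattern!r}")
        for klass, fracs in self.class_fractions.items():
            if klass not in RECRUIT_CLASSES:
                raise ValueError(f"unknown recruitment class {klass!r}")
            if len(fracs) != self.n_blocks:
                raise ValueError(f"{klass}: need one fraction per block")
        for b in range(self.n_blocks):
            total = sum(fracs[b] for fracs in self.class_fractions.values())
            if total > 1:
                raise ValueError(f"block {b}: class fractions sum to {total} > 1")

    def effective_fractions(self) -> dict[str, tuple[float, ...]]:
        """Per-block fractions after the anesthesia rule.

        Under anesthesia, network-driven recruitment is absent: no
        sustained neurons (either sign) and no transient inhibited
        neurons are planted; only transient excited (antidromic)
        recruitment survives.
        """
        if not self.anesthetized:
            return dict(self.class_fractions)
        zero = tuple(0.0 for _ in range(self.n_blocks))
        return {
            k: (v if k == "transient_excited" else zero)
            for k, v in self.class_fractions.items()
        }

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=1, default=list))


@dataclass
class GroundTruth:
    """Planted labels for one synthetic session.

    ``neuron_class`` is (n_neurons, n_blocks) of strings in
    RECRUIT_CLASSES or "none"; ``neuron_sign`` per neuron is the planted
    response direction ("excited" / "inhibited" / "n/a");
    ``behavior_tuning`` per neuron is grooming / locomotion / both /
    none.
    """

    neuron_class: np.ndarray
    neuron_sign: np.ndarray
    behavior_tuning: np.ndarray
    centroids: np.ndarray
    spatial_pattern: str

    def recruited(self, block: int) -> np.ndarray:
        """Indices of neurons planted as recruited in ``block``."""
        return np.flatnonzero(self.neuron_class[:, block] != "none")

    def to_json(self, path: str | Path) -> None:
        d = {
            "neuron_class": self.neuron_class.tolist(),
            "neuron_sign": self.neuron_sign.tolist(),
            "behavior_tuning": self.behavior_tuning.tolist(),
            "centroids": self.centroids.tolist(),
            "spatial_pattern": self.spatial_pattern,
        }
        Path(path).write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------------------
# timing


def build_trial_table(config: SynthConfig) -> tuple[pd.DataFrame, int]:
    """Trial table plus total session frame count for a config.

    Trials within a block are separated by ``iti_s``, blocks by
    ``interblock_s``.  Frames are 0-based, windows half-open.
    """
    rate = config.frame_rate_hz
    trial_frames = int(round(config.trial_len_s * rate))
    onset = int(round(config.dbs_onset_s * rate))
    dbs_frames = int(round(config.dbs_len_s * rate))
    iti = int(round(config.iti_s * rate))
    interblock = int(round(config.interblock_s * rate))

    rows = []
    cursor = 0
    for b in range(config.n_blocks):
        for t in range(config.trials_per_block):
            on = cursor + onset
            rows.append(
                {
                    "block": b,
                    "trial": t,
                    "intensity_label": f"block{b}",
                    "dbs_on_frame": on,
                    "dbs_off_frame": on + dbs_frames,
                }
            )
            cursor += trial_frames
            if t < config.trials_per_block - 1:
                cursor += iti
        if b < config.n_blocks - 1:
            cursor += interblock
    return pd.DataFrame(rows), cursor


# ---------------------------------------------------------------------------
# spatial layouts


def generate_spatial_layout(
    pattern: str,
    n_recruited: int,
    n_total: int,
    fov: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Centroids for all neurons plus the recruited index set.

    Patterns: ``random`` (uniform recruitment), ``single_cluster`` /
    ``multi_cluster`` / ``small_clusters`` (Gaussian blobs of decreasing
    size), ``ring`` (annulus), ``dispersed`` (greedy farthest-point
    placement).  Non-recruited neurons are always uniform over the field
    of view.
    """
    if n_recruited > n_total:
        raise ValueError("n_recruited > n_total")
    if pattern not in SPATIAL_PATTERNS:
        raise ValueError(f"unknown spatial pattern {pattern!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    centroids = rng.uniform(0, fov, size=(n_total, 2))
    recruited = rng.choice(n_total, size=n_recruited, replace=False)
    if n_recruited == 0 or pattern == "random":
        return centroids, np.sort(recruited)

    if pattern in ("single_cluster", "multi_cluster", "small_clusters"):
        n_blobs = {"single_cluster": 1, "multi_cluster": 3, "small_clusters": 5}[pattern]
        sigma = {"single_cluster": 0.04, "multi_cluster": 0.03, "small_clusters": 0.015}[
            pattern
        ] * fov
        # blob centres kept away from the border so blobs stay in view
        centres = rng.uniform(0.2 * fov, 0.8 * fov, size=(n_blobs, 2))
        blob_of = rng.integers(0, n_blobs, size=n_recruited)
        pts = centres[blob_of] + rng.normal(0, sigma, size=(n_recruited, 2))
    elif pattern == "ring":
        centre = np.array([fov / 2, fov / 2])
        radius = 0.2 * fov
        angles = np.linspace(0, 2 * np.pi, n_recruited, endpoint=False)
        angles = angles + rng.normal(0, 0.02, size=n_recruited)
        r = radius + rng.normal(0, 0.01 * fov, size=n_recruited)
        pts = centre + np.c_[r * np.cos(angles), r * np.sin(angles)]
    elif pattern == "dispersed":
        pts = _farthest_points(n_recruited, fov, rng)
    centroids[recruited] = np.clip(pts, 0, np.nextafter(fov, 0))
    return centroids, np.sort(recruited)


def _farthest_points(n: int, fov: float, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point sampling over a dense uniform candidate set."""
    candidates = rng.uniform(0, fov, size=(max(2000, 50 * n), 2))
    # seed with a corner-most candidate to push the set outward
    chosen = [int(np.argmax(np.abs(candidates - fov / 2).sum(axis=1)))]
    d = np.linalg.norm(candidates - candidates[chosen[0]], axis=1)
    for _ in range(1, n):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(candidates - candidates[nxt], axis=1))
    return candidates[chosen]


# ---------------------------------------------------------------------------
# behavior streams


def generate_behavior(
    config: SynthConfig,
    n_frames: int | None = None,
    dbs_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-indexed grooming (binary) and locomotion speed streams.

    Grooming bouts follow the renewal process in
    :class:`BehaviorParams`; bouts overlapping DBS-on frames survive
    with probability ``dbs_groom_suppression`` (the surviving bout keeps
    only its non-suppressed frames if the draw fails).  Locomotion is a
    rectified AR(1) speed signal forced to zero within grooming bouts,
    so grooming and locomotion never co-occur.
    """
    bp = config.behavior_params
    if not 0.0 <= bp.dbs_groom_suppression <= 1.0:
        raise ValueError("dbs_groom_suppression must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed + 104729)
    if n_frames is None:
        trial_table, n_frames = build_trial_table(config)
        dbs_mask = stim_mask(config, trial_table, n_frames)
    if dbs_mask is None:
        dbs_mask = np.zeros(n_frames, dtype=bool)

    rate = config.frame_rate_hz
    p_bout_end = min(1.0, 1.0 / (bp.groom_bout_mean_s * rate))
    p_bout_start = min(1.0, 1.0 / (bp.groom_interbout_mean_s * rate))

    grooming = np.zeros(n_frames, dtype=bool)
    t = 0
    while t < n_frames:
        gap = rng.geometric(p_bout_start)
        t += gap
        if t >= n_frames:
            break
        bout_len = max(int(rng.geometric(p_bout_end)), bp.min_bout_frames)
        stop = min(t + bout_len, n_frames)
        if rng.random() < bp.dbs_groom_suppression:
            grooming[t:stop] = True
        else:
            # suppressed bout: only its DBS-off frames survive
            seg = np.arange(t, stop)
            grooming[seg[~dbs_mask[seg]]] = True
        t = stop

    ar = lfilter([1.0], [1.0, -bp.locomotion_ar], rng.normal(size=n_frames))
    locomotion = np.clip(ar, 0, None) * bp.locomotion_scale * (1 - bp.locomotion_ar)
    locomotion[grooming] = 0.0
    return grooming.astype(float), locomotion


def dbs_mask_from_trials(trial_table: pd.DataFrame, n_frames: int) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for _, row in trial_table.iterrows():
        mask[int(row["dbs_on_frame"]) : int(row["dbs_off_frame"])] = True
    return mask


def stim_mask(config: SynthConfig, trial_table: pd.DataFrame, n_frames: int) -> np.ndarray:
    """DBS-on frames of the actively stimulated (non-control) blocks."""
    control = set(config.resolved_control_blocks())
    active = trial_table[~trial_table["block"].isin(control)]
    return dbs_mask_from_trials(active, n_frames)


# ---------------------------------------------------------------------------
# session generation


def _draw_amplitudes(rng: np.random.Generator, spec: tuple[str, dict], size: int) -> np.ndarray:
    name, params = spec
    if name == "exponential":
        return rng.exponential(params.get("scale", 1.0), size=size)
    if name == "lognormal":
        return rng.lognormal(params.get("mean", 0.0), params.get("sigma", 0.5), size=size)
    if name == "constant":
        return np.full(size, params.get("value", 1.0))
    raise ValueError(f"unknown event amplitude distribution {name!r}")


def _assign_classes(config: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron x per-block class matrix plus per-neuron sign.

    Each class owns a disjoint pool of neurons sized by its maximum
    per-block fraction; within block b the first round(f_b * N) pool
    members are active.  Nested activation keeps a neuron's duration and
    sign identical across blocks, mirroring the consistent recruitment
    seen across stimulation intensities.
    """
    n = config.n_neurons
    fractions = config.effective_fractions()
    classes = np.full((n, config.n_blocks), "none", dtype=object)
    signs = np.full(n, "n/a", dtype=object)

    order = rng.permutation(n)
    cursor = 0
    for klass in RECRUIT_CLASSES:
        fracs = fractions.get(klass)
        if fracs is None:
            continue
        pool_size = int(np.ceil(max(fracs) * n))
        if pool_size == 0:
            continue
        pool = order[cursor : cursor + pool_size]
        if len(pool) < pool_size:
            raise ValueError("class fractions exceed available neurons")
        cursor += pool_size
        sign = "excited" if klass.endswith("excited") else "inhibited"
        signs[pool] = sign
        for b, f in enumerate(fracs):
            k = int(round(f * n))
            if f > 0 and k == 0:
                k = 1  # every planted class with positive fraction gets >= 1 neuron
            classes[pool[:k], b] = klass
    return classes, signs


def _effect_templates(config: SynthConfig) -> dict[str, np.ndarray]:
    """Within-DBS effect waveforms (DF/F added to an excited neuron).

    Sustained: constant ``effect_amplitude`` over the full DBS period.
    Transient: a decaying box over the first ``transient_len_s`` seconds
    (amplitude falling linearly to zero), truncated at the window end.
    """
    rate = config.frame_rate_hz
    n_dbs = int(round(config.dbs_len_s * rate))
    n_tr = min(int(round(config.transient_len_s * rate)), n_dbs)
    sustained = np.full(n_dbs, config.effect_amplitude)
    transient = np.zeros(n_dbs)
    transient[:n_tr] = config.effect_amplitude * np.linspace(1.0, 0.0, n_tr, endpoint=False)
    return {"sustained": sustained, "transient": transient}


def generate_session(config: SynthConfig) -> tuple[Session, GroundTruth]:
    """Generate a full synthetic session plus its ground truth.

    Traces are the sum of (i) baseline Poisson events (amplitudes from
    ``event_amp_distribution``) convolved with a single-exponential
    calcium kernel (tau = ``calcium_tau_s``), (ii) the class-specific
    stimulation waveform for planted neurons in their active blocks, and
    (iii) white Gaussian noise of SD ``noise_sd``.  The emitted event
    train is the planted train itself (the generator emulates the output
    of source extraction and deconvolution, not the raw video).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    trial_table, n_frames = build_trial_table(config)
    dbs_mask = stim_mask(config, trial_table, n_frames)
    rate = config.frame_rate_hz
    n = config.n_neurons

    classes, signs = _assign_classes(config, rng)

    # behavior streams + per-neuron behavior tuning
    grooming, locomotion = generate_behavior(config, n_frames, dbs_mask, rng)
    bp = config.behavior_params
    tuning = np.full(n, "none", dtype=object)
    perm = rng.permutation(n)
    cursor = 0
    for kind, frac in bp.tuned_fractions.items():
        k = int(round(frac * n))
        tuning[perm[cursor : cursor + k]] = kind
        cursor += k

    nz = locomotion[grooming == 0]
    loco_thresh = np.median(nz) if nz.size else 0.0
    groom_frames = grooming > 0
    loco_frames = (locomotion > loco_thresh) & ~groom_frames

    # event trains: Bernoulli per frame with behavior-dependent gain
    p_base = min(1.0, config.baseline_event_rate_hz / rate)
    gain = np.ones((n, n_frames))
    gain[tuning == "grooming"] = np.where(groom_frames, bp.tuning_gain, 1.0)
    gain[tuning == "locomotion"] = np.where(loco_frames, bp.tuning_gain, 1.0)
    gain[tuning == "both"] = np.where(groom_frames | loco_frames, bp.tuning_gain, 1.0)
    p = np.minimum(p_base * gain, 1.0)
    occur = rng.random((n, n_frames)) < p
    events = np.zeros((n, n_frames))
    n_ev = int(occur.sum())
    if n_ev:
        events[occur] = _draw_amplitudes(rng, config.event_amp_distribution, n_ev)

    # calcium kernel: exponential decay, implemented as an AR(1) filter
    decay = np.exp(-1.0 / (config.calcium_tau_s * rate))
    traces = lfilter([1.0], [1.0, -decay], events, axis=1)

    # stimulation effects
    templates = _effect_templates(config)
    for b in range(config.n_blocks):
        block_trials = trial_table[trial_table["block"] == b]
        for i in range(n):
            klass = classes[i, b]
            if klass == "none":
                continue
            duration = "sustained" if klass.startswith("sustained") else "transient"
            waveform = templates[duration]
            if signs[i] == "inhibited":
                waveform = -waveform
            for _, row in block_trials.iterrows():
                on = int(row["dbs_on_frame"])
                traces[i, on : on + waveform.size] += waveform

    if config.noise_sd > 0:
        traces = traces + rng.normal(0, config.noise_sd, size=traces.shape)

    # spatial layout: recruited set = union of planted neurons in the
    # highest-intensity block
    recruited_last = np.flatnonzero(classes[:, -1] != "none")
    centroids = np.empty((n, 2))
    pattern_centroids, pattern_idx = generate_spatial_layout(
        config.spatial_pattern, len(recruited_last), n, config.fov_size_px, rng
    )
    # map the pattern's recruited slots onto the planted neurons
    rest = np.setdiff1d(np.arange(n), recruited_last)
    pattern_rest = np.setdiff1d(np.arange(n), pattern_idx)
    centroids[recruited_last] = pattern_centroids[pattern_idx]
    centroids[rest] = pattern_centroids[pattern_rest]

    behavior = pd.DataFrame({"grooming": grooming, "locomotion": locomotion})
    session = Session(
        traces=traces,
        events=events,
        centroids=centroids,
        trial_table=trial_table,
        frame_rate_hz=rate,
        behavior=behavior,
        genotype="synthetic",
    )
    session.validate()
    gt = GroundTruth(
        neuron_class=classes,
        neuron_sign=signs,
        behavior_tuning=tuning,
        centroids=centroids,
        spatial_pattern=config.spatial_pattern,
    )
    return session, gt


def write_synthetic_session(config: SynthConfig, outdir: str | Path) -> Path:
    """Generate and persist a session, its ground truth and config."""
    outdir = Path(outdir)
    session, gt = generate_session(config)
    write_session(session, outdir)
    gt.to_json(outdir / "ground_truth.json")
    config.to_json(outdir / "config.json")
    return outdir


# ---------------------------------------------------------------------------
# wide-field fixtures


def generate_widefield_stack(
    n_trials: int = 3,
    n_blocks: int = 1,
    height: int = 64,
    width: int = 64,
    frame_rate_hz: float = 20.0,
    trial_len_s: float = 30.0,
    dbs_onset_s: float = 10.0,
    dbs_len_s: float = 15.0,
    baseline_level: float = 100.0,
    texture_sd: float = 10.0,
    activity_sd: float = 0.02,
    noise_sd: float = 1.0,
    suppressed_region: str | None = "FC",
    suppression_depth: float | tuple[float, ...] = 0.2,
    shifts: np.ndarray | None = None,
    seed: int = 0,
):
    """Synthetic wide-field stack with four rectangular region masks.

    A static spatial texture rides on ``baseline_level``; each region
    carries its own slow multiplicative activity fluctuation (AR(1),
    fractional SD ``activity_sd``), emulating ongoing cortical dynamics.
    The ``suppressed_region`` ramps down by ``suppression_depth``
    (relative; scalar or one value per block) over each DBS period.
    Optional per-frame integer ``shifts`` (T, 2) apply circular rigid
    displacement for motion-correction tests.  Returns (stack: ndarray
    (T, H, W), masks: dict, trial_table: DataFrame, frame_rate).
    """
    rng = np.random.default_rng(seed)
    rate = frame_rate_hz
    trial_frames = int(round(trial_len_s * rate))
    n_frames = n_blocks * n_trials * trial_frames
    depths = (
        tuple(suppression_depth)
        if np.ndim(suppression_depth)
        else (float(suppression_depth),) * n_blocks
    )
    if len(depths) != n_blocks:
        raise ValueError("need one suppression depth per block")
    rows = []
    for b in range(n_blocks):
        for t in range(n_trials):
            on = (b * n_trials + t) * trial_frames + int(round(dbs_onset_s * rate))
            rows.append(
                {
                    "block": b,
                    "trial": t,
                    "intensity_label": f"block{b}",
                    "dbs_on_frame": on,
                    "dbs_off_frame": on + int(round(dbs_len_s * rate)),
                }
            )
    trial_table = pd.DataFrame(rows)

    h2, w2 = height // 2, width // 2
    masks = {
        "FC": np.zeros((height, width), dtype=bool),
        "SS": np.zeros((height, width), dtype=bool),
        "RSP": np.zeros((height, width), dtype=bool),
        "VIS": np.zeros((height, width), dtype=bool),
    }
    masks["FC"][:h2, :w2] = True
    masks["SS"][:h2, w2:] = True
    masks["RSP"][h2:, :w2] = True
    masks["VIS"][h2:, w2:] = True

    texture = baseline_level + rng.normal(0, texture_sd, size=(height, width))
    texture = np.clip(texture, baseline_level * 0.5, None)
    stack = np.tile(texture, (n_frames, 1, 1))

    if activity_sd > 0:
        a = 0.95
        for mask in masks.values():
            ar = lfilter([1.0], [1.0, -a], rng.normal(size=n_frames))
            ar *= activity_sd * np.sqrt(1 - a**2)
            stack[:, mask] *= (1.0 + ar)[:, None]

    region_mod = np.ones(n_frames)
    for _, row in trial_table.iterrows():
        on, off = int(row["dbs_on_frame"]), int(row["dbs_off_frame"])
        ramp = np.linspace(0, depths[int(row["block"])], off - on)
        region_mod[on:off] = 1.0 - ramp
    if suppressed_region is not None:
        stack[:, masks[suppressed_region]] *= region_mod[:, None]
    if noise_sd > 0:
        stack = stack + rng.normal(0, noise_sd, size=stack.shape)
    if shifts is not None:
        for t, (dy, dx) in enumerate(shifts):
            stack[t] = np.roll(stack[t], (int(dy), int(dx)), axis=(0, 1))
    return stack, masks, trial_table, rate
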