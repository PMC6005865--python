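"""Synthetic data generation for the altered-auditory-feedback piano paradigm.

Emulates the study conditions of a sensorimotor sequence-learning MEG
experiment: subjects play short (4-5 note) piano sequences continuously in
15-trial blocks of 23 s at a metronome-induced 200 bpm tempo, while the
auditory feedback of occasional keystrokes is altered (AF).  AF events are
inserted between every 8th and 10th produced note, never on trials 1, 6 and
10 of a block, and coincide with either a boundary (Bo: first or last) or a
within-sequence (In) ordinal position.  Configurable ground-truth effects —
post-AF slowing of the next inter-onset interval, an error-probability
boost in the five keystrokes after AF, and condition-specific evoked-field
templates on designated sensor groups — let every downstream analysis stage
be validated against known truth.

The sensor model is a planar-gradiometer-pair array: two orthogonal
gradient channels per position, with a 2-D layout and a distance-threshold
adjacency graph.  Recordings are AR(1)-plus-white noise with additive
condition templates; triggers lag keystrokes by the MIDI trigger delay
(20-25 ms in the hardware being emulated).  A toy forward model (smooth
leadfield over a 3-D grid partitioned into named regions) supports
closed-loop minimum-norm inverse tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "ErfEffect",
    "SimulationConfig",
    "SensorLayout",
    "ContinuousRecording",
    "ForwardModel",
    "generate_performance",
    "generate_sensor_layout",
    "generate_recording",
    "generate_recordings",
    "generate_forward",
    "project_sources",
    "simulate_condition_erfs",
    "condition_label",
    "DEFAULT_PATTERNS",
]

# Six explicitly taught 4-5 note right-hand patterns (MIDI pitches around
# middle C), mirroring the mixed 4- and 5-note design of the paradigm.
DEFAULT_PATTERNS: tuple[tuple[int, ...], ...] = (
    (60, 62, 64, 65, 67),
    (60, 64, 62, 67, 65),
    (62, 60, 65, 64, 67),
    (60, 62, 65, 64),
    (62, 65, 60, 67),
    (64, 60, 67, 62),
)

CONDITIONS = ("NF-Bo", "NF-In", "AF-Bo", "AF-In")


def condition_label(feedback: str, position_class: str) -> str:
    return f"{feedback}-{position_class}"


@dataclass(frozen=True)
class ErfEffect:
    """A planted evoked-field template.

    Deposited additively at every keystroke whose condition label
    (e.g. ``"AF-Bo"``) is in ``conditions``, on both gradiometer channels
    of the pair positions named by ``sensor_group`` (a group name from the
    layout, or an explicit sequence of pair indices), as a Hanning bump of
    ``amplitude`` spanning ``window`` seconds relative to the keystroke.
    """

    conditions: tuple[str, ...]
    sensor_group: str | tuple[int, ...]
    window: tuple[float, float]
    amplitude: float
    polarity: int = 1

    def __post_init__(self):
        t0, t1 = self.window
        if not (-1.0 <= t0 < t1 <= 1.0):
            raise ValueError(
                f"effect window {self.window} outside the [-1, 1] s epoch range")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


def _zeros_by_class() -> dict:
    return {"Bo": 0.0, "In": 0.0}


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic experiment.

    Defaults reproduce the emulated study conditions: 20 subjects, six
    4-5 note patterns, 15 trials of 23 s per block at 200 bpm, AF spacing
    uniform on 8-10 keystrokes, AF-free trials {1, 6, 10}, and a MIDI
    trigger delay of 22.5 ms (midpoint of the 20-25 ms hardware range).
    ``slowing_effect`` (ms added to the inter-onset interval following an
    AF event) and ``error_boost`` (increment of the probability that at
    least one pitch error occurs within the five keystrokes after an AF
    event) are specified separately per ordinal class {"Bo", "In"}.
    """

    n_subjects: int = 20
    sequence_patterns: tuple[tuple[int, ...], ...] = DEFAULT_PATTERNS
    trials_per_block: int = 15
    trial_duration: float = 23.0           # s
    tempo: float = 200.0                   # beats per minute
    af_spacing: tuple[int, int] = (8, 10)  # keystrokes between AF events
    af_spacing_weights: tuple[float, ...] | None = None
    af_free_trials: frozenset = frozenset({1, 6, 10})
    slowing_effect: dict = field(default_factory=_zeros_by_class)   # ms
    error_boost: dict = field(default_factory=_zeros_by_class)      # prob.
    baseline_error_prob: float = 0.001     # per keystroke
    error_horizon: int = 5                 # keystrokes after AF
    ioi_noise_sd: float = 70.0             # ms
    min_ioi: float = 1.0                   # ms, keeps onsets monotonic
    midi_trigger_delay: float = 22.5       # ms
    velocity_mean: float = 64.0
    velocity_sd: float = 8.0
    erf_effects: tuple[ErfEffect, ...] = ()
    noise_ar1: float = 0.9                 # AR(1) coefficient of sensor noise
    noise_sd: float = 1.0                  # white innovation sd
    sfreq: float = 1000.0                  # Hz
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.af_spacing
        if not (2 <= lo <= hi):
            raise ValueError("af_spacing must satisfy 2 <= min <= max")
        for pat in self.sequence_patterns:
            if len(pat) not in (4, 5):
                raise ValueError("sequence patterns must have length 4 or 5")
        for name, p in (("baseline_error_prob", self.baseline_error_prob),
                        ("error_boost[Bo]", self.error_boost["Bo"]),
                        ("error_boost[In]", self.error_boost["In"])):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.trial_duration <= 0 or self.tempo <= 0:
            raise ValueError("trial_duration and tempo must be positive")
        if self.af_spacing_weights is not None and \
                len(self.af_spacing_weights) != hi - lo + 1:
            raise ValueError("af_spacing_weights must have one weight per "
                             "spacing in af_spacing")

    @property
    def nominal_ioi(self) -> float:
        """Nominal inter-onset interval in ms (60000 / tempo)."""
        return 60000.0 / self.tempo

    def to_dict(self) -> dict:
        d = asdict(self)
        d["af_free_trials"] = sorted(self.af_free_trials)
        d["erf_effects"] = [asdict(e) for e in self.erf_effects]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "af_free_trials" in d:
            d["af_free_trials"] = frozenset(d["af_free_trials"])
        if "sequence_patterns" in d:
            d["sequence_patterns"] = tuple(tuple(p) for p in d["sequence_patterns"])
        if "af_spacing" in d:
            d["af_spacing"] = tuple(d["af_spacing"])
        if "erf_effects" in d:
            effects = []
            for e in d["erf_effects"]:
                e = dict(e)
                e["conditions"] = tuple(e["conditions"])
                e["window"] = tuple(e["window"])
                g = e["sensor_group"]
                if not isinstance(g, str):
                    e["sensor_group"] = tuple(g)
                effects.append(ErfEffect(**e))
            d["erf_effects"] = tuple(effects)
        return cls(**d)


# ---------------------------------------------------------------------------
# performance events
# ---------------------------------------------------------------------------

def _position_class(idx: np.ndarray, pattern_len: int) -> np.ndarray:
    pos = idx % pattern_len
    return np.where((pos == 0) | (pos == pattern_len - 1), "Bo", "In")


def _place_af(n_keys: int, pattern_len: int, config: SimulationConfig,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """AF keystroke indices and their target classes for one trial.

    Spacings are drawn from af_spacing (uniform unless weights are given).
    Target class alternates Bo/In with a random phase per trial; among the
    admissible spacings the draw is restricted to those landing on the
    target class when possible, so conditions stay balanced.
    """
    lo, hi = config.af_spacing
    if lo >= n_keys:
        raise ValueError(
            f"AF spacing minimum {lo} exceeds the {n_keys} keystrokes of a "
            "trial; no AF event could be placed")
    weights = np.asarray(config.af_spacing_weights
                         if config.af_spacing_weights is not None
                         else np.ones(hi - lo + 1), dtype=float)
    weights = weights / weights.sum()
    spacings = np.arange(lo, hi + 1)

    target = rng.choice(["Bo", "In"])
    prev = -1
    indices, classes = [], []
    while True:
        cand = prev + spacings
        valid = cand < n_keys
        if not valid.any():
            break
        cls = _position_class(cand, pattern_len)
        match = valid & (cls == target)
        pool = match if match.any() else valid
        w = weights * pool
        s = rng.choice(spacings, p=w / w.sum())
        idx = prev + s
        indices.append(idx)
        classes.append(str(_position_class(np.array([idx]), pattern_len)[0]))
        prev = idx
        target = "In" if target == "Bo" else "Bo"
    return np.asarray(indices, dtype=int), np.asarray(classes)


def generate_performance(config: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Generate the keystroke event table for the whole experiment.

    Returns one row per keystroke with columns: subject, block, trial
    (global), trial_in_block, pattern_id, keystroke_index, onset_ms (within
    trial), pitch_played, pitch_heard, velocity, seq_position (1-based),
    position_class {Bo, In}, feedback {NF, AF}, is_error, and ground-truth
    columns gt_error_prob and gt_slowing_ms.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nominal = config.nominal_ioi
    n_keys = int(config.trial_duration * 1000.0 / nominal) + 1
    horizon = config.error_horizon

    rows: dict[str, list] = {k: [] for k in (
        "subject", "block", "trial", "trial_in_block", "pattern_id",
        "keystroke_index", "onset_ms", "pitch_played", "pitch_heard",
        "velocity", "seq_position", "position_class", "feedback",
        "is_error", "gt_error_prob", "gt_slowing_ms")}

    n_blocks = len(config.sequence_patterns)
    for subj in range(1, config.n_subjects + 1):
        for block in range(n_blocks):
            pattern = np.asarray(config.sequence_patterns[block])
            L = len(pattern)
            for tib in range(1, config.trials_per_block + 1):
                trial = block * config.trials_per_block + tib
                iois = nominal + rng.normal(0.0, config.ioi_noise_sd,
                                            n_keys - 1)
                np.clip(iois, config.min_ioi, None, out=iois)

                idx = np.arange(n_keys)
                if tib in config.af_free_trials:
                    af_idx = np.empty(0, dtype=int)
                    af_cls = np.empty(0, dtype=object)
                else:
                    af_idx, af_cls = _place_af(n_keys, L, config, rng)

                slowing = np.zeros(n_keys)
                err_prob = np.full(n_keys, config.baseline_error_prob)
                for k, c in zip(af_idx, af_cls):
                    if k < n_keys - 1:
                        iois[k] += config.slowing_effect[c]
                        slowing[k] = config.slowing_effect[c]
                    err_prob[k + 1:k + 1 + horizon] += \
                        config.error_boost[c] / horizon
                np.clip(err_prob, 0.0, 1.0, out=err_prob)
                onsets = np.concatenate(([0.0], np.cumsum(iois)))

                is_err = rng.random(n_keys) < err_prob
                pitch_true = pattern[idx % L]
                pitch_played = pitch_true.copy()
                if is_err.any():
                    pitch_played[is_err] = pitch_true[is_err] + rng.choice(
                        [-2, -1, 1, 2], size=int(is_err.sum()))
                pitch_heard = pitch_played.copy()
                if af_idx.size:
                    # altered feedback: a tone from a different serial
                    # position of the same pattern
                    shift = rng.integers(1, L, size=af_idx.size)
                    pitch_heard[af_idx] = pattern[(af_idx + shift) % L]

                feedback = np.full(n_keys, "NF", dtype=object)
                feedback[af_idx] = "AF"

                rows["subject"].append(np.full(n_keys, subj))
                rows["block"].append(np.full(n_keys, block + 1))
                rows["trial"].append(np.full(n_keys, trial))
                rows["trial_in_block"].append(np.full(n_keys, tib))
                rows["pattern_id"].append(np.full(n_keys, block))
                rows["keystroke_index"].append(idx)
                rows["onset_ms"].append(onsets)
                rows["pitch_played"].append(pitch_played)
                rows["pitch_heard"].append(pitch_heard)
                rows["velocity"].append(rng.normal(config.velocity_mean,
                                                   config.velocity_sd,
                                                   n_keys))
                rows["seq_position"].append(idx % L + 1)
                rows["position_class"].append(_position_class(idx, L))
                rows["feedback"].append(feedback)
                rows["is_error"].append(is_err)
                rows["gt_error_prob"].append(err_prob)
                rows["gt_slowing_ms"].append(slowing)

    return pd.DataFrame({k: np.concatenate(v) for k, v in rows.items()})


# ---------------------------------------------------------------------------
# sensor layout
# ---------------------------------------------------------------------------

@dataclass
class SensorLayout:
    """A planar-gradiometer-pair array.

    ``positions`` are the 2-D pair positions; each pair contributes two
    channels (h then v) so sensor i of pair p sits at
    ``sensor_names[2p + i]``.  ``adjacency`` is a symmetric, irreflexive
    boolean matrix over pair positions.
    """

    positions: np.ndarray            # (n_pairs, 2)
    pair_names: list[str]
    sensor_names: list[str]          # 2 * n_pairs, interleaved h/v
    adjacency: np.ndarray            # (n_pairs, n_pairs) bool
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    threshold: float = 0.0

    @property
    def n_pairs(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sensors(self) -> int:
        return 2 * self.n_pairs

    @property
    def h_idx(self) -> np.ndarray:
        return np.arange(0, self.n_sensors, 2)

    @property
    def v_idx(self) -> np.ndarray:
        return np.arange(1, self.n_sensors, 2)

    def group_pairs(self, group: str | Sequence[int]) -> np.ndarray:
        if isinstance(group, str):
            try:
                return self.groups[group]
            except KeyError:
                raise KeyError(f"unknown sensor group {group!r}; known: "
                               f"{sorted(self.groups)}") from None
        return np.asarray(group, dtype=int)

    def group_sensors(self, group: str | Sequence[int]) -> np.ndarray:
        pairs = self.group_pairs(group)
        return np.sort(np.concatenate([2 * pairs, 2 * pairs + 1]))


def _make_groups(positions: np.ndarray) -> dict[str, np.ndarray]:
    x, y = positions[:, 0], positions[:, 1]
    y0, y1 = y.min(), y.max()
    x0, x1 = x.min(), x.max()
    thirds = np.array([y0 + (y1 - y0) / 3, y0 + 2 * (y1 - y0) / 3])
    groups = {
        "frontal": np.nonzero(y > thirds[1] - 1e-12)[0],
        "central": np.nonzero((y > thirds[0] + 1e-12) &
                              (y <= thirds[1] - 1e-12))[0],
        "posterior": np.nonzero(y <= thirds[0] + 1e-12)[0],
        "temporal_left": np.nonzero(x <= x0 + 0.25 * (x1 - x0) + 1e-12)[0],
        "temporal_right": np.nonzero(x >= x1 - 0.25 * (x1 - x0) - 1e-12)[0],
    }
    return {k: v for k, v in groups.items() if v.size}


def generate_sensor_layout(n_pairs: int,
                           geometry: str | np.ndarray = "grid",
                           spacing: float = 1.0,
                           adjacency_threshold: float | None = None,
                           rng: np.random.Generator | None = None,
                           ) -> SensorLayout:
    """Build a planar-pair sensor layout with a distance-threshold adjacency.

    ``geometry`` is ``"grid"`` (square-ish grid with step ``spacing``),
    ``"random"`` (uniform in a square), or an explicit (n_pairs, 2) array
    of positions.  Two pairs are adjacent when their distance is at most
    ``adjacency_threshold`` (default: 1.01 x spacing for grids, 1.5 x the
    median nearest-neighbour distance otherwise).
    """
    if n_pairs < 4:
        raise ValueError("need at least 4 sensor pairs")
    if isinstance(geometry, str):
        if geometry == "grid":
            rows = int(np.floor(np.sqrt(n_pairs)))
            cols = int(np.ceil(n_pairs / rows))
            xx, yy = np.meshgrid(np.arange(cols), np.arange(rows))
            positions = np.column_stack([xx.ravel(), yy.ravel()])[:n_pairs]
            positions = positions.astype(float) * spacing
            default_thr = 1.01 * spacing
        elif geometry == "random":
            if rng is None:
                rng = np.random.default_rng(0)
            side = np.sqrt(n_pairs) * spacing
            positions = rng.uniform(0, side, size=(n_pairs, 2))
            default_thr = None
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
    else:
        positions = np.asarray(geometry, dtype=float)
        if positions.shape != (n_pairs, 2):
            raise ValueError("explicit geometry must be (n_pairs, 2)")
        default_thr = None

    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    off = ~np.eye(n_pairs, dtype=bool)
    if dist[off].min() < 1e-9:
        raise ValueError("degenerate geometry: coincident sensor positions")
    if default_thr is None:
        nn = np.where(off, dist, np.inf).min(axis=1)
        default_thr = 1.5 * float(np.median(nn))
    thr = adjacency_threshold if adjacency_threshold is not None else default_thr

    adjacency = (dist <= thr) & off

    pair_names = [f"P{i:03d}" for i in range(n_pairs)]
    sensor_names = []
    for p in pair_names:
        sensor_names += [p + "h", p + "v"]
    return SensorLayout(positions=positions, pair_names=pair_names,
                        sensor_names=sensor_names, adjacency=adjacency,
                        groups=_make_groups(positions), threshold=float(thr))


# ---------------------------------------------------------------------------
# continuous recordings
# ---------------------------------------------------------------------------

@dataclass
class ContinuousRecording:
    """One subject's continuous multi-sensor recording with triggers."""

    data: np.ndarray                  # (n_sensors, n_samples)
    sfreq: float
    triggers: np.ndarray              # trigger sample indices (post MIDI delay)
    events: pd.DataFrame              # one row per trigger (condition, trial, ...)
    baseline_segments: list[tuple[int, int]]   # pre-trial noise spans (samples)
    sensor_names: list[str]


def _ar1_noise(shape: tuple[int, int], phi: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    w = rng.normal(0.0, sd, size=shape)
    if phi == 0.0:
        return w
    return lfilter([1.0], [1.0, -phi], w, axis=-1)


def _hanning_template(window: tuple[float, float], sfreq: float) -> np.ndarray:
    n = max(int(round((window[1] - window[0]) * sfreq)), 2)
    return np.hanning(n)


def generate_recording(events: pd.DataFrame, subject: int,
                       layout: SensorLayout, config: SimulationConfig,
                       rng: np.random.Generator,
                       pre_trial_gap: float = 3.0,
                       post_trial_gap: float = 1.5) -> ContinuousRecording:
    """Synthesize one subject's continuous recording.

    Trials from the event table are laid out sequentially, each preceded by
    ``pre_trial_gap`` seconds of performance-free noise (the span used for
    noise-covariance estimation, excluding the 1.2 s immediately before the
    first keystroke which falls into its epoch window).  Every keystroke of
    a condition matched by an ``ErfEffect`` deposits the effect template on
    the group's sensors; triggers are recorded at keystroke time plus the
    MIDI trigger delay.
    """
    ev = events[events["subject"] == subject]
    if ev.empty:
        raise ValueError(f"no events for subject {subject}")
    sf = config.sfreq
    gap = int(round(pre_trial_gap * sf))
    post = int(round(post_trial_gap * sf))
    trial_len = int(round(config.trial_duration * 1000.0)) + post

    trials = np.sort(ev["trial"].unique())
    offsets = {}
    cursor = 0
    baseline_segments = []
    for t in trials:
        cursor += gap
        offsets[t] = cursor
        baseline_segments.append((cursor - gap, cursor - int(1.2 * sf)))
        cursor += trial_len
    n_samples = cursor + post

    n_sensors = layout.n_sensors
    data = _ar1_noise((n_sensors, n_samples), config.noise_ar1,
                      config.noise_sd, rng)

    trial_offset = ev["trial"].map(offsets).to_numpy()
    key_samples = trial_offset + np.round(
        ev["onset_ms"].to_numpy() / 1000.0 * sf).astype(int)
    cond = (ev["feedback"].astype(str) + "-" +
            ev["position_class"].astype(str)).to_numpy()

    for eff in config.erf_effects:
        tmpl = _hanning_template(eff.window, sf) * eff.amplitude * eff.polarity
        n_t = tmpl.size
        off0 = int(round(eff.window[0] * sf))
        sens = layout.group_sensors(eff.sensor_group)
        for ks in key_samples[np.isin(cond, eff.conditions)]:
            start = ks + off0
            if start < 0 or start + n_t > n_samples:
                continue
            data[np.ix_(sens, np.arange(start, start + n_t))] += tmpl

    delay = int(round(config.midi_trigger_delay / 1000.0 * sf))
    triggers = key_samples + delay

    info = ev[["trial", "trial_in_block", "keystroke_index", "onset_ms",
               "velocity", "feedback", "position_class", "is_error"]].copy()
    info["condition"] = cond
    info["keystroke_sample"] = key_samples
    info = info.reset_index(drop=True)

    return ContinuousRecording(data=data, sfreq=sf, triggers=triggers,
                               events=info,
                               baseline_segments=baseline_segments,
                               sensor_names=list(layout.sensor_names))


def generate_recordings(events: pd.DataFrame, layout: SensorLayout,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        **kwargs) -> Iterable[tuple[int, ContinuousRecording]]:
    """Yield (subject, ContinuousRecording) lazily, one subject at a time."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    for subject in np.sort(events["subject"].unique()):
        yield int(subject), generate_recording(events, int(subject), layout,
                                               config, rng, **kwargs)


# ---------------------------------------------------------------------------
# toy forward model
# ---------------------------------------------------------------------------

@dataclass
class ForwardModel:
    """Toy leadfield over a 3-D source grid with a named region partition."""

    leadfield: np.ndarray     # (n_sensors, n_grid)
    grid_coords: np.ndarray   # (n_grid, 3)
    region_labels: np.ndarray  # (n_grid,) str
    sensor_names: list[str]

    @property
    def n_grid(self) -> int:
        return self.grid_coords.shape[0]

    def grid_adjacency(self, radius: float | None = None) -> np.ndarray:
        """Boolean neighbourhood matrix of grid points within ``radius``
        (default: 1.5 x the median nearest-neighbour distance)."""
        diff = self.grid_coords[:, None, :] - self.grid_coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(-1))
        off = ~np.eye(self.n_grid, dtype=bool)
        if radius is None:
            nn = np.where(off, dist, np.inf).min(axis=1)
            radius = 1.5 * float(np.median(nn))
        return (dist <= radius) & off


def _octant_regions(coords: np.ndarray, n_regions: int) -> np.ndarray:
    """Partition grid points into 2/4/8 regions by coordinate medians."""
    n_axes = int(np.log2(n_regions))
    med = np.median(coords, axis=0)
    labels = []
    names = (("L", "R"), ("Post", "Ant"), ("Inf", "Sup"))
    for g in coords:
        parts = [names[a][int(g[a] >= med[a])] for a in range(n_axes)]
        labels.append("-".join(parts))
    return np.asarray(labels)


def generate_forward(n_grid: int, layout: SensorLayout,
                     rng: np.random.Generator | None = None,
                     n_regions: int = 8,
                     depth_range: tuple[float, float] = (2.0, 6.0),
                     sensor_height: float = 8.0,
                     falloff_sigma: float = 3.0,
                     smoothing_sigma: float = 0.8) -> ForwardModel:
    """Build a smooth toy leadfield above a random 3-D source grid.

    Grid points are uniform in the box spanned by the sensor layout (with a
    margin), at depths ``depth_range`` below the sensor plane at
    ``sensor_height``.  The two channels of each pair respond to the x- and
    y-displacement of a source weighted by a Gaussian distance falloff
    (a planar-gradient-like sensitivity); columns are then smoothed over
    neighbouring grid points with a Gaussian kernel of ``smoothing_sigma``.
    """
    if n_regions not in (2, 4, 8):
        raise ValueError("n_regions must be 2, 4 or 8")
    if n_grid < n_regions:
        raise ValueError("n_grid must be at least the number of regions")
    if rng is None:
        rng = np.random.default_rng(0)
    pos = layout.positions
    lo = pos.min(axis=0) - 1.0
    hi = pos.max(axis=0) + 1.0
    coords = np.column_stack([
        rng.uniform(lo[0], hi[0], n_grid),
        rng.uniform(lo[1], hi[1], n_grid),
        rng.uniform(depth_range[0], depth_range[1], n_grid),
    ])

    sens3d = np.column_stack([pos, np.full(len(pos), sensor_height)])
    diff = sens3d[:, None, :] - coords[None, :, :]      # (n_pairs, n_grid, 3)
    r2 = (diff ** 2).sum(-1)
    fall = np.exp(-r2 / (2 * falloff_sigma ** 2))
    lf = np.empty((layout.n_sensors, n_grid))
    lf[0::2] = diff[:, :, 0] / falloff_sigma * fall     # h channels
    lf[1::2] = diff[:, :, 1] / falloff_sigma * fall     # v channels

    # spatial smoothing across neighbouring grid points (skipped at sigma 0)
    if smoothing_sigma > 0:
        gdiff = coords[:, None, :] - coords[None, :, :]
        k = np.exp(-(gdiff ** 2).sum(-1) / (2 * smoothing_sigma ** 2))
        k /= k.sum(axis=0, keepdims=True)
        lf = lf @ k

    col_norm = np.linalg.norm(lf, axis=0)
    if np.any(col_norm == 0.0):
        raise ValueError("leadfield has an all-zero column")
    if np.linalg.matrix_rank(lf) == 0:
        raise ValueError("rank-0 leadfield")

    return ForwardModel(leadfield=lf, grid_coords=coords,
                        region_labels=_octant_regions(coords, n_regions),
                        sensor_names=list(layout.sensor_names))


def project_sources(fm: ForwardModel, source_timecourses: np.ndarray,
                    noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Project source currents to sensors: data = L @ s (+ white noise).

    ``source_timecourses`` is (n_grid, n_times) or (n_trials, n_grid,
    n_times); the output has n_grid replaced by n_sensors.
    """
    s = np.asarray(source_timecourses, dtype=float)
    if s.shape[-2] != fm.n_grid:
        raise ValueError("source array's grid axis does not match the model")
    data = np.einsum("sg,...gt->...st", fm.leadfield, s)
    if noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng(0)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return data


# ---------------------------------------------------------------------------
# direct ERF simulation (subject-average level)
# ---------------------------------------------------------------------------

def simulate_condition_erfs(n_subjects: int, layout: SensorLayout,
                            times: np.ndarray,
                            effects: Sequence[ErfEffect],
                            noise_sd: float,
                            rng: np.random.Generator,
                            conditions: Sequence[str] = CONDITIONS,
                            noise_ar1: float = 0.9,
                            ) -> dict[str, np.ndarray]:
    """Simulate per-subject trial-averaged sensor ERFs directly.

    A shortcut past the continuous-recording stage for statistical
    calibration studies: each subject x condition ERF is the sum of the
    matching effect templates plus AR(1) noise at the subject-average
    level (``noise_sd`` is the residual noise sd of a trial average).
    Returns a dict mapping condition label to (n_subjects, n_sensors,
    n_times).
    """
    sfreq = 1.0 / float(times[1] - times[0])
    out = {}
    for cond in conditions:
        data = _ar1_noise((n_subjects, layout.n_sensors, len(times)),
                          noise_ar1, noise_sd, rng).reshape(
                              n_subjects, layout.n_sensors, len(times))
        for eff in effects:
            if cond not in eff.conditions:
                continue
            n_t = max(int(round((eff.window[1] - eff.window[0]) * sfreq)), 2)
            tmpl = np.hanning(n_t) * eff.amplitude * eff.polarity
            i0 = int(np.searchsorted(times, eff.window[0]))
            i1 = min(i0 + n_t, len(times))
            sens = layout.group_sensors(eff.sensor_group)
            data[:, sens, i0:i1] += tmpl[: i1 - i0]
        out[cond] = data
    return out
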