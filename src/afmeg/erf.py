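"""Event-related fields: filtering, epoching, baseline correction, planar
combination, and matched normal-feedback control selection.

The sensor pipeline mirrors the standard planar-gradiometer workflow:
continuous data are band-pass filtered (1-100 Hz, zero-phase FIR), cut into
[-1, +1] s epochs time-locked to the keystroke (triggers are shifted back
by the MIDI trigger delay so t=0 is the keystroke itself), corrected to a
pre-keystroke baseline (-200 to -100 ms), averaged per condition, and the
two orthogonal gradiometers of each pair are combined into a non-negative
field magnitude sqrt(h^2 + v^2).  Because the combination is nonlinear, the
order matters: condition averages are computed first on the raw channel
pairs and combined afterwards.

Normal-feedback control events are selected to match the altered-feedback
events in timing (preceding IOI) and keystroke velocity by greedy
nearest-neighbour assignment without replacement in z-scored covariate
space; NF events at +1/+2 after an AF event must be excluded from the
candidate pool beforehand (see behavior.mark_post_af).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import firls, oaconvolve

from .synthgen import SensorLayout

__all__ = [
    "EpochSet",
    "bandpass",
    "epoch",
    "baseline_correct",
    "combine_planar",
    "select_matched_controls",
    "condition_average",
]

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Epoched multi-sensor data: (n_trials, n_sensors, n_times)."""

    data: np.ndarray
    times: np.ndarray                       # s, relative to keystroke
    conditions: np.ndarray                  # str per trial
    covariates: pd.DataFrame | None = None  # per-trial (preceding IOI, velocity)
    subject: int | None = None
    sensor_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_sensors, n_times)")
        if self.data.shape[2] != len(self.times):
            raise ValueError("times length does not match data")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("conditions length does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        cov = None if self.covariates is None else \
            self.covariates.iloc[np.nonzero(mask)[0]].reset_index(drop=True)
        return replace(self, data=self.data[mask],
                       conditions=self.conditions[mask], covariates=cov)


def _design_bandpass(low: float, high: float, sfreq: float,
                     transition: float) -> np.ndarray:
    nyq = sfreq / 2.0
    n_taps = int(3.3 * sfreq / transition)
    n_taps += 1 - n_taps % 2  # odd length, type-I linear phase
    bands = [0.0, max(low - transition, 0.0), low, high,
             min(high + transition, nyq), nyq]
    desired = [0, 0, 1, 1, 0, 0]
    # firls requires strictly increasing band edges
    if bands[1] <= bands[0]:
        bands[1] = low / 2.0
    return firls(n_taps, bands, desired, fs=sfreq)


def bandpass(recording: np.ndarray, sfreq: float,
             low: float = 1.0, high: float = 100.0,
             transition: float = 1.0) -> np.ndarray:
    """Zero-phase FIR band-pass filter along the last axis.

    The filter is an odd-length least-squares linear-phase FIR whose order
    follows from the transition width (3.3 / normalized transition); being
    symmetric, a single centred convolution pass is exactly zero-phase.
    DC is removed before filtering so the stopband floor is not limited by
    a large offset.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if sfreq <= 2 * high:
        raise ValueError("sampling rate must exceed twice the high edge")
    data = np.asarray(recording, dtype=float)
    taps = _design_bandpass(low, high, sfreq, transition)
    data = data - data.mean(axis=-1, keepdims=True)
    # centred convolution of a symmetric kernel: zero phase in one pass
    shape = [1] * data.ndim
    shape[-1] = taps.size
    return oaconvolve(data, taps.reshape(shape), mode="same", axes=-1)


def epoch(recording: np.ndarray, sfreq: float, triggers: np.ndarray,
          latency_correction_ms: float = 22.5,
          window: tuple[float, float] = (-1.0, 1.0),
          conditions: np.ndarray | None = None,
          covariates: pd.DataFrame | None = None,
          subject: int | None = None,
          sensor_names: list[str] | None = None) -> EpochSet:
    """Cut continuous data into keystroke-locked epochs.

    Each epoch is centred on ``trigger - latency_correction_ms`` so that
    t=0 is the physical keystroke rather than the delayed MIDI trigger.
    Triggers whose window does not fit in the recording are dropped (and
    logged); associated condition labels / covariate rows are dropped with
    them.
    """
    data = np.asarray(recording, dtype=float)
    n_samples = data.shape[-1]
    shift = int(round(latency_correction_ms / 1000.0 * sfreq))
    i0 = int(round(window[0] * sfreq))
    n_t = int(round((window[1] - window[0]) * sfreq)) + 1
    centers = np.asarray(triggers, dtype=int) - shift
    starts = centers + i0
    keep = (starts >= 0) & (starts + n_t <= n_samples)
    if not keep.any():
        raise ValueError("no valid triggers within the recording")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d/%d triggers without full epoch windows",
                    dropped, len(centers))
    epochs = np.stack([data[:, s:s + n_t] for s in starts[keep]])
    times = (np.arange(n_t) + i0) / sfreq
    conds = (np.asarray(conditions)[keep] if conditions is not None
             else np.full(int(keep.sum()), "", dtype=object))
    cov = None
    if covariates is not None:
        cov = covariates.iloc[np.nonzero(keep)[0]].reset_index(drop=True)
    return EpochSet(data=epochs, times=times, conditions=conds,
                    covariates=cov, subject=subject,
                    sensor_names=list(sensor_names or []))


def baseline_correct(epochs: EpochSet,
                     window: tuple[float, float] = (-0.2, -0.1)) -> EpochSet:
    """Subtract the per-trial, per-sensor mean over the baseline window."""
    t = epochs.times
    mask = (t >= window[0]) & (t <= window[1])
    if not mask.any():
        raise ValueError("baseline window outside the epoch timebase")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def combine_planar(data: np.ndarray | EpochSet, layout: SensorLayout,
                   mode: str = "norm"):
    """Combine each planar gradiometer pair into a field magnitude.

    ``mode="norm"`` gives sqrt(h^2 + v^2) (the standard combination);
    ``mode="rms"`` gives sqrt((h^2 + v^2) / 2).  Works on an EpochSet or on
    any array whose second-to-last axis is sensors; the result has pair
    positions on that axis and is non-negative everywhere.
    """
    if mode not in ("norm", "rms"):
        raise ValueError("mode must be 'norm' or 'rms'")
    if isinstance(data, EpochSet):
        combined = combine_planar(data.data, layout, mode)
        return replace(data, data=combined,
                       sensor_names=list(layout.pair_names))
    arr = np.asarray(data, dtype=float)
    if arr.shape[-2] != layout.n_sensors:
        raise ValueError("sensor axis does not match the layout "
                         f"({arr.shape[-2]} != {layout.n_sensors})")
    h = arr[..., layout.h_idx, :]
    v = arr[..., layout.v_idx, :]
    out = np.sqrt(h ** 2 + v ** 2)
    if mode == "rms":
        out /= np.sqrt(2.0)
    return out


def select_matched_controls(pool: pd.DataFrame, targets: pd.DataFrame,
                            covariate_cols: tuple[str, ...] = ("prev_ioi",
                                                               "velocity"),
                            rng: np.random.Generator | None = None
                            ) -> np.ndarray:
    """Greedy covariate matching of control events to target events.

    Covariates are z-scored with statistics pooled over both sets, then
    each target (in order) takes its nearest remaining pool row by
    Euclidean distance, without replacement.  Returns the positional
    indices of the selected pool rows (one per target).  A warning is
    logged when a selected-set covariate mean deviates from the target
    mean by more than 0.25 pooled standard deviations.
    """
    if len(pool) < len(targets):
        raise ValueError("control pool smaller than the target set")
    both = pd.concat([pool[list(covariate_cols)],
                      targets[list(covariate_cols)]])
    mu = both.mean()
    sd = both.std(ddof=1).replace(0.0, 1.0)
    zp = ((pool[list(covariate_cols)] - mu) / sd).to_numpy()
    zt = ((targets[list(covariate_cols)] - mu) / sd).to_numpy()

    available = np.ones(len(pool), dtype=bool)
    chosen = np.empty(len(targets), dtype=int)
    for i in range(len(targets)):
        d = np.linalg.norm(zp - zt[i], axis=1)
        d[~available] = np.inf
        j = int(np.argmin(d))
        chosen[i] = j
        available[j] = False

    sel_mean = pool.iloc[chosen][list(covariate_cols)].mean()
    tgt_mean = targets[list(covariate_cols)].mean()
    off = ((sel_mean - tgt_mean).abs() / sd)
    if (off > 0.25).any():
        logger.warning("matched-control covariate means deviate by more than "
                       "0.25 pooled sd: %s", off.to_dict())
    return chosen


def condition_average(epochs: EpochSet) -> tuple[dict[str, np.ndarray],
                                                 dict[str, int]]:
    """Trial-wise mean ERF and trial count per condition."""
    erfs, counts = {}, {}
    for cond in np.unique(epochs.conditions):
        mask = epochs.conditions == cond
        if not mask.any():
            raise ValueError(f"empty condition {cond!r}")
        erfs[str(cond)] = epochs.data[mask].mean(axis=0)
        counts[str(cond)] = int(mask.sum())
    return erfs, counts
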