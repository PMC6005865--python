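"""Behavioral metrics of sequenced piano performance under feedback alteration.

Implements the timing and accuracy statistics of the paradigm: per-keystroke
inter-onset intervals (IOI), per-trial tempo and temporal variability
(cvIOI = sd/mean of the trial's IOIs), the windowed error-rate statistic
(fraction of feedback events followed by at least one pitch error within the
next five keystrokes, with events followed by another altered-feedback event
inside that window excluded), and post-feedback slowing (the change in IOI
at the first keystroke after a feedback event).  All statistics are
aggregated per subject and condition {NF, AF} x {Bo, In} before any group
inference, matching the across-subject permutation framework.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_ioi",
    "compute_cv_ioi",
    "compute_error_rate",
    "compute_post_feedback_change",
    "detect_errors",
    "mark_post_af",
    "learning_curves",
    "condition_summary",
    "factorial_cells",
]

CONDITION_ORDER = ("NF-Bo", "NF-In", "AF-Bo", "AF-In")


def _check_monotonic(events: pd.DataFrame) -> None:
    for (subj, trial), g in events.groupby(["subject", "trial"], sort=False):
        on = g.sort_values("keystroke_index")["onset_ms"].to_numpy()
        if np.any(np.diff(on) <= 0):
            raise ValueError(
                f"non-monotonic onset times in subject {subj}, trial {trial}")


def _sorted(events: pd.DataFrame) -> pd.DataFrame:
    return events.sort_values(["subject", "trial", "keystroke_index"],
                              kind="stable")


def compute_ioi(events: pd.DataFrame) -> pd.Series:
    """Per-event inter-onset interval in ms, NaN for each trial's first key.

    IOI_k = onset_k - onset_{k-1}, computed strictly within trials (no
    cross-trial intervals).  The returned series is aligned with the input
    index.
    """
    _check_monotonic(events)
    ev = _sorted(events)
    ioi = ev.groupby(["subject", "trial"], sort=False)["onset_ms"].diff()
    return ioi.reindex(events.index).rename("ioi")


def compute_cv_ioi(events: pd.DataFrame) -> pd.DataFrame:
    """Per subject x trial mean IOI (ms) and cvIOI (sd/mean, ddof=1)."""
    ev = events.copy()
    ev["ioi"] = compute_ioi(events)
    grp = ev.dropna(subset=["ioi"]).groupby(["subject", "trial"])["ioi"]
    out = grp.agg(mean_ioi="mean", sd_ioi=lambda s: s.std(ddof=1))
    out["cv_ioi"] = out["sd_ioi"] / out["mean_ioi"]
    return out.reset_index().drop(columns="sd_ioi")


def _condition(events: pd.DataFrame) -> pd.Series:
    return events["feedback"].astype(str) + "-" + \
        events["position_class"].astype(str)


def compute_error_rate(events: pd.DataFrame, horizon: int = 5
                       ) -> pd.DataFrame:
    """Windowed error rate per subject x condition.

    An event "induces an error" when at least one of the next ``horizon``
    keystrokes of the same trial is a pitch error (the window is clipped at
    the trial end; multiple errors count once).  Events followed by an AF
    event within the window are excluded from both numerator and
    denominator — for AF events because the later alteration could have
    caused the error, and symmetrically for NF events.  Events with no
    following keystroke in their trial are ineligible.  Conditions with an
    empty denominator get rate NaN.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    ev = _sorted(events).reset_index(drop=True)
    is_af = (ev["feedback"] == "AF").to_numpy()
    is_err = ev["is_error"].to_numpy().astype(bool)
    cond = _condition(ev).to_numpy()
    subj = ev["subject"].to_numpy()

    eligible = np.zeros(len(ev), dtype=bool)
    induced = np.zeros(len(ev), dtype=bool)
    for _, g in ev.groupby(["subject", "trial"], sort=False):
        idx = g.index.to_numpy()
        n = idx.size
        for j in range(n):
            stop = min(j + 1 + horizon, n)
            if stop == j + 1:
                continue  # no following keystroke
            window = idx[j + 1:stop]
            if is_af[window].any():
                continue  # excluded: another AF in range
            eligible[idx[j]] = True
            induced[idx[j]] = is_err[window].any()

    df = pd.DataFrame({"subject": subj, "condition": cond,
                       "eligible": eligible, "induced": induced & eligible})
    out = df.groupby(["subject", "condition"]).agg(
        n_events=("eligible", "sum"), n_induced=("induced", "sum"))
    out["error_rate"] = np.where(out["n_events"] > 0,
                                 out["n_induced"] / out["n_events"], np.nan)
    return out.reset_index()


def compute_post_feedback_change(events: pd.DataFrame) -> pd.DataFrame:
    """Mean change in IOI at the +1 keystroke, per subject x condition.

    For each event, dIOI = IOI(next keystroke) - IOI(event); events whose
    own IOI is undefined (trial-initial) or that lack a +1 keystroke within
    the trial are excluded.  Returns per subject x condition mean dIOI (ms)
    and event counts.
    """
    ev = _sorted(events).reset_index(drop=True)
    ev["ioi"] = compute_ioi(ev)
    nxt = ev.groupby(["subject", "trial"], sort=False)["ioi"].shift(-1)
    ev["d_ioi"] = nxt - ev["ioi"]
    ev["condition"] = _condition(ev)
    valid = ev.dropna(subset=["d_ioi"])
    out = valid.groupby(["subject", "condition"]).agg(
        mean_d_ioi=("d_ioi", "mean"), n_events=("d_ioi", "size"))
    return out.reset_index()


def detect_errors(events: pd.DataFrame,
                  patterns: Mapping[int, Sequence[int]]) -> pd.Series:
    """Flag pitch errors by aligning played pitches to the trial's pattern.

    A keystroke is an error when ``pitch_played`` deviates from the pattern
    pitch expected at the current cyclic position.  After a mismatch the
    alignment resynchronizes at the next keystroke whose pitch matches an
    upcoming pattern position (smallest forward shift); if none matches the
    position simply advances by one.
    """
    ev = _sorted(events)
    flags = pd.Series(False, index=ev.index, name="is_error")
    for (subj, trial), g in ev.groupby(["subject", "trial"], sort=False):
        pid = g["pattern_id"].iloc[0]
        try:
            pat = list(patterns[pid])
        except KeyError:
            raise KeyError(f"unknown pattern id {pid!r}") from None
        L = len(pat)
        pos = 0
        played = g["pitch_played"].to_numpy()
        idx = g.index.to_numpy()
        for j in range(len(played)):
            if played[j] == pat[pos % L]:
                pos += 1
                continue
            flags.loc[idx[j]] = True
            # resynchronize on the following keystroke if possible
            if j + 1 < len(played):
                nxt = played[j + 1]
                for shift in range(1, L + 1):
                    if nxt == pat[(pos + shift) % L]:
                        pos += shift
                        break
                else:
                    pos += 1
            else:
                pos += 1
    return flags.reindex(events.index)


def mark_post_af(events: pd.DataFrame, lags: Sequence[int] = (1, 2)
                 ) -> pd.Series:
    """True for keystrokes occurring ``lags`` positions after an AF event
    within the same trial (used to exclude contaminated NF control events)."""
    ev = _sorted(events)
    is_af = (ev["feedback"] == "AF")
    mask = pd.Series(False, index=ev.index)
    grp = ev.assign(af=is_af).groupby(["subject", "trial"], sort=False)["af"]
    for lag in lags:
        mask |= grp.shift(lag, fill_value=False)
    return mask.reindex(events.index).rename("post_af")


def learning_curves(events: pd.DataFrame) -> dict:
    """Training-related performance trajectories in perturbation-free trials.

    NF trials (trials containing no AF event) are ordered per subject; the
    result holds per-trial tempo/variability trajectories plus the paired
    comparisons ready for group permutation tests: first vs. last NF trial
    cvIOI, and mean IOI in the first vs. second half of the NF trials.
    """
    af_trials = events.loc[events["feedback"] == "AF",
                           ["subject", "trial"]].drop_duplicates()
    key = set(map(tuple, af_trials.to_numpy()))
    per_trial = compute_cv_ioi(events)
    nf = per_trial[[tuple(r) not in key for r in
                    per_trial[["subject", "trial"]].to_numpy()]]

    rows = []
    for subj, g in nf.groupby("subject"):
        g = g.sort_values("trial")
        if len(g) < 2:
            raise ValueError(
                f"subject {subj} has fewer than 2 perturbation-free trials")
        half = len(g) // 2
        rows.append({
            "subject": subj,
            "cv_first": g["cv_ioi"].iloc[0],
            "cv_last": g["cv_ioi"].iloc[-1],
            "mean_ioi_first_half": g["mean_ioi"].iloc[:half].mean(),
            "mean_ioi_second_half": g["mean_ioi"].iloc[half:].mean(),
        })
    return {"trajectories": nf.reset_index(drop=True),
            "pairs": pd.DataFrame(rows)}


def condition_summary(events: pd.DataFrame, horizon: int = 5) -> dict:
    """Bundle the per-subject condition tables for the 2x2 analyses."""
    return {
        "d_ioi": compute_post_feedback_change(events),
        "error_rate": compute_error_rate(events, horizon=horizon),
        "per_trial": compute_cv_ioi(events),
    }


def factorial_cells(table: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray]:
    """Arrange a per subject x condition table into (n_subjects, 2, 2) cells.

    Axis 1 is Feedback (AF, NF), axis 2 is Position (Bo, In).  Raises if a
    subject is missing a cell.
    """
    wide = table.pivot(index="subject", columns="condition", values=value)
    missing = [c for c in CONDITION_ORDER if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(f"missing cells for factorial analysis: "
                         f"{missing or 'NaN entries'}")
    cells = np.stack([
        np.column_stack([wide["AF-Bo"], wide["AF-In"]]),
        np.column_stack([wide["NF-Bo"], wide["NF-In"]]),
    ], axis=1)
    return cells, wide.index.to_numpy()
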