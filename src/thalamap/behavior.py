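"""Behavioral event detection for the lever-pushing and locomotion tasks.

Lever events follow the task rules: lever excursions greater than 1 mm
count as pushes, and pushes crossing the 5 mm threshold are rewarded and
counted as successes (the 1 mm comparison is strict).  Movement onsets
for photometry alignment are detected from forward velocity.  Optogenetic
sessions are quantified in three fixed 2-minute windows: baseline
(the 2 min before laser onset), inhibition (starting 1 min after onset),
and post-stimulation washout (starting 1 min after laser offset).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PUSH_MM = 1.0
SUCCESS_MM = 5.0
LEVER_RANGE_MM = 8.0
WHEEL_DIAMETER_CM = 16.0


def _supra_regions(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean mask."""
    idx = np.nonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))[0]
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def detect_pushes(
    position_mm: np.ndarray,
    fs: float,
    push_mm: float = PUSH_MM,
    success_mm: float = SUCCESS_MM,
    onset_fraction: float = 0.1,
) -> pd.DataFrame:
    """Detect lever pushes and flag successful (rewarded) ones.

    An excursion counts as a push when its peak exceeds ``push_mm``
    strictly; it is successful when the peak reaches ``success_mm``.
    Supra-threshold crossings separated only by samples still above half
    the push threshold are merged into one event, which makes the counts
    robust to additive noise smaller than ``push_mm / 2``.  The onset is
    the first sample of the contiguous run above ``onset_fraction *
    push_mm`` that leads into the threshold crossing.

    Returns a DataFrame with ``onset_index``, ``onset_s``, ``peak_mm``
    and ``success`` per push.
    """
    pos = np.asarray(position_mm, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("lever position trace contains non-finite samples")
    if push_mm >= success_mm:
        raise ValueError("push threshold must be below the success threshold")

    high = pos > push_mm  # strict: an excursion peaking exactly at push_mm is not a push
    low = pos > push_mm / 2
    onset_thr = onset_fraction * push_mm

    # merge high-crossing runs that stay connected above the low threshold
    events: list[tuple[int, int]] = []
    for ls, le in _supra_regions(low):
        if np.any(high[ls:le]):
            events.append((ls, le))

    rows = []
    for ls, le in events:
        peak = float(pos[ls:le].max())
        onset = ls
        while onset > 0 and pos[onset - 1] > onset_thr:
            onset -= 1
        rows.append(
            dict(
                onset_index=onset,
                onset_s=onset / fs,
                peak_mm=peak,
                success=bool(peak >= success_mm),
            )
        )
    return pd.DataFrame(rows, columns=["onset_index", "onset_s", "peak_mm", "success"])


def movement_onset_from_velocity(
    velocity: np.ndarray,
    fs: float,
    threshold: float,
    min_quiet_s: float = 0.5,
) -> np.ndarray:
    """Onset times (s) where velocity crosses threshold after a quiet period.

    An onset is the first supra-threshold sample preceded by at least
    ``min_quiet_s`` of sub-threshold velocity; the start of the recording
    counts as quiet.  Used to align photometry trials for both tasks.
    """
    v = np.asarray(velocity, dtype=float)
    above = v > threshold
    q = max(int(round(min_quiet_s * fs)), 1)
    padded = np.concatenate([np.zeros(q, dtype=bool), above])
    onsets = []
    for start, _ in _supra_regions(above):
        if not padded[start : start + q].any():  # the q samples before `start`
            onsets.append(start)
    return np.asarray(onsets, dtype=float) / fs


def detect_running_bouts(
    velocity: np.ndarray,
    fs: float,
    threshold: float = 1.0,
    min_duration_s: float = 1.0,
    merge_gap_s: float = 0.5,
) -> pd.DataFrame:
    """Running bouts: supra-threshold epochs of sufficient duration.

    Maximal runs of velocity above ``threshold`` (cm/s) are merged when
    separated by gaps shorter than ``merge_gap_s``, then filtered to
    those lasting at least ``min_duration_s``.  The threshold and
    duration criteria are explicit configuration: the task itself only
    defines performance as the number of bouts.
    """
    v = np.asarray(velocity, dtype=float)
    regions = _supra_regions(v > threshold)
    merged: list[list[int]] = []
    gap = merge_gap_s * fs
    for s, e in regions:
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    rows = [
        dict(start_s=s / fs, end_s=e / fs, duration_s=(e - s) / fs)
        for s, e in merged
        if (e - s) / fs >= min_duration_s
    ]
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s"])


def wheel_velocity_from_counts(
    counts: np.ndarray,
    fs: float,
    pulses_per_rev: int,
    wheel_diameter_cm: float = WHEEL_DIAMETER_CM,
) -> np.ndarray:
    """Linear treadmill velocity (cm/s) from cumulative encoder counts."""
    circumference = np.pi * wheel_diameter_cm
    dc = np.diff(np.asarray(counts, dtype=float), prepend=counts[0])
    return dc * circumference / pulses_per_rev * fs


def opto_windows(laser_on_s: float, laser_off_s: float) -> dict[str, tuple[float, float]]:
    """Baseline / inhibition / post analysis windows for a silencing session.

    Baseline is the 2 min before laser onset; inhibition the 2 min window
    starting 1 min after onset; post the 2 min window starting 1 min
    after the laser turned off.  A session whose laser starts before
    120 s has no full baseline and is rejected.
    """
    if laser_off_s <= laser_on_s:
        raise ValueError("laser_off must be after laser_on")
    if laser_on_s < 120.0:
        raise ValueError("laser onset before 120 s: no full 2-min baseline available")
    return {
        "baseline": (laser_on_s - 120.0, laser_on_s),
        "inhibition": (laser_on_s + 60.0, laser_on_s + 180.0),
        "post": (laser_off_s + 60.0, laser_off_s + 180.0),
    }


def apply_inclusion(sessions: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Apply the study inclusion rules to a session summary table.

    ``mode="photometry"``: keep subjects averaging at least 10 lever
    pushes per session (columns ``subject``, ``n_pushes``).

    ``mode="opto"``: keep sessions with a baseline rate of at least 2
    pushes/min (columns ``subject``, ``baseline_pushes``,
    ``baseline_minutes``), then keep, per subject, the single session
    with the higher baseline push count.
    """
    if mode == "photometry":
        means = sessions.groupby("subject")["n_pushes"].mean()
        keep = means[means >= 10].index
        return sessions[sessions["subject"].isin(keep)].reset_index(drop=True)
    if mode == "opto":
        rate = sessions["baseline_pushes"] / sessions["baseline_minutes"]
        kept = sessions[rate >= 2.0]
        idx = kept.groupby("subject")["baseline_pushes"].idxmax()
        return kept.loc[idx].reset_index(drop=True)
    raise ValueError(f"unknown inclusion mode {mode!r}")
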