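"""Fiber-photometry preprocessing: isosbestic dF/F, trial alignment, z-scoring.

The preprocessing follows the standard isosbestic-control recipe for
GCaMP recordings sampled at 30 Hz: background subtraction, a 4th-order
Butterworth low-pass at 2 Hz applied identically to the 470 nm signal and
the 410 nm isosbestic channel, a least-squares linear fit aligning the
410 nm channel to the 470 nm channel, and
``dF/F = (470 - fitted410) / fitted410``.  Because both channels share
bleaching and motion artifacts but only the 470 nm channel carries
Ca²⁺ transients, the division cancels the shared artifacts.

Filtering is zero-phase (forward-backward), so movement-onset alignment
is not biased by group delay.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

REGIONS = ("snr", "dcn", "thalamus")

#: day groupings used to average early vs late learning sessions per task
DAY_GROUPS = {
    "lever": {"early": (1, 2, 3), "late": (8, 9, 10)},
    "locomotion": {"early": (1, 2), "late": (4, 5)},
}


@dataclass
class PhotometryBundle:
    """Synchronized multi-site recording: per-region 470/410 + background.

    ``signals`` maps each recorded region to ``{"470": array, "410":
    array}``; all channels share the sampling rate ``fs`` and length.
    ``behavior`` optionally carries synchronized behavior streams (lever
    position, wheel velocity, laser state).  ``truth`` is populated by the
    synthetic generator with the ground-truth ideal traces.
    """

    signals: dict[str, dict[str, np.ndarray]]
    background: np.ndarray
    fs: float
    session_id: str = "session"
    day_index: int = 1
    behavior: dict[str, np.ndarray] = field(default_factory=dict)
    truth: dict | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")
        lengths = {
            len(ch) for chans in self.signals.values() for ch in chans.values()
        } | {len(self.background)}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.background)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def save(self, stem: str | Path) -> None:
        """Write ``<stem>.npz`` (arrays) and ``<stem>.json`` (metadata)."""
        stem = Path(stem)
        arrays = {"background": self.background}
        for region, chans in self.signals.items():
            for ch, arr in chans.items():
                arrays[f"{region}__{ch}"] = arr
        for name, arr in self.behavior.items():
            arrays[f"behavior__{name}"] = arr
        np.savez(stem.with_suffix(".npz"), **arrays)
        stem.with_suffix(".json").write_text(
            json.dumps(
                {
                    "fs": self.fs,
                    "session_id": self.session_id,
                    "day_index": self.day_index,
                    "regions": sorted(self.signals),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, stem: str | Path) -> "PhotometryBundle":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        with np.load(stem.with_suffix(".npz")) as data:
            signals: dict[str, dict[str, np.ndarray]] = {}
            behavior: dict[str, np.ndarray] = {}
            background = data["background"]
            for key in data.files:
                if key.startswith("behavior__"):
                    behavior[key.split("__", 1)[1]] = data[key]
                elif "__" in key:
                    region, ch = key.split("__", 1)
                    signals.setdefault(region, {})[ch] = data[key]
        return cls(
            signals=signals,
            background=background,
            fs=meta["fs"],
            session_id=meta["session_id"],
            day_index=meta["day_index"],
            behavior=behavior,
        )


@dataclass
class TrialMatrix:
    """Onset-aligned, z-scored trials: (n_trials, window_samples).

    The window spans ±``window_s/2`` around movement onset (10 s total by
    default); each trial is z-scored against its own pre-movement baseline
    (700 ms, optionally shifted 500 ms earlier for the locomotion task).
    Trials with a zero-variance baseline are excluded and their original
    indices recorded in ``excluded``.
    """

    z: np.ndarray
    fs: float
    window_s: float
    baseline_ms: float
    baseline_shift_ms: float
    task: str = ""
    reward: np.ndarray | None = None
    excluded: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.z.shape[0]

    @property
    def onset_index(self) -> int:
        return self.z.shape[1] // 2

    def trial_average(self) -> np.ndarray:
        return self.z.mean(axis=0)


# ----------------------------------------------------------------------
# Preprocessing
# ----------------------------------------------------------------------
def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int) -> np.ndarray:
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def dff(
    signal_470: np.ndarray,
    isosbestic_410: np.ndarray,
    background: np.ndarray | float,
    fs: float,
    cutoff_hz: float = 2.0,
    order: int = 4,
) -> np.ndarray:
    """Isosbestic-corrected dF/F.

    Order of operations: subtract the background estimate (mean of the
    dedicated background channel) from both channels, low-pass both with
    a zero-phase Butterworth filter (default 4th order, 2 Hz), fit
    ``a + b * filt410`` to ``filt470`` by least squares, and return
    ``(filt470 - fit) / fit``.

    Raises if the fitted isosbestic trace passes through zero, where the
    division is undefined.
    """
    f470 = np.asarray(signal_470, dtype=float)
    f410 = np.asarray(isosbestic_410, dtype=float)
    if f470.shape != f410.shape:
        raise ValueError("470 and 410 traces must have equal length")
    if len(f470) < 10 * fs:
        raise ValueError("traces must be at least 10 s long")
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    bg = float(np.mean(background))
    f470 = _lowpass(f470 - bg, fs, cutoff_hz, order)
    f410 = _lowpass(f410 - bg, fs, cutoff_hz, order)
    design = np.column_stack([np.ones_like(f410), f410])
    coef, *_ = np.linalg.lstsq(design, f470, rcond=None)
    fitted = design @ coef
    if np.any(np.abs(fitted) < 1e-12 * max(np.abs(fitted).max(), 1.0)):
        raise ValueError("fitted isosbestic trace crosses zero; dF/F undefined")
    return (f470 - fitted) / fitted


def segment_trials(
    signal_470: np.ndarray,
    isosbestic_410: np.ndarray,
    background: np.ndarray | float,
    fs: float,
    onsets_s: np.ndarray,
    window_s: float = 10.0,
    cutoff_hz: float = 2.0,
    order: int = 4,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cut raw trial windows around onsets and preprocess each window.

    The raw channels are segmented for ``window_s`` seconds centred on
    each onset, and the dF/F preprocessing (background subtraction,
    filtering, isosbestic fit) is applied *within each trial window*.
    Onsets too close to the recording edges are dropped and counted.

    Returns ``(segments, kept_onsets_s, n_dropped)`` with ``segments`` of
    shape ``(n_trials, round(window_s * fs))``.
    """
    f470 = np.asarray(signal_470, dtype=float)
    n = len(f470)
    half = int(round(window_s / 2 * fs))
    onsets_s = np.asarray(onsets_s, dtype=float)
    centers = np.round(onsets_s * fs).astype(int)
    valid = (centers - half >= 0) & (centers + half <= n)
    n_dropped = int(np.sum(~valid))
    if n_dropped:
        logger.info("segment_trials: dropped %d out-of-range onsets", n_dropped)
    centers = centers[valid]
    if len(centers) == 0:
        raise ValueError("no onsets fall fully inside the recording")
    segments = np.empty((len(centers), 2 * half))
    f410 = np.asarray(isosbestic_410, dtype=float)
    for i, c in enumerate(centers):
        sl = slice(c - half, c + half)
        segments[i] = dff(f470[sl], f410[sl], background, fs, cutoff_hz, order)
    return segments, onsets_s[valid], n_dropped


def zscore_trials(
    segments: np.ndarray,
    fs: float,
    baseline_ms: float = 700.0,
    baseline_shift_ms: float = 0.0,
    task: str = "",
    reward: np.ndarray | None = None,
) -> TrialMatrix:
    """Z-score each trial against its pre-movement baseline.

    The baseline spans ``baseline_ms`` and ends ``baseline_shift_ms``
    before the onset sample (the window centre): shift 0 for the
    lever-pushing task, 500 ms for the locomotion task, where forward
    velocity lags the underlying movement.  Trials whose baseline has
    zero standard deviation are excluded and logged.
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    n_trials, n_samp = segments.shape
    onset = n_samp // 2
    end = onset - int(round(baseline_shift_ms / 1000 * fs))
    start = end - int(round(baseline_ms / 1000 * fs))
    if start < 0 or end > n_samp or start >= end:
        raise ValueError("baseline window falls outside the trial window")
    mean = segments[:, start:end].mean(axis=1)
    sd = segments[:, start:end].std(axis=1)
    good = sd > 0
    excluded = [int(i) for i in np.nonzero(~good)[0]]
    if excluded:
        logger.warning("zscore_trials: excluded %d zero-baseline-sd trials", len(excluded))
    z = (segments[good] - mean[good, None]) / sd[good, None]
    kept_reward = None if reward is None else np.asarray(reward)[good]
    return TrialMatrix(
        z=z,
        fs=fs,
        window_s=n_samp / fs,
        baseline_ms=baseline_ms,
        baseline_shift_ms=baseline_shift_ms,
        task=task,
        reward=kept_reward,
        excluded=excluded,
    )


def group_sessions(
    trials_by_day: list[tuple[str, int, TrialMatrix]],
    task: str = "lever",
    early_days: tuple[int, ...] | None = None,
    late_days: tuple[int, ...] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Average trials into early/late learning phases per subject.

    Defaults follow the training schedules: days 1–3 (early) and 8–10
    (late) for the 10-day lever task, days 1–2 and 4–5 for the 5-day
    locomotion task.  Input is a list of ``(subject, day_index,
    TrialMatrix)``; output maps subject → phase → trial-averaged trace.
    """
    if task not in DAY_GROUPS and (early_days is None or late_days is None):
        raise ValueError(f"unknown task {task!r}; supply explicit day groups")
    early = tuple(early_days) if early_days is not None else DAY_GROUPS[task]["early"]
    late = tuple(late_days) if late_days is not None else DAY_GROUPS[task]["late"]
    subjects = sorted({s for s, _, _ in trials_by_day})
    out: dict[str, dict[str, np.ndarray]] = {}
    for subject in subjects:
        out[subject] = {}
        for phase, days in (("early", early), ("late", late)):
            mats = [
                tm.z
                for s, d, tm in trials_by_day
                if s == subject and d in days and tm.n_trials > 0
            ]
            if not mats:
                raise ValueError(f"no trials for subject {subject!r} in phase {phase!r}")
            out[subject][phase] = np.vstack(mats).mean(axis=0)
    return out
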