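"""Linear integration model: does thalamic activity mirror SNr + DCN input?

The test asks whether the thalamic Ca²⁺ signal is predicted by a linear
combination of its two input structures,

    A * Ca_SNr + B * Ca_DCN + C = Ca_Thalamus,

fitted by ordinary least squares over randomly sampled 135-second
intervals.  Goodness of fit (R²) is compared against a time-shift shuffle
null in which the SNr and DCN windows are each shifted by an independent
uniform random amount up to ±67.5 s relative to the thalamus window,
destroying temporal correspondence while preserving each trace's
autocorrelation.  Per-interval results are averaged per subject; the
paired observed-vs-shuffled difference is the quantity of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERVAL_S = 135.0
MAX_SHIFT_S = 67.5


@dataclass
class IntegrationFit:
    """OLS result on one interval: coefficients, prediction, and R²."""

    A: float
    B: float
    C: float
    r2: float
    predicted: np.ndarray


def sample_intervals(
    session_lengths_s: dict[str, float],
    interval_s: float = INTERVAL_S,
    n_intervals: int = 20,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, float]]:
    """Draw interval start positions uniformly across eligible sessions.

    Each interval lies wholly within a single session; sessions shorter
    than ``interval_s`` are excluded (logged).  Returns ``(session_id,
    start_s)`` pairs.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eligible = {k: v for k, v in session_lengths_s.items() if v >= interval_s}
    skipped = sorted(set(session_lengths_s) - set(eligible))
    if skipped:
        logger.info("sample_intervals: sessions shorter than %.0f s excluded: %s",
                    interval_s, skipped)
    if not eligible:
        raise ValueError(f"no session is at least {interval_s} s long")
    ids = sorted(eligible)
    out = []
    for _ in range(n_intervals):
        sid = ids[rng.integers(len(ids))]
        start = rng.uniform(0.0, eligible[sid] - interval_s)
        out.append((sid, float(start)))
    return out


def fit_integration(thal: np.ndarray, snr: np.ndarray, dcn: np.ndarray) -> IntegrationFit:
    """OLS fit of ``A*snr + B*dcn + C`` to ``thal`` over one interval."""
    thal = np.asarray(thal, dtype=float)
    snr = np.asarray(snr, dtype=float)
    dcn = np.asarray(dcn, dtype=float)
    if not (len(thal) == len(snr) == len(dcn)):
        raise ValueError("traces must have equal length")
    if len(thal) < 3:
        raise ValueError("need at least 3 samples to fit 3 coefficients")
    design = np.column_stack([snr, dcn, np.ones_like(snr)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("SNr and DCN traces are collinear; coefficients not identifiable")
    coef, *_ = np.linalg.lstsq(design, thal, rcond=None)
    predicted = design @ coef
    ss_res = float(np.sum((thal - predicted) ** 2))
    ss_tot = float(np.sum((thal - thal.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return IntegrationFit(A=float(coef[0]), B=float(coef[1]), C=float(coef[2]),
                          r2=r2, predicted=predicted)


def _shifted_window(
    trace: np.ndarray,
    start_idx: int,
    n_samp: int,
    max_shift_samp: int,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> tuple[np.ndarray, int]:
    """A window shifted by a uniform random amount, kept inside the trace.

    Shifts exiting the session are redrawn (bounded retries) and finally
    clamped to the admissible range rather than wrapped, so no splice
    discontinuity is introduced.
    """
    n = len(trace)
    for _ in range(max_retries):
        shift = int(round(rng.uniform(-max_shift_samp, max_shift_samp)))
        s = start_idx + shift
        if 0 <= s and s + n_samp <= n:
            return trace[s : s + n_samp], shift
    lo = -start_idx
    hi = n - n_samp - start_idx
    shift = int(np.clip(int(round(rng.uniform(-max_shift_samp, max_shift_samp))), lo, hi))
    logger.warning("shuffled_control: shift clamped to %d samples", shift)
    s = start_idx + shift
    return trace[s : s + n_samp], shift


def shuffled_control(
    thal: np.ndarray,
    snr: np.ndarray,
    dcn: np.ndarray,
    intervals: list[tuple[int, int]],
    fs: float,
    max_shift_s: float = MAX_SHIFT_S,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Shuffle-null R² for each interval.

    ``intervals`` holds ``(start_idx, n_samp)`` pairs into the full
    session traces.  For each interval the SNr and DCN windows are read
    at independently shifted positions (uniform within ±``max_shift_s``,
    rounded to whole samples) while the thalamus window stays in place;
    the same regression and R² computation are then applied.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    max_shift_samp = max_shift_s * fs
    rows = []
    for start_idx, n_samp in intervals:
        t = thal[start_idx : start_idx + n_samp]
        s_win, shift_s = _shifted_window(snr, start_idx, n_samp, max_shift_samp, rng)
        d_win, shift_d = _shifted_window(dcn, start_idx, n_samp, max_shift_samp, rng)
        fit = fit_integration(t, s_win, d_win)
        rows.append(
            dict(start_idx=start_idx, r2_shuffled=fit.r2,
                 shift_snr_s=shift_s / fs, shift_dcn_s=shift_d / fs)
        )
    return pd.DataFrame(rows)


def analyze_subject(
    sessions: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    fs: float,
    subject: str = "subject",
    interval_s: float = INTERVAL_S,
    n_intervals: int = 20,
    max_shift_s: float = MAX_SHIFT_S,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Observed and shuffled fits over sampled intervals for one subject.

    ``sessions`` maps session id → ``(thal, snr, dcn)`` dF/F traces.
    Each sampled interval yields one observed regression and one matched
    shuffled control drawn from the same session.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lengths = {sid: len(t[0]) / fs for sid, t in sessions.items()}
    picks = sample_intervals(lengths, interval_s, n_intervals, rng)
    n_samp = int(round(interval_s * fs))
    rows = []
    for sid, start_s in picks:
        thal, snr, dcn = sessions[sid]
        i0 = int(round(start_s * fs))
        i0 = min(i0, len(thal) - n_samp)
        fit = fit_integration(thal[i0 : i0 + n_samp], snr[i0 : i0 + n_samp], dcn[i0 : i0 + n_samp])
        shuf = shuffled_control(thal, snr, dcn, [(i0, n_samp)], fs, max_shift_s, rng)
        rows.append(
            dict(
                subject=subject,
                session_id=sid,
                interval_start_s=start_s,
                A=fit.A,
                B=fit.B,
                C=fit.C,
                r2_observed=fit.r2,
                r2_shuffled=float(shuf["r2_shuffled"].iloc[0]),
                shift_snr_s=float(shuf["shift_snr_s"].iloc[0]),
                shift_dcn_s=float(shuf["shift_dcn_s"].iloc[0]),
            )
        )
    return pd.DataFrame(rows)


def summarize_integration(results: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean observed and shuffled R² plus paired differences.

    The returned table (one row per subject) is ready for a paired test
    in standard statistics tooling; the test itself is out of scope here.
    """
    if results.empty:
        raise ValueError("no intervals to summarize")
    g = results.groupby("subject")
    out = g.agg(
        n_intervals=("r2_observed", "size"),
        r2_observed=("r2_observed", "mean"),
        r2_shuffled=("r2_shuffled", "mean"),
    ).reset_index()
    out["r2_diff"] = out["r2_observed"] - out["r2_shuffled"]
    return out
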