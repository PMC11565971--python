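"""Optogenetically evoked synaptic currents and input classification.

Thalamic neurons are probed in whole-cell voltage clamp while SNr or DCN
axon terminals are stimulated optogenetically.  Evoked amplitude is the
peak current after laser onset minus the mean baseline current over the
50 ms before onset, with the sign convention inward negative / outward
positive.  A cell is classified as receiving DCN input when the inward
(excitatory) current is at least 25 pA, and SNr input when the outward
(inhibitory, GABAergic at the holding potential used) current is at
least 100 pA; the two booleans define four exhaustive classes.

When ChrimsonR (SNr) and ChR2 (DCN) are co-expressed, 450 nm light can
cross-activate ChrimsonR, producing a spurious inward current at −70 mV.
Comparing the response at −70 mV and +10 mV to the same 450 nm stimulus
disambiguates: a large outward current at +10 mV is the GABAergic
signature of cross-activation.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

DCN_THRESH_PA = 25.0
SNR_THRESH_PA = 100.0
BASELINE_MS = 50.0


class InputClass(str, Enum):
    DUAL = "dual"
    SNR_ONLY = "snr_only"
    DCN_ONLY = "dcn_only"
    NONE = "none"


class CrossActivation(str, Enum):
    GENUINE = "genuine"
    CROSS_ACTIVATION = "cross_activation"
    UNVERIFIED = "unverified"


def evoked_amplitude(
    trace_pa: np.ndarray,
    fs: float,
    onset_s: float,
    baseline_ms: float = BASELINE_MS,
    search_ms: float = 100.0,
) -> float:
    """Signed evoked amplitude: post-onset extremum minus baseline mean.

    The baseline is the ``baseline_ms`` window immediately before laser
    onset; the peak is the sample of largest absolute deviation from the
    baseline within ``search_ms`` after onset, sign preserved.
    """
    trace = np.asarray(trace_pa, dtype=float)
    i_on = int(round(onset_s * fs))
    n_base = int(round(baseline_ms / 1000 * fs))
    if i_on - n_base < 0:
        raise ValueError(f"need {baseline_ms} ms of pre-onset data")
    n_search = int(round(search_ms / 1000 * fs))
    baseline = trace[i_on - n_base : i_on].mean()
    window = trace[i_on : min(i_on + n_search, len(trace))] - baseline
    if window.size == 0:
        raise ValueError("no post-onset samples in the search window")
    return float(window[np.argmax(np.abs(window))])


def classify_input(
    dcn_amp_pa: float,
    snr_amp_pa: float,
    dcn_thresh: float = DCN_THRESH_PA,
    snr_thresh: float = SNR_THRESH_PA,
) -> InputClass:
    """Classify a cell from its two evoked amplitudes.

    DCN input: inward (negative) current of magnitude >= ``dcn_thresh``
    when stimulating DCN projections.  SNr input: outward (positive)
    current >= ``snr_thresh`` when stimulating SNr projections.
    """
    has_dcn = dcn_amp_pa <= -dcn_thresh
    has_snr = snr_amp_pa >= snr_thresh
    if has_dcn and has_snr:
        return InputClass.DUAL
    if has_snr:
        return InputClass.SNR_ONLY
    if has_dcn:
        return InputClass.DCN_ONLY
    return InputClass.NONE


def cross_activation_check(
    amp_at_minus70_pa: float,
    amp_at_plus10_pa: float | None,
    outward_thresh: float = SNR_THRESH_PA,
) -> CrossActivation:
    """Is an inward current at −70 mV under 450 nm light a genuine oEPSC?

    Cross-activation of ChrimsonR produces a GABAergic current that is
    inward at −70 mV (reversed chloride gradient) but strongly outward at
    +10 mV.  The −70 mV response is flagged as cross-activation when the
    +10 mV response to the same stimulus is outward above
    ``outward_thresh`` (the same 100 pA criterion used for SNr input);
    a missing +10 mV measurement leaves the call unverified.
    """
    if amp_at_plus10_pa is None or (
        isinstance(amp_at_plus10_pa, float) and np.isnan(amp_at_plus10_pa)
    ):
        return CrossActivation.UNVERIFIED
    if amp_at_minus70_pa < 0 and amp_at_plus10_pa >= outward_thresh:
        return CrossActivation.CROSS_ACTIVATION
    return CrossActivation.GENUINE


def class_fractions(classes: list[InputClass]) -> dict[str, float]:
    """Fraction of cells per input class over a recorded cohort."""
    if not classes:
        raise ValueError("empty cohort")
    n = len(classes)
    return {c.value: sum(1 for x in classes if x == c) / n for c in InputClass}
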