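"""Behavioral event detection and synaptic input classification.

Lever pushes (>1 mm) and successes (>=5 mm reward threshold), running
bouts, the optogenetic-silencing analysis windows, and classification of
thalamic neurons by their evoked DCN (inward >= 25 pA) and SNr
(outward >= 100 pA) currents.
"""

import numpy as np

from thalamap import (
    classify_input, detect_pushes, detect_running_bouts, evoked_amplitude,
    gen_behavior, opto_windows,
)

FS = 30.0

trace = gen_behavior("lever", [(3.0, 2.0), (8.0, 6.0), (14.0, 7.0)], FS, 20.0)
events = detect_pushes(trace, FS)
print(f"lever fixture (2, 6, 7 mm excursions): {len(events)} pushes, "
      f"{int(events['success'].sum())} successes")
print(events.to_string(index=False))

velocity = gen_behavior("wheel", [(5.0, 4.0), (12.0, 5.0)], FS, 30.0)
bouts = detect_running_bouts(velocity, FS, threshold=1.0, min_duration_s=0.3)
print(f"\nrunning bouts: {len(bouts)} (threshold 1 cm/s)")

w = opto_windows(laser_on_s=180.0, laser_off_s=360.0)
print(f"opto windows for laser 180-360 s: baseline {w['baseline']}, "
      f"inhibition {w['inhibition']}, post {w['post']}")

# evoked currents: an oEPSC-like trace at -70 mV
fs_ephys = 10_000.0
t = np.arange(int(0.5 * fs_ephys)) / fs_ephys
current = -20.0 + np.where(t > 0.2, -100.0 * np.exp(-(t - 0.2) / 0.02), 0.0)
amp = evoked_amplitude(current, fs_ephys, onset_s=0.2)
print(f"\nevoked amplitude (baseline -20 pA, peak -120 pA): {amp:.1f} pA")
for dcn, snr in ((-30.0, 150.0), (-5.0, 200.0), (-80.0, 10.0), (0.0, 0.0)):
    print(f"  DCN {dcn:+6.1f} pA, SNr {snr:+6.1f} pA -> {classify_input(dcn, snr).value}")
print("(dual-input cells are the anatomical substrate of basal-ganglia/")
print(" cerebellar convergence the pipeline maps and records)")
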