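"""The linear integration model and its time-shift shuffle null.

Does thalamic activity follow A*SNr + B*DCN + C?  The regression is fit
on random 135 s intervals; the control refits after shifting the SNr and
DCN windows by independent random amounts up to +/-67.5 s, which
destroys temporal correspondence but keeps each trace's statistics.
"""

import numpy as np

from thalamap import SynthSignalTruth, analyze_subject, dff, gen_photometry, summarize_integration

FS = 30.0
truth = SynthSignalTruth(A=0.5, B=0.3, C=0.1, noise_sd=0.05, seed=4)
bundle = gen_photometry(600.0, FS, truth)
traces = {r: dff(bundle.signals[r]["470"], bundle.signals[r]["410"],
                 bundle.background, FS) for r in bundle.signals}

results = analyze_subject(
    {"session_1": (traces["thalamus"], traces["snr"], traces["dcn"])},
    FS, subject="mouse_0", n_intervals=10, seed=5,
)
summary = summarize_integration(results)

print(f"true mixture: thal = {truth.A}*snr + {truth.B}*dcn + {truth.C} + noise")
print(f"fitted coefficients (mean over 10 intervals): "
      f"A = {results['A'].mean():.3f}, B = {results['B'].mean():.3f}, "
      f"C = {results['C'].mean():.4f}")
print(f"observed R^2 = {summary['r2_observed'].iloc[0]:.3f}  "
      f"shuffled R^2 = {summary['r2_shuffled'].iloc[0]:.3f}  "
      f"(paired difference {summary['r2_diff'].iloc[0]:.3f})")
print("(the observed fit beats the shuffle null because only true temporal")
print(" correspondence lets SNr and DCN predict the thalamus trace; dF/F")
print(" rescaling attenuates A and B slightly below the generative values)")
shift_mag = np.abs(results[["shift_snr_s", "shift_dcn_s"]].to_numpy())
print(f"shuffle shifts drawn up to +/-67.5 s (max drawn {shift_mag.max():.1f} s)")
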