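"""Extract the 8 autonomic indices from one synthetic recording.

Runs the full feature chain on a single ship-search condition recording:
R-peak detection -> RR resampling -> averaged spectrum for HRV, and sparse
tonic/phasic deconvolution + spectral indices for EDA.
"""

import taskphysio as tp

profile = tp.default_profiles()["SS"]
rr, _ = tp.generate_rr(profile, duration=240, seed=7)
ecg = tp.synthesize_ecg(rr, fs=256, seed=7, noise_sd=profile.noise_sd_ecg,
                        duration=240)
eda, truth = tp.synthesize_eda(profile, duration=120, fs=8, seed=7)

h = tp.hrv_indices(ecg)
e = tp.eda_indices(eda)

print("HRV (cardiac autonomic balance):")
print(f"  HRVLF  = {h.HRVLF:8.1f} ms²   (0.045-0.15 Hz, mixed sympathetic)")
print(f"  HRVHF  = {h.HRVHF:8.1f} ms²   (0.15-0.4 Hz, parasympathetic)")
print(f"  HRVLFn = {h.HRVLFn:8.3f} n.u.  HRVHFn = {h.HRVHFn:.3f} n.u.")
print("EDA (sympathetic sudomotor activity):")
print(f"  SCL     = {e.SCL:7.2f} µS    (tonic level; true mean "
      f"{truth.tonic_curve.mean():.2f} µS)")
print(f"  NS.SCRs = {e.NS_SCRs:7.1f} /min  (responses > 0.05 µS; "
      f"{truth.scr_event_times.size} events generated in 2 min)")
print(f"  EDASymp = {e.EDASymp:7.3f} µS²   (0.045-0.25 Hz band power)")
print(f"  TVSymp  = {e.TVSymp:7.3f} n.u.  (mean instantaneous amplitude, "
      "0.08-0.24 Hz)")
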