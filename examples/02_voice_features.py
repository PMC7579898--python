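"""Extract the 22 dysphonia features from a simulated sustained vowel.

Simulates a 10 s /a/ phonation with 1% jitter, 3% shimmer and 25 dB HNR,
runs the pre-processing chain (truncate, band-pass, downsample, normalize)
and prints the full feature vector.
"""

import pdscreen as pds
from pdscreen.voice import jitter_percent

rec, truth = pds.simulate_vowel(pds.VowelSimSpec(
    f0=150, jitter_pct=1.0, shimmer_pct=3.0, hnr_db=25, seed=1))
pre = pds.preprocess_voice(rec)
features = pds.compute_voice_features(pre)

print(f"preprocessed: {pre.duration:.1f} s at {pre.fs:.0f} Hz")
for name, value in features.as_dict().items():
    print(f"  {name:18s} {value:10.4f}")

tw = truth.in_window(1.0, rec.duration - 3.0)
print(f"\nground-truth Jitter(%) from the generator's period sequence: "
      f"{jitter_percent(tw.periods):.3f}")
# MDVP:Jitter(%) above should agree with the ground-truth value within
# about +-0.2; HNR should sit near the generated 25 dB (the band-pass
# preprocessing keeps only in-band noise).
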