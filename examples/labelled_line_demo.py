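"""Labelled-line (place code) walkthrough: correlogram, mixing, decoding.

Builds the reference cross-correlogram for a +200 us source, calibrates
the internal-noise mixing coefficient for a few target Pearson
correlations, and shows that the decoded peak stays near the source ITD
while its variability grows as the correlogram degrades.
"""

import numpy as np

from itdcode import (Correlogram, LabelledLineEngine, TAU_GRID_US, apply_itd,
                     decode_peak, make_noise_token)

token = apply_itd(make_noise_token(1.0, 16_000.0, seed=3), 200.0)
engine = LabelledLineEngine(token, seed=4)

ref = engine.reference()
print(f"reference correlogram: rates {ref.rate_prenoise.min():.0f}-"
      f"{ref.rate_prenoise.max():.0f} spikes/s before spontaneous noise, "
      f"peak at tau = {decode_peak(ref):+.0f} us (source +200 us)")

for target_r in (0.99, 0.95, 0.90):
    cal = engine.calibrate(target_r, seed=5)
    rates = engine.degraded_batch(cal.alpha, 100, np.random.default_rng(6))
    ests = [decode_peak(Correlogram(TAU_GRID_US, r, 0.0, 200.0))
            for r in rates]
    print(f"target r={target_r:.2f}: alpha={cal.alpha:.3f} "
          f"(achieved {cal.achieved_r:.3f}, rel. err "
          f"{100 * cal.relative_error:.2f}%), decoded ITD over 100 draws: "
          f"{np.mean(ests):+6.1f} +/- {np.std(ests):4.1f} us")
# mean decoded ITD is essentially level (r) invariant; only the spread
# grows -- the labelled line predicts no medial bias at low intensity
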