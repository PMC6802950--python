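"""Hemispheric-difference (rate code) walkthrough: medial bias at low level.

Builds the mirrored population of inferior-colliculus-like units, fits
the pooled rate likelihood, and decodes a +375 us source at several sound
levels with bootstrap uncertainty.
"""

from itdcode import (bootstrap_decode, build_population, fit_likelihood,
                     hemispheric_difference)

pop = build_population(n_units=81, seed=2)
print(f"population: {len(pop.contra)} contra + {len(pop.ipsi)} mirrored "
      "ipsi units")

for level in (5.0, 60.0):
    d = hemispheric_difference(pop, 375.0, level)
    print(f"hemispheric rate difference at +375 us, {level:g} dB SPL: "
          f"{d:+6.1f} spikes/s")
# the contra-minus-ipsi signal is steep at high level but nearly flat
# near threshold -- the source of the rate code's level dependence

lik = fit_likelihood(pop, seed=3)
print("\nmaximum-likelihood decodes of a +375 us source "
      "(100 bootstrap resamples):")
for level in (0.0, 5.0, 10.0, 30.0, 60.0, 80.0):
    res = bootstrap_decode(lik, pop, 375.0, level, n_boot=100, seed=4)
    print(f"  {level:4.0f} dB SPL -> {res['mean_us']:+7.1f} "
          f"+/- {res['sem_us']:5.1f} us")
# at and below ~10 dB SPL the decoded direction collapses toward the
# midline (medial bias); from ~30 dB up it is level invariant at +375 us
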