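"""Summarise serotonin-injection effects on ear tuning over time.

Simulates a single-injection experiment (a sustained +75 Hz tuning
shift with 8 Hz measurement noise) and a two-injection experiment
(serotonin then a receptor antagonist that pulls tuning back down),
then prints the loess-based summaries: median dFrequency and
min dFrequency.
"""

from mozear.injection import median_delta_frequency, min_delta_frequency
from mozear.synthgen import gen_injection_series

single, truth = gen_injection_series(seed=2, effect_hz=75.0)
res = median_delta_frequency(single)
print(f"single injection: true shift {truth.parameters['effect_hz']:+.0f} Hz, "
      f"median dFrequency {res.median_delta_hz:+.1f} Hz "
      f"(baseline {res.baseline_hz:.1f} Hz)")

double, truth2 = gen_injection_series(
    seed=3, effect_hz=150.0,
    second_compound="methiothepin", second_effect_hz=-70.0)
res2 = min_delta_frequency(double)
print(f"two injections : serotonin phase median {res2.phase1_median_delta_hz:+.1f} Hz, "
      f"min dFrequency after antagonist {res2.min_delta_hz:+.1f} Hz "
      f"(true second step {truth2.parameters['second_effect_hz']:+.0f} Hz)")
# median dFrequency is the median of per-minute smoothed shifts over the
# 35 min after injection; min dFrequency is the deepest point of the
# post-antagonist curve relative to the level reached under serotonin.
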