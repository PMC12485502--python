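"""Detect a fatigue episode with the reliability-change stopping rule.

Simulates a trainee whose noise scale spikes x3 for 5 repetitions just
past mid-series, monitors reliability at a tube volume calibrated so the
steady-state success probability is 0.95, and applies the |dR| >= 0.05
stopping rule.
"""

import math

from scipy.stats import chi

from rvskill import (
    apply_stopping_rule,
    arc_length,
    fatigue_profile,
    make_standard_path,
    reliability_trace,
    simulate_repetitions,
)

sigma, n_points = 0.8, 200
standard = make_standard_path("helix", scale=1.0, n_points=n_points)
reps = simulate_repetitions(standard, fatigue_profile(sigma=sigma, n_reps=50, seed=3))

# tube radius whose closed-form containment probability is 0.95
d95 = sigma * chi(3).ppf(0.95 ** (1.0 / n_points))
volume = math.pi * d95**2 * arc_length(standard)

trace = reliability_trace(standard, reps, (10, 25, 50), fixed_volume=volume)
decision = apply_stopping_rule(trace, delta_threshold=0.05)

print(f"monitoring volume: {volume:.2f} cm^3 (radius {d95:.3f} cm)")
print("reliability per checkpoint:", [f"{v:.2f}" for v in trace.values])
if decision.triggered:
    print(f"stopping rule triggered at checkpoint {decision.trigger_checkpoint} "
          f"(dR = {decision.delta_r:+.2f}); pause training, read skill from "
          f"checkpoint {decision.stop_checkpoint}")
else:
    print("no reliability change >= 0.05: continue training")
# The noise spike makes several repetitions exit the tube, so reliability
# drops between the last two checkpoints and the rule fires.
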