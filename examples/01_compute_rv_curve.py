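"""Compute an RV curve for a simulated training session.

Builds a two-loop helix standard path, simulates 50 imitation repetitions
with constant isotropic noise, and prints the RV curve's headline numbers:
the tube volume at full reliability (every repetition contained) and the
smallest volume still reached with 95% reliability.
"""

from rvskill import (
    arc_length,
    compute_rv_curve,
    flat_profile,
    make_standard_path,
    simulate_repetitions,
    volume_at_reliability,
)

standard = make_standard_path("helix", scale=1.0, n_points=200)
reps = simulate_repetitions(standard, flat_profile(sigma=0.8, n_reps=50, seed=1))
curve = compute_rv_curve(standard, reps)

print(f"standard path arc length h = {arc_length(standard):.2f} cm")
print(f"repetitions M = {reps.M}, points per path N = {reps.N}")
print(f"max RV volume (R = 1):   {curve.max_volume:8.2f} cm^3")
print(f"volume at R >= 0.95:     {volume_at_reliability(curve, 0.95):8.2f} cm^3")
print()
print("largest five rungs (d_cm, volume_cm3, reliability):")
for p in curve.points[:5]:
    print(f"  d = {p.d:5.3f}  V = {p.volume:7.2f}  R = {p.reliability:4.2f}")
# Each rung is a tolerance tube around the standard path: V = pi d^2 h is
# its volume and R the fraction of repetitions staying entirely inside it.
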