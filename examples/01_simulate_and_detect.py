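"""Simulate a hinged helix pair and recover its pivot.

Builds two states of an idealized A-form helix whose distal arm is rotated
10° about a hinge after base pair 6, with 0.3 Å coordinate noise, then runs
the stem-decoupled detection and compares against the generator's ground
truth.
"""

from rnapivot import detect_pivots
from rnapivot.synthetic import HingeSpec, make_hinge_pair

spec = HingeSpec(n_stem=6, n_arm=12, hinge_angle_deg=10.0, noise_sigma=0.3,
                 seed=42)
state_a, state_b, truth = make_hinge_pair(spec)

(call,) = detect_pivots(state_a, state_b, [truth.stem])

print(f"true pivot residue      : {truth.pivot_residue}")
print(f"detected pivot residue  : {call.pivot_location}")
print(f"tip displacement        : {call.displacement:.2f} A  "
      f"(analytic chord {truth.expected_tip_chord:.2f} A)")
print(f"stem residual after fit : {call.stem_residual:.3f} A")
print(f"motif at pivot          : {call.motif_class}")
# The detected pivot should sit within one residue of the truth; the tip
# displacement approximates 2*sin(theta/2)*r_tip, degraded only by noise.
# The stem residual near the noise level confirms the stem really is rigid.
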