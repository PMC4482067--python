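"""Per-residue deviation profile along a hinged helix.

After superimposing the two states on the rigid stem, deviations stay at
the noise floor up to the hinge and then grow linearly with the distance
from the hinge axis — the signature used to localize the pivot.
"""

from rnapivot import align_stem, deviation_profile
from rnapivot.synthetic import HingeSpec, make_hinge_pair

state_a, state_b, truth = make_hinge_pair(
    HingeSpec(n_stem=6, n_arm=10, hinge_angle_deg=12.0, noise_sigma=0.2,
              seed=7))

result, b_aligned = align_stem(state_a, state_b, truth.stem)
profile = deviation_profile(state_a, b_aligned, truth.stem)

print(f"stem residual: {result.rmsd_kept:.3f} A "
      f"({result.n_rejected}/{result.n_input} atom pairs rejected)")
print("residue  deviation_A  expected_chord_A")
for residue, deviation in profile.entries:
    expected = truth.expected_chord(residue)
    marker = " <- pivot" if residue == truth.pivot_residue else ""
    print(f"{residue:7d}  {deviation:11.2f}  {expected:16.2f}{marker}")
# Each deviation tracks the analytic chord 2*sin(theta/2)*r_j of its
# residue; the onset of sustained divergence marks the pivot.
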