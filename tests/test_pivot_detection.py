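"""Stem-decoupled pivot localization and displacement quantification."""

import numpy as np
import pytest

from rnapivot.pivot_detection import (
    DetectionConfig,
    DeviationProfile,
    StemIncompleteError,
    align_stem,
    detect_pivots,
    deviation_profile,
    estimate_hinge_rotation,
    locate_pivot,
    screen_mobile_helices,
    tip_displacement,
)
from rnapivot.stems import StemDefinition


def test_rigid_stem_has_negligible_residual(hinge_factory):
    a, b, truth = hinge_factory(theta=10.0, sigma=0.0)
    sr, _ = align_stem(a, b, truth.stem)
    assert sr.rmsd_kept < 1e-6


def test_no_motion_residual_tracks_noise(hinge_factory):
    a, b, truth = hinge_factory(theta=0.0, sigma=0.3, seed=4)
    sr, b_t = align_stem(a, b, truth.stem)
    assert 0.1 < sr.rmsd_all < 1.0     # of the order of the noise
    profile = deviation_profile(a, b_t, truth.stem)
    assert max(profile.deviations()) < 6 * 0.3


def test_stem_crossing_the_hinge_is_exposed(hinge_factory):
    """If the chosen stem straddles the hinge, the stem residual blows up
    far beyond the noise level — the diagnostic for a bad catalog entry."""
    a, b, truth = hinge_factory(n_stem=6, n_arm=10, theta=20.0, sigma=0.0)
    bad = StemDefinition(
        helix_id="bad", chain="A",
        stem_ranges=[(4, 10)],           # spans the hinge at 6/7
        path_ranges=[(11, truth.stem.helix_path()[-1])],
        tip_residue=truth.tip_residue)
    sr_bad, _ = align_stem(a, b, bad)
    sr_good, _ = align_stem(a, b, truth.stem)
    assert sr_bad.rmsd_kept > 100 * max(sr_good.rmsd_kept, 1e-6)


def test_profile_zero_for_identical_models(hinge_factory):
    a, _, truth = hinge_factory()
    profile = deviation_profile(a, a, truth.stem)
    assert max(profile.deviations()) < 1e-12


def test_profile_step_for_rigid_distal_translation(hinge_factory):
    """Translating everything distal to the hinge by 5 Å gives deviations of
    exactly 0 before and 5.0 after the step."""
    a, _, truth = hinge_factory(theta=0.0, sigma=0.0)
    b = a.copy()
    mobile = set(truth.mobile_residues)
    for res in b.chains["A"]:
        if res.author_number in mobile:
            for atom in res.atoms:
                atom.position = atom.position + np.array([0.0, 5.0, 0.0])
    sr, b_t = align_stem(a, b, truth.stem)
    profile = deviation_profile(a, b_t, truth.stem)
    for num, dev in profile.entries:
        expected = 5.0 if num in mobile else 0.0
        assert dev == pytest.approx(expected, abs=1e-9)
    assert tip_displacement(a, b_t, truth.stem) == pytest.approx(5.0, abs=1e-9)


def test_profile_matches_chord_oracle(hinge_factory):
    """Noise-free deviations equal the analytic chord 2·sin(θ/2)·r_j from
    the generator's truth record, residue by residue."""
    a, b, truth = hinge_factory(theta=12.0, sigma=0.0)
    _, b_t = align_stem(a, b, truth.stem)
    profile = deviation_profile(a, b_t, truth.stem)
    for num, dev in profile.entries:
        assert dev == pytest.approx(truth.expected_chord(num), abs=1e-9)


def test_profile_flags_missing_residue(hinge_factory):
    a, b, truth = hinge_factory()
    missing = truth.stem.helix_path()[2]
    b.chains["A"] = [r for r in b.chains["A"] if r.author_number != missing]
    _, b_t = align_stem(a, b, truth.stem)
    profile = deviation_profile(a, b_t, truth.stem)
    gaps = [num for num, d in profile.entries if d is None]
    assert gaps == [missing]


class TestLocatePivot:
    def test_all_zero_profile_gives_no_pivot(self):
        profile = DeviationProfile(
            "h", "A", [(i, 0.0) for i in range(1, 7)], "per_residue_backbone_mean")
        assert locate_pivot(profile, threshold=1.0) is None

    def test_step_profile_localizes_onset(self):
        profile = DeviationProfile(
            "h", "A", list(zip(range(1, 7), [0.0, 0.0, 0.0, 3.0, 4.0, 5.0])),
            "per_residue_backbone_mean")
        assert locate_pivot(profile, threshold=1.0, persistence=2) == 4

    def test_persistence_suppresses_isolated_spike(self):
        profile = DeviationProfile(
            "h", "A", list(zip(range(1, 7), [0.0, 6.0, 0.0, 3.0, 4.0, 5.0])),
            "per_residue_backbone_mean")
        assert locate_pivot(profile, threshold=1.0, persistence=2) == 4

    def test_absent_entries_are_skipped(self):
        profile = DeviationProfile(
            "h", "A", [(1, 0.0), (2, None), (3, 2.0), (4, 2.5)],
            "per_residue_backbone_mean")
        assert locate_pivot(profile, threshold=1.0, persistence=2) == 3


def test_tip_displacement_matches_chord(hinge_factory):
    a, b, truth = hinge_factory(theta=10.0, sigma=0.0)
    _, b_t = align_stem(a, b, truth.stem)
    assert tip_displacement(a, b_t, truth.stem) == pytest.approx(
        truth.expected_tip_chord, abs=1e-9)


def test_detect_on_self_reports_zero_everywhere(hinge_factory):
    a, _, truth = hinge_factory()
    calls = detect_pivots(a, a, [truth.stem], annotate=False)
    assert len(calls) == 1
    assert calls[0].displacement == pytest.approx(0.0, abs=1e-9)
    assert calls[0].pivot_location is None


def test_detect_flags_subthreshold_motion(hinge_factory):
    """A hinge much smaller than the comparison's global control RMSD is
    reported but marked sub-threshold, not dropped."""
    a, b, truth = hinge_factory(theta=0.3, sigma=0.25, seed=6)
    calls = detect_pivots(a, b, [truth.stem], annotate=False)
    call = calls[0]
    assert call.displacement == call.displacement   # present (not NaN)
    assert "sub_threshold" in call.flags


def test_detect_continues_past_bad_stem(hinge_factory):
    a, b, truth = hinge_factory()
    broken = StemDefinition(helix_id="ghost", chain="A",
                            stem_ranges=[(900, 905)], path_ranges=[(906, 910)],
                            tip_residue=908)
    calls = detect_pivots(a, b, [broken, truth.stem], annotate=False)
    assert len(calls) == 2
    assert any(f.startswith("error:") for f in calls[0].flags)
    assert calls[1].pivot_location is not None


def test_missing_stem_residues_named(hinge_factory):
    a, b, truth = hinge_factory()
    b.chains["A"] = [r for r in b.chains["A"] if r.author_number != 2]
    with pytest.raises(StemIncompleteError, match="2"):
        align_stem(a, b, truth.stem)


def test_screen_identical_models_is_empty(screen_pair):
    a, _, _ = screen_pair
    assert screen_mobile_helices(a, a) == []


def test_screen_reports_only_the_hinged_helix(screen_pair):
    a, b, truth = screen_pair
    regions = screen_mobile_helices(a, b)
    assert regions, "hinged helix not detected"
    assert {r.chain for r in regions} == {"M"}
    lo = min(r.start for r in regions)
    hi = max(r.end for r in regions)
    assert abs(lo - truth.mobile_residues[0]) <= 2
    assert abs(hi - truth.mobile_residues[-1]) <= 2


def test_hinge_angle_recovered_from_arm_rotation(hinge_factory):
    a, b, truth = hinge_factory(theta=17.0, sigma=0.0)
    _, b_t = align_stem(a, b, truth.stem)
    angle = estimate_hinge_rotation(a, b_t, "A", truth.mobile_residues)
    assert angle == pytest.approx(17.0, abs=0.1)


def test_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(metric="nope")
    with pytest.raises(ValueError):
        DetectionConfig(persistence=0)
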