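"""Coupled-motion measurement and the pivot contact network."""

import math

import numpy as np
import pytest

from rnapivot.cascade_analysis import cascade_table, contact_network, network_graph
from rnapivot.pivot_detection import detect_pivots
from rnapivot.synthetic import HingeSpec, make_hinge_pair, make_two_hinge_construct


def _construct(theta_up=10.0, theta_local=0.0, sigma=0.0, seed=0):
    up = HingeSpec(n_stem=5, n_arm=7, hinge_angle_deg=theta_up,
                   noise_sigma=sigma, seed=seed)
    lo = HingeSpec(n_stem=4, n_arm=6, hinge_angle_deg=theta_local)
    return make_two_hinge_construct(up, lo)


def test_rigidly_carried_branch_shows_upstream_motion_only():
    """With the local hinge frozen, the branch tip moves by the chord of the
    upstream hinge at the branch-tip radius when aligned at the upstream
    stem, and by nothing when aligned at its own stem."""
    a, b, truths = _construct(theta_up=10.0, theta_local=0.0)
    rows = cascade_table(a, b, truths["upstream"].stem, [truths["local"].stem])
    (row,) = rows
    r_tip = truths["upstream"].axis_distances[("B", truths["local"].tip_residue)]
    expected = 2 * math.sin(math.radians(5.0)) * r_tip
    assert row.displacement_upstream_aligned == pytest.approx(expected, abs=1e-6)
    assert row.displacement_individual < 1e-9
    assert "individual_below_floor" in row.flags
    assert row.amplification == pytest.approx(
        row.displacement_upstream_aligned / 0.05, rel=1e-6)


def test_both_hinges_give_local_chord_individually():
    a, b, truths = _construct(theta_up=10.0, theta_local=7.0)
    rows = cascade_table(a, b, truths["upstream"].stem, [truths["local"].stem])
    (row,) = rows
    assert row.displacement_individual == pytest.approx(
        truths["local"].expected_tip_chord, abs=1e-6)
    assert row.displacement_upstream_aligned > row.displacement_individual


def test_zero_upstream_hinge_columns_agree():
    a, b, truths = _construct(theta_up=0.0, theta_local=8.0, sigma=0.1, seed=3)
    rows = cascade_table(a, b, truths["upstream"].stem, [truths["local"].stem])
    (row,) = rows
    noise = 3 * 0.1
    assert abs(row.displacement_upstream_aligned
               - row.displacement_individual) < 3 * noise


def test_identical_models_give_all_zeros():
    a, _, truths = _construct()
    rows = cascade_table(a, a, truths["upstream"].stem, [truths["local"].stem])
    (row,) = rows
    assert row.displacement_upstream_aligned == pytest.approx(0.0, abs=1e-9)
    assert row.displacement_individual == pytest.approx(0.0, abs=1e-9)


def test_upstream_alignment_strictly_amplifies(hinge_factory):
    """Across several upstream angles, the upstream-aligned displacement
    strictly exceeds the individually aligned one (noise-free)."""
    for theta in (2.0, 5.0, 10.0, 20.0):
        a, b, truths = _construct(theta_up=theta, theta_local=0.0)
        (row,) = cascade_table(a, b, truths["upstream"].stem,
                               [truths["local"].stem])
        assert row.displacement_upstream_aligned > row.displacement_individual


def test_failed_downstream_helix_is_recorded_not_fatal():
    a, b, truths = _construct()
    from rnapivot.stems import StemDefinition
    ghost = StemDefinition(helix_id="ghost", chain="B",
                           stem_ranges=[(500, 505)], path_ranges=[(506, 510)],
                           tip_residue=508)
    rows = cascade_table(a, b, truths["upstream"].stem,
                         [ghost, truths["local"].stem])
    assert len(rows) == 2
    assert any(f.startswith("error:") for f in rows[0].flags)
    assert rows[1].displacement_upstream_aligned > 0


class TestContactNetwork:
    def test_distant_pivots_without_cascade_have_no_edges(self, hinge_factory):
        a, b, truth = hinge_factory(theta=10.0)
        far_a, far_b, far_truth = hinge_factory(theta=10.0)
        for model in (far_a, far_b):
            for res in model.chains["A"]:
                res.chain_id = "Z"
                for atom in res.atoms:
                    atom.position = atom.position + np.array([50.0, 0.0, 0.0])
        a.chains["Z"] = far_a.chains["A"]
        b.chains["Z"] = far_b.chains["A"]
        far_stem = far_truth.stem
        far_stem.chain = "Z"
        far_stem.helix_id = "far"
        calls = detect_pivots(a, b, [truth.stem, far_stem], annotate=False)
        edges = contact_network(calls, a)
        assert edges == []

    def test_touching_helices_form_one_physical_edge(self):
        a, b, truths = _construct(theta_up=10.0, theta_local=0.0)
        calls = detect_pivots(a, b, [truths["upstream"].stem,
                                     truths["local"].stem], annotate=False)
        # trunk loop and branch stem sit within a few Å by construction
        edges = contact_network(calls, a, cutoff=8.0)
        physical = [e for e in edges if e.kind == "physical_contact"]
        assert len(physical) == 1
        assert physical[0].value < 8.0

    def test_induced_motion_edge_from_cascade(self):
        a, b, truths = _construct(theta_up=10.0, theta_local=0.0)
        rows = cascade_table(a, b, truths["upstream"].stem,
                             [truths["local"].stem])
        calls = detect_pivots(a, b, [truths["upstream"].stem,
                                     truths["local"].stem], annotate=False)
        edges = contact_network(calls, a, cascade_rows=rows,
                                amplification_factor=1.5)
        induced = [e for e in edges if e.kind == "induced_motion"]
        assert len(induced) == 1
        assert (induced[0].pivot_a, induced[0].pivot_b) == ("trunk", "branch")

    def test_graph_symmetry_conventions(self):
        a, b, truths = _construct(theta_up=10.0, theta_local=0.0)
        rows = cascade_table(a, b, truths["upstream"].stem,
                             [truths["local"].stem])
        calls = detect_pivots(a, b, [truths["upstream"].stem,
                                     truths["local"].stem], annotate=False)
        edges = contact_network(calls, a, cutoff=8.0, cascade_rows=rows)
        g = network_graph(edges)
        for e in edges:
            if e.kind == "physical_contact":
                assert g.has_edge(e.pivot_a, e.pivot_b)
                assert g.has_edge(e.pivot_b, e.pivot_a)
            else:
                assert g.has_edge(e.pivot_a, e.pivot_b)
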