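import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixcm import (ContactSpec, assign_bw_numbers, build_ideal_helix,
                     classify_aromatic, classify_chi1, contact_audit,
                     detect_ionic_lock)
from helixcm.structure import AtomRecord, HelixStructure, Residue


def ring(center, normal, radius=1.39, n=6):
    """Planar n-membered ring with a given centre and normal."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ normal) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return center + radius * (np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2))


def residue_with(index, name, atoms, chain="A"):
    return Residue(index, name, chain,
                   [AtomRecord(an, an[0], index, name, chain, np.asarray(c, float))
                    for an, c in atoms])


class TestChi1Rotamers:
    @pytest.mark.parametrize("chi1, label", [(-60.0, "g+"), (180.0, "trans"),
                                             (65.0, "g-"), (-120.0, "g+"),
                                             (0.0, "g-"), (120.0, "trans")])
    def test_window_convention(self, chi1, label):
        assert classify_chi1(chi1).label == label

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(min_value=-179.999, max_value=180.0))
    def test_windows_partition_the_circle(self, chi1):
        labels = [classify_chi1(chi1).label]
        assert len(labels) == 1 and labels[0] in {"g+", "g-", "trans"}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_chi1(200.0)

    def test_built_tryptophan_chi1_round_trips(self):
        h = build_ideal_helix(["ALA", "TRP", "ALA", "ALA"], chi1=-60.0)
        h.measure_internal()
        assert classify_chi1(h.chi1[1]).label == "g+"


class TestIonicLock:
    def _structure(self, d_acceptor, angle_deg=170.0):
        """Arg donor with guanidinium NH1 at the origin; Thr OG1 placed at the
        requested distance/donor angle."""
        theta = np.radians(180.0 - angle_deg)
        acc = d_acceptor * np.array([np.cos(theta), np.sin(theta), 0.0])
        arg = residue_with(10, "ARG", [
            ("N", [-6, 0, 0]), ("CA", [-5, 0, 0]), ("C", [-4.3, 1, 0]),
            ("CZ", [-1.33, 0, 0]), ("NH1", [0, 0, 0]), ("NH2", [-2, 1.1, 0]),
            ("NE", [-2, -1.1, 0]),
        ])
        thr = residue_with(40, "THR", [
            ("N", acc + [3, 2, 0]), ("CA", acc + [2.5, 1, 0]), ("C", acc + [3, 0, 0]),
            ("CB", acc + [1.4, 0, 0]), ("OG1", acc),
        ])
        s = HelixStructure([arg, thr])
        bw = assign_bw_numbers(60, {3: 10, 6: 60}, spans={3: (1, 20), 6: (30, 60)})
        return s, bw

    def test_close_linear_pair_is_formed(self):
        s, bw = self._structure(2.9)
        res = detect_ionic_lock(s, bw, donor="3.50", acceptor="6.30")
        assert res.formed
        assert res.distance == pytest.approx(2.9)
        assert {res.donor_atom, res.acceptor_atom} == {"NH1", "OG1"}

    def test_distant_pair_is_broken(self):
        s, bw = self._structure(6.0)
        assert detect_ionic_lock(s, bw, donor="3.50", acceptor="6.30").status == "broken"

    def test_criteria_bounds_are_inclusive(self):
        # acceptor placed on the donor axis: distance exactly 3.5 (an exact
        # binary float), donor angle 180
        s, bw = self._structure(3.5, angle_deg=180.0)
        res = detect_ionic_lock(s, bw, donor="3.50", acceptor="6.30")
        assert res.distance == 3.5
        assert res.formed
        # the angle bound is inclusive too: require exactly the measured angle
        res2 = detect_ionic_lock(s, bw, donor="3.50", acceptor="6.30",
                                 min_angle=res.angle_deg)
        assert res2.formed

    def test_missing_sidechain_is_indeterminate_with_warning(self):
        arg = residue_with(10, "ARG", [("N", [0, 0, 0]), ("CA", [1.4, 0, 0]),
                                       ("C", [2, 1, 0])])
        thr = residue_with(40, "THR", [("N", [5, 0, 0]), ("CA", [6, 0, 0]),
                                       ("C", [7, 1, 0]), ("OG1", [5, 2, 0]),
                                       ("CB", [5.5, 1, 0])])
        s = HelixStructure([arg, thr])
        bw = assign_bw_numbers(60, {3: 10, 6: 60}, spans={3: (1, 20), 6: (30, 60)})
        res = detect_ionic_lock(s, bw, donor="3.50", acceptor="6.30")
        assert res.status == "indeterminate"
        assert "missing side-chain atoms" in res.warning


class TestAromaticContacts:
    def test_coplanar_stack_is_parallel(self):
        a = ring([0, 0, 0], [0, 0, 1])
        b = ring([0, 0, 3.8], [0, 0, 1])
        c = classify_aromatic(a, b)
        assert c.contact_class == "parallel"
        assert c.interplanar_angle == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_over_face_is_t_stack(self):
        a = ring([0, 0, 0], [0, 0, 1])
        b = ring([0, 0, 5.0], [1, 0, 0])
        assert classify_aromatic(a, b).contact_class == "T-stack"

    def test_perpendicular_edge_on_is_edge_to_face(self):
        a = ring([0, 0, 0], [0, 0, 1])
        b = ring([5.0, 0, 0.3], [0, 1, 0])
        assert classify_aromatic(a, b).contact_class == "edge-to-face"

    def test_intermediate_tilt_is_tilted_t(self):
        from helixcm._geom import rotation_matrix

        n = rotation_matrix([0, 1, 0], 45.0) @ np.array([0, 0, 1.0])
        a = ring([0, 0, 0], [0, 0, 1])
        b = ring([0, 0, 4.5], n)
        assert classify_aromatic(a, b).contact_class == "tilted-T"

    def test_beyond_cutoff_is_none(self):
        a = ring([0, 0, 0], [0, 0, 1])
        b = ring([0, 0, 9.0], [1, 0, 0])
        assert classify_aromatic(a, b).contact_class == "none"

    def test_classification_is_symmetric(self):
        a = ring([0, 0, 0], [0, 0, 1])
        b = ring([1.2, 0.5, 4.6], [0.3, 0.1, 1.0])
        ca = classify_aromatic(a, b)
        cb = classify_aromatic(b, a)
        assert ca.contact_class == cb.contact_class
        assert ca.centroid_distance == pytest.approx(cb.centroid_distance)

    def test_nonplanar_ring_rejected_with_deviation(self):
        a = ring([0, 0, 0], [0, 0, 1])
        bent = a.copy()
        bent[0, 2] += 0.8
        with pytest.raises(ValueError, match="out-of-plane"):
            classify_aromatic(bent, ring([0, 0, 4], [0, 0, 1]))


class TestContactAudit:
    def _triad(self, spacing):
        """Ser/Thr/Ser polar triad with consecutive O-O distances `spacing`."""
        res = []
        for k, (idx, name, og) in enumerate(
                [(10, "SER", "OG"), (30, "THR", "OG1"), (50, "SER", "OG")]):
            base = np.array([k * spacing, 0.0, 0.0])
            res.append(residue_with(idx, name, [
                ("N", base + [0, 3, 0]), ("CA", base + [0, 2, 0]),
                ("C", base + [1, 2, 0]), ("CB", base + [0, 1, 0]), (og, base),
            ]))
        s = HelixStructure(res)
        bw = assign_bw_numbers(70, {1: 10, 2: 30, 7: 50},
                               spans={1: (1, 20), 2: (21, 40), 7: (41, 70)})
        specs = ContactSpec.chain("hbond", "1.50", "2.50", "7.50")
        return s, bw, specs

    def test_close_triad_fully_satisfied(self):
        s, bw, specs = self._triad(2.8)
        results = contact_audit(s, bw, specs)
        assert [r.status for r in results] == ["satisfied", "satisfied"]
        assert all(r.measured_distance == pytest.approx(2.8) for r in results)

    def test_separated_triad_fully_unsatisfied(self):
        s, bw, specs = self._triad(8.0)
        results = contact_audit(s, bw, specs)
        assert [r.status for r in results] == ["unsatisfied", "unsatisfied"]

    def test_each_expected_interaction_appears_exactly_once(self):
        s, bw, specs = self._triad(2.8)
        results = contact_audit(s, bw, specs)
        assert [r.spec for r in results] == specs

    def test_absent_label_is_unresolvable_not_a_crash(self):
        s, bw, _ = self._triad(2.8)
        results = contact_audit(s, bw, [ContactSpec("hbond", "1.50", "4.50")])
        assert results[0].status == "unresolvable"
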