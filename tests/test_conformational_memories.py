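import numpy as np
import pytest
from scipy import stats

from helixcm import (FreeBondAngle, FreeDihedral, HingeSpec, build_ideal_helix,
                     make_schedule, metropolis_accept, run_cm,
                     sample_fixed_temperature, superpose_ensemble)
from helixcm.conformational_memories import (KB, ConformerEnsemble,
                                             EmptyMemoryError, MemoryMap,
                                             _CMState, propose_move)
from helixcm.energy import ForceFieldParams


def short(t_start, t_end, n, steps=1500):
    return make_schedule(t_start, t_end, n, steps)


class TestSchedule:
    @pytest.mark.parametrize(
        "t_start, t_end, n",
        [(3000.0, 310.0, 18), (749.4, 310.0, 9), (310.0, 310.0, 5)],
    )
    def test_ladder_endpoints_and_length(self, t_start, t_end, n):
        temps = make_schedule(t_start, t_end, n).temperatures()
        assert len(temps) == n
        assert temps[0] == pytest.approx(t_start)
        assert temps[-1] == pytest.approx(t_end)

    def test_cooling_is_geometric(self):
        temps = make_schedule(3000.0, 310.0, 18).temperatures()
        ratios = temps[1:] / temps[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_single_step_with_distinct_endpoints_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(3000.0, 310.0, 1)

    def test_heating_schedule_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(310.0, 3000.0, 5)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-5.0, T, rng) for T in (10.0, 310.0, 3000.0))

    def test_non_finite_delta_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(float("nan"), 310.0, rng)

    def test_acceptance_probability_matches_boltzmann_factor(self):
        rng = np.random.default_rng(11)
        n = 20_000
        de = KB * 310.0 * np.log(2.0)
        acc = sum(metropolis_accept(de, 310.0, rng) for _ in range(n)) / n
        assert acc == pytest.approx(0.5, abs=0.02)


class TestProposeMove:
    def test_move_changes_two_dihedrals_and_one_bond_angle(
            self, hinge_helix, hinge_spec, params):
        state = _CMState(hinge_helix, hinge_spec, params)
        rng = np.random.default_rng(4)
        for _ in range(25):
            _, dih, ang = propose_move(state, rng)
            assert int(np.sum(~np.isclose(dih, state.dih_values))) == 2
            assert int(np.sum(~np.isclose(ang, state.ang_values))) == 1

    def test_proline_hinge_respects_database_ranges(self, params):
        h = build_ideal_helix("AAAAAAAAPAAAAAAA", psi=-35.0)
        spec = HingeSpec.for_hinge(h, 8)
        pro = [d for d in spec.free_dihedrals if d.residue_pos == 8]
        by_name = {d.name: (d.lo, d.hi) for d in pro}
        assert by_name["phi"] == (-120.0, 40.0)
        assert by_name["psi"] == (-70.0, 0.0)
        assert by_name["omega"] == (-160.0, 160.0)
        state = _CMState(h, spec, params)
        rng = np.random.default_rng(5)
        k_phi = next(i for i, d in enumerate(spec.free_dihedrals)
                     if d.residue_pos == 8 and d.name == "phi")
        for _ in range(300):
            _, dih, _ = propose_move(state, rng)
            assert -120.0 <= dih[k_phi] <= 40.0

    def test_biased_mode_confined_to_single_retained_bin(
            self, hinge_helix, hinge_spec, params):
        state = _CMState(hinge_helix, hinge_spec, params)
        nd = len(hinge_spec.free_dihedrals)
        # synthetic memory: every dihedral retains only the [55, 65) bin
        samples = np.full((50, nd), 60.0)
        from helixcm.conformational_memories import _make_memory

        memory = _make_memory(hinge_spec.free_dihedrals, samples, 10.0, 0.01)
        rng = np.random.default_rng(6)
        for _ in range(100):
            _, dih, _ = propose_move(state, rng, memory)
            changed = dih[~np.isclose(dih, state.dih_values)]
            assert np.all((changed >= 50.0) & (changed < 70.0))

    def test_empty_memory_instructs_to_lower_threshold(
            self, hinge_helix, hinge_spec, params):
        state = _CMState(hinge_helix, hinge_spec, params)
        nd = len(hinge_spec.free_dihedrals)
        memory = MemoryMap(
            hinge_spec.free_dihedrals, 10.0,
            [np.array([-180.0, 180.0])] * nd, [np.array([0.0])] * nd, 0.01,
        )
        with pytest.raises(EmptyMemoryError, match="retention threshold"):
            propose_move(state, np.random.default_rng(0), memory)


class TestSampling:
    def test_flat_landscape_samples_uniformly(self, torsion_only_params):
        # zero energy everywhere: the accepted marginal must be uniform
        h = build_ideal_helix("A" * 8)
        spec = HingeSpec(4, (FreeDihedral(4, "psi", -180.0, 180.0, "undefined"),), ())
        samples = sample_fixed_temperature(h, spec, torsion_only_params,
                                           310.0, 20_000, seed=3)[:, 0]
        counts, _ = np.histogram(samples, bins=18, range=(-180, 180))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_acceptance_rate_does_not_increase_on_cooling(self, torsion_only_params):
        # rugged analytic landscape: acceptance is non-increasing in 1/T
        h = build_ideal_helix("A" * 8)
        spec = HingeSpec(
            4,
            (FreeDihedral(4, "psi", -180.0, 180.0, "threefold"),
             FreeDihedral(4, "phi", -180.0, 180.0, "threefold")),
            (),
        )
        rates = {T: [] for T in (2000.0, 900.0, 310.0)}
        for seed in range(3):
            for T in rates:
                s = sample_fixed_temperature(h, spec, torsion_only_params, T,
                                             4_000, seed=seed)
                moves = np.any(np.diff(s, axis=0) != 0, axis=1)
                rates[T].append(moves.mean())
        means = [np.mean(rates[T]) for T in (2000.0, 900.0, 310.0)]
        assert means[0] >= means[1] - 0.02 >= means[2] - 0.04


class TestRunCM:
    def test_reduced_run_is_bit_reproducible(self, hinge_helix, hinge_spec, params):
        kwargs = dict(exploratory=short(3000, 310, 6), biased=short(749.4, 310, 4),
                      n_output=20, seed=42)
        m1, e1 = run_cm(hinge_helix, hinge_spec, params, **kwargs)
        m2, e2 = run_cm(hinge_helix, hinge_spec, params, **kwargs)
        assert np.array_equal(e1.energies, e2.energies)
        assert all(np.array_equal(a.coords(), b.coords())
                   for a, b in zip(e1.frames, e2.frames))
        assert all(np.array_equal(c1, c2) for c1, c2 in zip(m1.counts, m2.counts))

    def test_memory_invariants_and_biased_support(self, hinge_helix, hinge_spec, params):
        memory, ensemble = run_cm(hinge_helix, hinge_spec, params,
                                  exploratory=short(3000, 310, 6),
                                  biased=short(749.4, 310, 4),
                                  n_output=30, seed=7)
        n_acc = memory.n_accepted
        assert n_acc > 0
        for i in range(len(memory.dihedrals)):
            assert memory.counts[i].sum() == n_acc
            retained = memory.retained(i)
            assert np.all(memory.counts[i][retained] > 0)
        # every output conformer's free dihedrals lie inside retained bins
        for frame in ensemble.frames:
            frame.measure_internal()
            for i, d in enumerate(memory.dihedrals):
                v = getattr(frame, d.name)[d.residue_pos]
                assert any(lo - 0.02 <= v < hi + 0.02
                           for lo, hi in memory.retained_intervals(i))

    def test_provenance_records_the_run_configuration(self, hinge_helix,
                                                      hinge_spec, params):
        _, ens = run_cm(hinge_helix, hinge_spec, params,
                        exploratory=short(3000, 310, 4), biased=short(749.4, 310, 3),
                        n_output=10, seed=9)
        assert ens.provenance["seed"] == 9
        assert ens.provenance["biased"][0] == pytest.approx(749.4)
        assert len(ens.provenance["acceptance_trace"]["exploratory"]) == 4


class TestSuperpose:
    def _tiny_ensemble(self):
        h = build_ideal_helix("A" * 16)
        return h

    def test_identical_copies_have_zero_anchor_rmsd(self):
        from helixcm.helix_geometry import kabsch_rmsd

        h = self._tiny_ensemble()
        ens = ConformerEnsemble([h.copy(), h.copy()], np.zeros(2))
        sup = superpose_ensemble(ens, (2, 10))
        a = sup.frames[0].backbone_coords(residue_slice=slice(2, 11))
        b = sup.frames[1].backbone_coords(residue_slice=slice(2, 11))
        assert kabsch_rmsd(a, b, superpose=False) < 1e-12

    def test_rigid_motion_is_removed(self):
        from helixcm._geom import rotation_matrix
        from helixcm.helix_geometry import kabsch_rmsd

        h = self._tiny_ensemble()
        g = h.copy()
        R = rotation_matrix([0.3, 1.0, -2.0], 55.0)
        g.set_coords(g.coords() @ R.T + np.array([4.0, 4.0, -1.0]))
        sup = superpose_ensemble(ConformerEnsemble([h, g], np.zeros(2)), (0, 15))
        a = sup.frames[0].backbone_coords()
        b = sup.frames[1].backbone_coords()
        assert kabsch_rmsd(a, b, superpose=False) < 1e-9

    def test_kinked_frames_keep_distal_spread_after_anchor_fit(self):
        from helixcm.helix_geometry import kabsch_rmsd
        from helixcm.synthetic_data import KinkConstruction, build_kinked_helix

        straight = build_ideal_helix("A" * 24)
        kinked, _ = build_kinked_helix(KinkConstruction(true_bend_deg=30.0))
        ens = ConformerEnsemble([straight, kinked], np.zeros(2))
        sup = superpose_ensemble(ens, (0, 10))  # anchor on the proximal half
        a0 = sup.frames[0].backbone_coords(residue_slice=slice(0, 11))
        a1 = sup.frames[1].backbone_coords(residue_slice=slice(0, 11))
        assert kabsch_rmsd(a0, a1, superpose=False) < 1e-6
        d0 = sup.frames[0].backbone_coords(residue_slice=slice(18, 24))
        d1 = sup.frames[1].backbone_coords(residue_slice=slice(18, 24))
        assert kabsch_rmsd(d0, d1, superpose=False) > 3.0

    def test_short_anchor_rejected(self):
        h = self._tiny_ensemble()
        with pytest.raises(ValueError):
            superpose_ensemble(ConformerEnsemble([h.copy()], np.zeros(1)), (3, 4))
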