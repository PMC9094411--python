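import numpy as np
import pytest

from kissfret.geometry import ideal_hairpin, synthetic_kissing_construct
from kissfret.gomodel import (CGParams, CGState, TopologyError,
                              build_topology, energy, forces, initial_state,
                              integrate_langevin, radius_of_gyration, relax,
                              simulated_time_us, trajectory_observables)


class TestTopology:
    def test_site_count_is_three_per_residue_minus_5prime_p(self, hairpin,
                                                            hairpin_topology):
        structure, _ = hairpin
        n_res = hairpin_topology.n_residues
        assert n_res == 12
        assert hairpin_topology.n_sites == 3 * n_res - 1

    def test_paired_bases_form_hbond_contacts(self, hairpin_topology):
        top = hairpin_topology
        hbond_pairs = set()
        for (i, j), cls in zip(top.contacts, top.contact_class):
            if cls == "hbond":
                hbond_pairs.add(frozenset((top.res_ids[top.site_residue[i]],
                                           top.res_ids[top.site_residue[j]])))
        assert hbond_pairs == {frozenset(p) for p in
                               [(1, 12), (2, 11), (3, 10), (4, 9)]}

    def test_noninteracting_cap_contributes_no_contacts(self, hairpin):
        structure, pairing = hairpin
        top = build_topology(structure, pairing=pairing,
                             noninteracting_residues=[("A", 12)])
        cap_res = top.n_residues - 1
        cap_sites = set(np.flatnonzero(top.site_residue == cap_res))
        for i, j in top.contacts:
            assert i not in cap_sites and j not in cap_sites
        assert np.all(top.charges[top.site_residue == cap_res] == 0)

    def test_missing_backbone_atoms_listed(self, hairpin):
        structure, pairing = hairpin
        keep = structure.atom_name != "C4'"
        keep |= structure.res_id != 3
        broken = structure.subset(keep)
        with pytest.raises(TopologyError, match="A/3"):
            build_topology(broken, pairing=pairing)

    def test_sequence_edit_map_deletes_residues(self, hairpin):
        structure, pairing = hairpin
        top = build_topology(structure, pairing=pairing,
                             sequence_edit_map={("A", 6): None})
        assert top.n_residues == 11


class TestEnergy:
    def test_reference_zeroes_bonded_terms(self, hairpin_topology):
        terms = energy(hairpin_topology, hairpin_topology.ref_coords)
        assert terms["bond"] == pytest.approx(0.0, abs=1e-9)
        assert terms["angle"] == pytest.approx(0.0, abs=1e-9)
        n_contacts = len(hairpin_topology.contacts)
        # every native contact sits at its minimum -eps at the reference
        assert terms["native"] < 0
        assert terms["native"] == pytest.approx(
            -sum({"hbond": 3.0, "stack": 2.0, "tertiary": 2.0}[c]
                 for c in hairpin_topology.contact_class), rel=1e-9)

    def test_electrostatics_vanish_beyond_cutoff(self):
        structure, pairing = ideal_hairpin(n_bp=2, loop="AA")
        top = build_topology(structure, pairing=pairing)
        coords = top.ref_coords.copy()
        # pull the molecule apart into two distant halves
        coords[top.n_sites // 2:] += np.array([10.0, 0.0, 0.0])
        params = CGParams()
        terms = energy(top, coords, params)
        p_sites = np.flatnonzero(top.site_kind == "P")
        # phosphates of the two halves are > 3 nm apart: only intra-half terms
        left = [i for i in p_sites if i < top.n_sites // 2]
        right = [i for i in p_sites if i >= top.n_sites // 2]
        for i in left:
            for j in right:
                r = np.linalg.norm(coords[i] - coords[j])
                assert r > params.elec_cutoff

    def test_forces_match_numerical_gradient(self, hairpin_topology):
        params = CGParams()
        rng = np.random.default_rng(0)
        coords = hairpin_topology.ref_coords + rng.normal(0, 0.01, (hairpin_topology.n_sites, 3))
        f, _ = forces(hairpin_topology, coords, params)
        h = 1e-6
        for idx in [(0, 0), (5, 1), (20, 2)]:
            cp = coords.copy(); cp[idx] += h
            cm = coords.copy(); cm[idx] -= h
            num = -(energy(hairpin_topology, cp, params)["total"]
                    - energy(hairpin_topology, cm, params)["total"]) / (2 * h)
            assert f[idx] == pytest.approx(num, rel=1e-4, abs=1e-5)


class TestDynamics:
    def test_same_seed_bitwise_identical(self, hairpin_topology):
        params = CGParams()
        s = initial_state(hairpin_topology, params, seed=3)
        t1 = integrate_langevin(hairpin_topology, s, params, 500, seed=4)
        s2 = CGState(coords=s.coords.copy(), velocities=s.velocities.copy())
        t2 = integrate_langevin(hairpin_topology, s2, params, 500, seed=4)
        assert np.array_equal(t1.frames, t2.frames)

    def test_equipartition_under_thermostat(self, hairpin_topology):
        params = CGParams(friction=0.2)
        state = initial_state(hairpin_topology, params, seed=5)
        kes = []
        current = state
        for _ in range(15):
            traj = integrate_langevin(hairpin_topology, current, params,
                                      2000, seed=len(kes), stride=2000)
            current = traj.final_state
            ke = 0.5 * (hairpin_topology.masses[:, None]
                        * current.velocities ** 2).sum()
            kes.append(ke / (3 * hairpin_topology.n_sites))
        mean_ke = np.mean(kes[3:])  # skip equilibration
        assert mean_ke == pytest.approx(0.5 * params.temperature, rel=0.05)

    def test_divergence_detected(self, hairpin_topology):
        params = CGParams(h=5.0)  # absurdly large step
        state = initial_state(hairpin_topology, params, seed=6,
                              relax_reference=False)
        with pytest.raises(Exception, match="smaller time step"):
            integrate_langevin(hairpin_topology, state, params, 2000, seed=6)

    def test_simulated_time_bookkeeping(self):
        assert simulated_time_us(1.5e9) == pytest.approx(3.75)
        assert simulated_time_us(1) == pytest.approx(2.5e-9)


class TestObservables:
    def test_rg_closed_form_two_sites(self):
        structure, pairing = ideal_hairpin(n_bp=2, loop="AA")
        top = build_topology(structure, pairing=pairing)
        top.masses[:] = 0.0
        top.masses[:2] = 1.0
        coords = np.zeros((top.n_sites, 3))
        coords[1] = [2.0, 0.0, 0.0]
        assert radius_of_gyration(coords, top) == pytest.approx(1.0)
        top.masses[:] = 1.0

    def test_rg_translation_invariant_and_matches_oracle(self,
                                                         hairpin_topology):
        rng = np.random.default_rng(7)
        coords = rng.normal(0, 2.0, (hairpin_topology.n_sites, 3))
        rg = radius_of_gyration(coords, hairpin_topology)
        shifted = radius_of_gyration(coords + [5.0, -3.0, 1.0],
                                     hairpin_topology)
        assert rg == pytest.approx(shifted, abs=1e-10)
        m = hairpin_topology.masses
        com = (m[:, None] * coords).sum(0) / m.sum()
        direct = np.sqrt(sum(mi * ((c - com) ** 2).sum()
                             for mi, c in zip(m, coords)) / m.sum())
        assert rg == pytest.approx(direct, abs=1e-10)

    def test_frozen_trajectory_constant_observables(self, hairpin_topology):
        from kissfret.gomodel import CGTrajectory
        coords = hairpin_topology.ref_coords
        traj = CGTrajectory(frames=np.array([coords, coords]),
                            times=np.array([0.0, 1.0]),
                            final_state=CGState(coords, np.zeros_like(coords)))
        b_first = hairpin_topology.site_index(0, "B")
        b_last = hairpin_topology.site_index(hairpin_topology.n_residues - 1, "B")
        obs = trajectory_observables(traj, hairpin_topology,
                                     (b_first, b_last), grid_spacing=1.2)
        assert obs["rg"].nunique() == 1
        assert obs["efficiency"].nunique() == 1

    def test_folded_vs_extended_geometry(self, hairpin_topology):
        top = hairpin_topology
        folded = top.ref_coords
        extended = np.column_stack([np.arange(top.n_sites) * 0.55,
                                    np.zeros(top.n_sites),
                                    np.zeros(top.n_sites)])
        from kissfret.avfret import snapshot_fret
        a, b = 0, top.n_sites - 1
        e_fold = snapshot_fret(folded, top.radii, (a, b), grid_spacing=1.2)
        e_ext = snapshot_fret(extended, top.radii, (a, b), grid_spacing=1.2)
        assert e_fold > e_ext
        assert radius_of_gyration(folded, top) < radius_of_gyration(extended, top)


class TestElectrostaticSurrogate:
    def test_stronger_screening_contracts_charged_chain(self):
        """Raising the Mg2+ screening surrogate weakens the phosphate
        repulsion that stretches a straight charged chain, so the relaxed
        chain contracts monotonically."""
        from kissfret.avfret import Structure

        n_res = 15
        names, rids, coords = [], [], []
        for i in range(n_res):
            for name, off in (("P", (0.0, 0.0, 0.0)),
                              ("C4'", (2.5, 3.0, 0.0)),
                              ("N1", (2.5, 6.0, 0.0))):
                names.append(name)
                rids.append(i + 1)
                coords.append(np.array([7.0 * i, 0.0, 0.0]) + off)  # Angstrom
        structure = Structure(np.array(names), np.array(rids),
                              np.array(["A"] * len(names)),
                              np.array(["A"] * len(names)),
                              np.array([n[0] for n in names]),
                              np.array(coords),
                              np.zeros(len(names), bool))
        top = build_topology(structure, pairing=[])
        rgs = []
        for factor in (0.0, 2.0, 8.0):
            params = CGParams(mg_screening_factor=factor)
            relaxed = relax(top, params)
            rgs.append(radius_of_gyration(relaxed, top))
        assert rgs[0] >= rgs[1] >= rgs[2]
        assert rgs[2] < rgs[0]


class TestKissingConstructModel:
    def test_construct_build_and_contacts(self):
        structure, pairing = synthetic_kissing_construct()
        top = build_topology(structure, pairing=pairing)
        assert top.n_residues == 35  # 23-nt P1 hairpin + 12-nt shortened P2
        kiss = [(ci, ri, cj, rj) for (ci, ri, cj, rj) in pairing
                if ci != cj]
        assert len(kiss) == 2
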