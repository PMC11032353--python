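"""Engine assembly: brute-force oracles, gradients, conservation laws."""

import math

import numpy as np
import pytest

from dropletmd.dynamics import State
from dropletmd.forcefield import (angle_modulation, debye_huckel_energy,
                                  debye_length, excluded_volume_energy,
                                  hps_pair_energy, morse_components,
                                  relative_permittivity)
from dropletmd.forcefield.engine import total_energy_forces
from dropletmd.forcefield import geometry
from dropletmd.spatial import neighbor_lists_for
from dropletmd.topology import (PWMcosSite, build_dsdna_topology,
                                build_protein_topology, identity_placements,
                                replicate_system)

BOX = np.array([80.0, 80.0, 80.0])


def small_cutoffs(params):
    import copy
    ps = copy.deepcopy(params)
    ps.cutoffs.exv, ps.cutoffs.dna, ps.cutoffs.hps, ps.cutoffs.ele = \
        10.0, 12.0, 14.0, 16.0
    return ps


def random_hps_system(params, rng, n_chains=4, length=5):
    top1 = build_protein_topology("DEKRA"[:length] if length <= 5 else
                                  "DEKRA" * (length // 5),
                                  [((1, length), "HPS")], params)
    top = replicate_system(top1, n_chains, identity_placements(n_chains))
    coords = rng.uniform(0, BOX[0], size=(top.n_particles, 3))
    state = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                  seed=0)
    return top, state


def evaluate(top, state, ps):
    _grid, nl = neighbor_lists_for(top, state.coords, state.box, ps)
    return total_energy_forces(top, state, ps, nl)


class TestPairOracles:
    def test_isolated_pair_beyond_cutoff(self, params):
        ps = small_cutoffs(params)
        top1 = build_protein_topology("A", [((1, 1), "HPS")], params)
        top = replicate_system(top1, 2, identity_placements(2))
        coords = np.array([[10.0, 10, 10], [40.0, 10, 10]])
        st = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                   seed=0)
        energies, forces = evaluate(top, st, ps)
        assert all(v == 0.0 for v in energies.values())
        assert np.all(forces == 0.0)

    def test_hps_system_matches_double_loop(self, params, rng):
        """Engine energy equals an O(N^2) sum of the scalar pair terms."""
        ps = small_cutoffs(params)
        top, st = random_hps_system(ps, rng)
        energies, _ = evaluate(top, st, ps)

        excl = set(map(tuple, top.bonded_exclusions()))
        eps_r = relative_permittivity(ps.env.temperature,
                                      ps.env.salt_molarity)
        lam_d = debye_length(ps.env.temperature, ps.env.ionic, eps_r)
        e_hps = e_ele = 0.0
        n = top.n_particles
        for i in range(n):
            for j in range(i + 1, n):
                d = st.coords[j] - st.coords[i]
                d -= BOX * np.round(d / BOX)
                r = float(np.linalg.norm(d))
                if (i, j) in excl:
                    continue
                ci, cj = str(top.code[i]), str(top.code[j])
                if r < ps.cutoffs.hps:
                    sig = 0.5 * (ps.hps.sigma[ci] + ps.hps.sigma[cj])
                    lam = 0.5 * (ps.hps.lam[ci] + ps.hps.lam[cj])
                    e_hps += hps_pair_energy(r, sig, lam, ps.hps.eps)[0]
                if r < ps.cutoffs.ele and top.charge[i] * top.charge[j] != 0:
                    e_ele += debye_huckel_energy(
                        r, top.charge[i], top.charge[j], eps_r, lam_d)[0]
        assert energies["hps"] == pytest.approx(e_hps, rel=1e-10)
        assert energies["ele"] == pytest.approx(e_ele, rel=1e-10)

    def test_newtons_third_law(self, params, rng):
        ps = small_cutoffs(params)
        top, st = random_hps_system(ps, rng, n_chains=6)
        _, forces = evaluate(top, st, ps)
        assert np.abs(forces.sum(axis=0)).max() < 1e-9


class TestGradients:
    def numeric_force(self, top, st, ps, i, ax, h=1e-5):
        _grid, nl = neighbor_lists_for(top, st.coords, st.box, ps)
        cp = st.coords.copy()
        cp[i, ax] += h
        ep, _ = total_energy_forces(
            top, State(coords=cp, velocities=st.velocities, box=st.box,
                       seed=0), ps, nl)
        cm = st.coords.copy()
        cm[i, ax] -= h
        em, _ = total_energy_forces(
            top, State(coords=cm, velocities=st.velocities, box=st.box,
                       seed=0), ps, nl)
        return -(sum(ep.values()) - sum(em.values())) / (2 * h)

    def check_system(self, top, st, ps, picks, tol=1e-5):
        _, forces = evaluate(top, st, ps)
        for i in picks:
            for ax in range(3):
                num = self.numeric_force(top, st, ps, i, ax)
                assert forces[i, ax] == pytest.approx(num, rel=tol, abs=1e-6)

    def test_protein_system_forces(self, params, rng):
        """Analytic forces equal -dE/dx for a mixed folded/disordered chain."""
        ps = small_cutoffs(params)
        top1 = build_protein_topology(
            "DEKRAGHEAF", [((1, 3), "HPS"), ((4, 8), "AICG2+"),
                           ((9, 10), "HPS")], ps)
        top = replicate_system(top1, 3, identity_placements(3))
        # compact self-avoiding configuration: no overlaps, so the total
        # energy stays small enough for clean finite differences
        from dropletmd.synthetic import gen_droplet
        coords = gen_droplet(3, 10, 14.0, seed=5, center=BOX / 2,
                             min_sep=3.6)
        st = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                   seed=0)
        self.check_system(top, st, ps, picks=[0, 4, 7, 12, 21, 29], tol=2e-5)

    def test_dna_system_forces(self, params, rng):
        ps = small_cutoffs(params)
        top = build_dsdna_topology("ACGTA", ps)
        coords = top.ref_coords + BOX / 2 - top.ref_coords.mean(axis=0)
        coords = coords + rng.normal(0, 0.1, coords.shape)
        st = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                   seed=0)
        self.check_system(top, st, ps, picks=[0, 3, 8, 14, 20, 25], tol=5e-5)

    def test_rigid_motion_invariance(self, params, rng):
        ps = small_cutoffs(params)
        top = build_dsdna_topology("ACGT", ps)
        coords = top.ref_coords + BOX / 2 - top.ref_coords.mean(axis=0)
        coords += rng.normal(0, 0.05, coords.shape)
        st = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                   seed=0)
        e0, _ = evaluate(top, st, ps)

        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0],
                        [0, 0, 1.0]])
        center = BOX / 2
        moved = (coords - center) @ rot.T + center + np.array([3.1, -2.2, 1.4])
        st2 = State(coords=moved, velocities=np.zeros_like(coords), box=BOX,
                    seed=0)
        e1, _ = evaluate(top, st2, ps)
        for k, v in e0.items():
            assert e1[k] == pytest.approx(v, rel=1e-9, abs=1e-9), k

    def test_stale_lists_rejected(self, params, rng):
        ps = small_cutoffs(params)
        top, st = random_hps_system(ps, rng)
        _grid, nl = neighbor_lists_for(top, st.coords, st.box, ps)
        nl.stale = True
        with pytest.raises(RuntimeError, match="stale"):
            total_energy_forces(top, st, ps, nl)


class TestDNAMultibody:
    def test_ideal_duplex_is_reference_minimum(self, params):
        """At the built geometry every Morse/modulation factor sits at its
        reference: stack/pair/cross equal minus the summed depths."""
        top = build_dsdna_topology("ACGT", params)
        coords = top.ref_coords + BOX / 2 - top.ref_coords.mean(axis=0)
        st = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                   seed=0)
        energies, _ = evaluate(top, st, params)
        assert energies["dna_stack"] == pytest.approx(
            -float(top.dna_stack.params[:, 0].sum()), rel=1e-9)
        assert energies["dna_pair"] == pytest.approx(
            -float(top.dna_pair.params[:, 0].sum()), rel=1e-9)
        assert energies["dna_cross"] == pytest.approx(
            -float(top.dna_cross.params[:, 0].sum()), rel=1e-9)

    def test_antiparallel_pairing_gate_closes(self, params):
        """Rotating one strand's sugar so the pairing dihedral flips by pi
        kills the attractive factor, leaving only Morse repulsion."""
        top = build_dsdna_topology("AT", params)
        coords = top.ref_coords + BOX / 2 - top.ref_coords.mean(axis=0)

        blk = top.dna_pair
        row = blk.indices[0]
        s1, b1, b2, s2 = (int(v) for v in row)
        # reflect S2 through the B1-B2 axis: dihedral shifts by ~pi
        axis = coords[b2] - coords[b1]
        axis /= np.linalg.norm(axis)
        v = coords[s2] - coords[b2]
        coords2 = coords.copy()
        coords2[s2] = coords[b2] + 2 * np.dot(v, axis) * axis - v
        phi, *_ = geometry.dihedral_value_grad(
            coords2[[s1]], coords2[[b1]], coords2[[b2]], coords2[[s2]])
        dphi = abs(geometry.wrap_angle(phi[0] - blk.params[0, 5]))
        assert dphi > 3.0
        st = State(coords=coords2, velocities=np.zeros_like(coords2),
                   box=BOX, seed=0)
        energies, _ = evaluate(top, st, params)
        # modulation angles also moved, but the (1 + cos dphi)/2 factor alone
        # caps the attraction near zero
        eps, alpha, r0 = blk.params[0, 0], blk.params[0, 1], blk.params[0, 2]
        attr_gate = 0.5 * (1 + math.cos(dphi))
        assert attr_gate < 0.02

    def test_random_geometry_matches_scalar_composition(self, params, rng):
        """Stack term = rep + f(dtheta) attr built from the scalar pieces."""
        top = build_dsdna_topology("ACG", params)
        coords = top.ref_coords + BOX / 2 - top.ref_coords.mean(axis=0)
        coords += rng.normal(0, 0.3, coords.shape)
        st = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                   seed=0)
        energies, _ = evaluate(top, st, params)

        expected = 0.0
        for row, par in zip(top.dna_stack.indices, top.dna_stack.params):
            s, b1, b2 = (int(v) for v in row)
            eps, alpha, r0, th0, gam = par
            r = float(np.linalg.norm(coords[b2] - coords[b1]))
            theta, *_ = geometry.angle_value_grad(
                coords[[s]], coords[[b1]], coords[[b2]])
            (rep, _), (attr, _) = morse_components(r, eps, alpha, r0)
            f, _ = angle_modulation(float(theta[0]) - th0, gam)
            expected += rep + f * attr
        assert energies["dna_stack"] == pytest.approx(expected, rel=1e-10)


class TestPWMcos:
    def make_system(self, params, gamma=0.4):
        """One DNA base pair plus a two-residue folded chain nearby."""
        top = build_dsdna_topology("ATA", params)
        prot = build_protein_topology("AKA", [((1, 3), "AICG2+")], params)
        n0 = top.n_particles
        import dataclasses
        merged = dataclasses.replace(top)
        merged.chain_id = np.concatenate([top.chain_id, prot.chain_id + 2])
        merged.residue_index = np.concatenate([top.residue_index,
                                               prot.residue_index])
        merged.kind = np.concatenate([top.kind, prot.kind])
        merged.code = np.concatenate([top.code, prot.code])
        merged.charge = np.concatenate([top.charge, np.zeros(3)])
        merged.mass = np.concatenate([top.mass, prot.mass])
        merged.bonds = top.bonds + [
            dataclasses.replace(b, indices=b.indices + n0)
            for b in prot.bonds]
        merged.angles = top.angles
        merged.dihedrals = top.dihedrals

        base, sugar = 4, 3        # middle base of strand 1 and its sugar
        base5, base3 = 1, 7
        ca, ca_prev, ca_next = n0 + 1, n0, n0 + 2
        coords = np.vstack([top.ref_coords,
                            top.ref_coords[base] + np.array([
                                [6.0, 0.0, -3.8], [6.0, 0.0, 0.0],
                                [6.0, 0.0, 3.8]])])
        # reference geometry measured from the construction itself
        r0 = float(np.linalg.norm(coords[ca] - coords[base]))
        th1, *_ = geometry.angle_value_grad(
            coords[[sugar]], coords[[base]], coords[[ca]])
        th2, *_ = geometry.vector_angle_grad(
            coords[[base5]], coords[[base3]], coords[[base]], coords[[ca]])
        th3, *_ = geometry.vector_angle_grad(
            coords[[ca_prev]], coords[[ca_next]], coords[[base]], coords[[ca]])
        site = PWMcosSite(base, sugar, base5, base3, ca, ca_prev, ca_next,
                          eps_g=1.3, w=1.0, r0=r0,
                          theta1_0=float(th1[0]), theta2_0=float(th2[0]),
                          theta3_0=float(th3[0]), gamma=gamma)
        merged.pwmcos_sites = [site]
        return merged, coords, site

    def test_reference_geometry_gives_full_depth(self, params):
        top, coords, site = self.make_system(params)
        coords = coords + BOX / 2 - coords.mean(axis=0)
        st = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                   seed=0)
        energies, _ = evaluate(top, st, params)
        assert energies["pwmcos"] == pytest.approx(-site.eps_g, rel=1e-9)

    def test_wide_angle_contributes_nothing(self, params):
        top, coords, site = self.make_system(params, gamma=0.1)
        site.theta1_0 = site.theta1_0 + 0.5  # > 2 gamma away
        coords = coords + BOX / 2 - coords.mean(axis=0)
        st = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                   seed=0)
        energies, _ = evaluate(top, st, params)
        assert energies["pwmcos"] == 0.0

    def test_forces_match_numeric_gradient(self, params, rng):
        top, coords, _site = self.make_system(params)
        coords = coords + BOX / 2 - coords.mean(axis=0)
        coords += rng.normal(0, 0.05, coords.shape)
        st = State(coords=coords, velocities=np.zeros_like(coords), box=BOX,
                   seed=0)
        tg = TestGradients()
        tg.check_system(top, st, params,
                        picks=[1, 3, 4, 7, top.n_particles - 3,
                               top.n_particles - 2], tol=1e-4)
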