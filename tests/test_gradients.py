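"""Analytic gradients vs finite differences, conservation laws, and the
frozen-environment optimizer."""

import numpy as np
import pytest

from polembed.electrostatics import self_energy
from polembed.embedding import (
    FixedDensityProvider,
    ModelQM,
    QMRegion,
    electrostatic_energy,
    scf_loop,
    total_energy,
)
from polembed.fixtures import make_model_qm_case, make_random_cluster
from polembed.gradients import (
    DihedralRestraint,
    OptimizerError,
    grad_electrostatic,
    grad_polarization,
    mm_gradient_electrostatic,
    mm_gradient_self_energy,
    mm_torques,
    optimize_qm,
    qm_gradients,
    validate_fd,
)
from polembed.mmsystem import MMSite, build_system


def bare_charge_provider(position, z=1.0, label="SA"):
    region = QMRegion(atom_positions=[position], nuclear_charges=[z])
    return ModelQM(region=region, base_charges={label: np.zeros(0)},
                   response=np.zeros((0, 0)))


class TestElectrostaticGradient:
    def test_repulsive_pair_sign_and_value(self):
        # E = 1/r: dE/dx at x=2 is -0.25 (force +0.25 pushes the atom away)
        s = build_system([MMSite(index=0, position=[0, 0, 0], charge=1.0)])
        prov = bare_charge_provider([2.0, 0, 0])
        st = scf_loop(s, prov)
        g = grad_electrostatic(s, st.density, prov.region)
        np.testing.assert_allclose(g, [[-0.25, 0, 0]], atol=1e-14)
        dev, _ = validate_fd(
            lambda p: electrostatic_energy(s, prov.region.density(np.zeros(0),
                                                                  atom_positions=p)),
            prov.region.atom_positions, g, step=1e-4,
        )
        assert dev < 1e-8

    def test_neutral_colocated_pair_zero_gradient(self):
        s = build_system([MMSite(index=0, position=[0, 0, 0], charge=1.0)])
        region = QMRegion(
            atom_positions=[[3.0, 0, 0]], nuclear_charges=[1.0],
            site_atoms=[0], site_offsets=[[0.0, 0.0, 0.0]],
        )
        d = region.density(np.array([-1.0]))
        g = grad_electrostatic(s, d, region)
        np.testing.assert_allclose(g, 0.0, atol=1e-14)

    def test_action_reaction_force_balance(self, random_cluster):
        rng = np.random.default_rng(3)
        region = QMRegion(
            atom_positions=rng.uniform(14, 18, (3, 3)),
            nuclear_charges=[1.0, 2.0, 1.0],
        )
        d = region.density(np.zeros(0))
        g_qm = grad_electrostatic(random_cluster, d, region)
        g_mm = mm_gradient_electrostatic(random_cluster, d)
        assert np.max(np.abs(g_qm.sum(axis=0) + g_mm.sum(axis=0))) < 1e-12


class TestPolarizationGradient:
    def test_rigid_environment_zero(self, model_case):
        _, model = model_case
        s = build_system([MMSite(index=0, position=[20, 0, 0], charge=0.5)])
        st = scf_loop(s, model, "SA")
        g = grad_polarization(s, st.dipoles, st.density, model.region)
        np.testing.assert_allclose(g, 0.0, atol=1e-15)

    def test_single_site_closed_form(self):
        # E_pol(r) = -alpha q^2 / (2 r^4)  =>  dE/dr = 2 alpha q^2 / r^5
        alpha, q, r = 1.5, 1.0, 4.0
        s = build_system([MMSite(index=0, position=[0, 0, 0],
                                 polarizability=alpha)])
        prov = bare_charge_provider([r, 0, 0], z=q)
        st = scf_loop(s, prov, tol_e=1e-13, tol_mu=1e-11)
        g = grad_polarization(s, st.dipoles, st.density, prov.region)
        expected = 2 * alpha * q**2 / r**5
        np.testing.assert_allclose(g, [[expected, 0, 0]], atol=1e-12)


class TestFullGradient:
    def test_matches_fd_of_reconverged_total(self, model_case):
        system, model = model_case
        st = scf_loop(system, model, "SA", tol_e=1e-13, tol_mu=1e-11)
        report = qm_gradients(system, model.region, st)

        def energy(pos):
            s = scf_loop(system, model, "SA", tol_e=1e-13, tol_mu=1e-11,
                         atom_positions=pos)
            return total_energy(s)

        dev, _ = validate_fd(energy, model.region.atom_positions,
                             report.total, step=1e-4)
        assert dev < 1e-6

    def test_report_terms_sum_to_total(self, model_case):
        system, model = model_case
        st = scf_loop(system, model, "SA")
        rep = qm_gradients(system, model.region, st)
        np.testing.assert_allclose(
            rep.total, rep.electrostatic + rep.polarization + rep.qm_internal,
            atol=1e-12,
        )

    def test_unconverged_state_rejected(self, model_case):
        system, model = model_case
        st = scf_loop(system, model, "SA")
        st.converged = False
        with pytest.raises(RuntimeError, match="converged"):
            qm_gradients(system, model.region, st)


class TestMMGradientsAndConservation:
    def test_self_energy_gradient_matches_fd(self):
        s = make_random_cluster(5, seed=11)
        g = mm_gradient_self_energy(s)
        dev, _ = validate_fd(lambda p: self_energy(s.with_positions(p)),
                             s.positions, g, step=1e-4)
        assert dev < 1e-8

    def test_translation_zero_net_force(self):
        s = make_random_cluster(6, seed=3)
        g = mm_gradient_self_energy(s)
        assert np.max(np.abs(g.sum(axis=0))) < 1e-12

    def test_rotation_zero_net_torque(self):
        # forces alone do not balance rotation: site torques mu x E and the
        # quadrupole commutator close the budget
        s = make_random_cluster(6, seed=3)
        forces = -mm_gradient_self_energy(s)
        torque = np.cross(s.positions, forces).sum(axis=0) + mm_torques(s).sum(axis=0)
        assert np.max(np.abs(torque)) < 1e-9

    def test_site_torques_match_fd_of_rotating_multipoles(self):
        from helpers import rotation_matrix
        import dataclasses
        from polembed.mmsystem import pack_quadrupole, unpack_quadrupole

        s = make_random_cluster(4, seed=19)
        taus = mm_torques(s)
        h = 1e-6
        for k in range(s.n_sites):
            for ax in np.eye(3):
                def rotated_energy(angle):
                    R = rotation_matrix(ax, angle)
                    site = s.sites[k]
                    new = dataclasses.replace(
                        site,
                        dipole=R @ site.dipole,
                        quadrupole=pack_quadrupole(
                            R @ unpack_quadrupole(site.quadrupole) @ R.T
                        ),
                    )
                    sites = list(s.sites)
                    sites[k] = new
                    return self_energy(build_system(sites, s.bonds, s.rules,
                                                    groups=list(s.group_ids)))

                fd = -(rotated_energy(h) - rotated_energy(-h)) / (2 * h)
                assert fd == pytest.approx(taus[k] @ ax, abs=1e-7)


class TestValidateFD:
    def test_exact_for_quadratics(self):
        A = np.array([[2.0, 0.5], [0.5, 1.0]])

        def f(x):
            x = x.ravel()
            return 0.5 * x @ A @ x

        x0 = np.array([0.3, -0.7])
        dev, _ = validate_fd(f, x0, A @ x0, step=1e-3)
        assert dev < 1e-12

    def test_second_order_step_scaling(self):
        def f(x):
            return float(np.sum(np.sin(x)))

        x0 = np.array([0.4, 1.1, -0.6])
        g = np.cos(x0)
        dev1, _ = validate_fd(f, x0, g, step=1e-2)
        dev2, _ = validate_fd(f, x0, g, step=5e-3)
        assert dev2 == pytest.approx(dev1 / 4, rel=0.1)

    def test_richardson_beats_plain(self):
        def f(x):
            return float(np.sum(np.exp(x)))

        x0 = np.array([0.2, -0.1])
        g = np.exp(x0)
        plain, _ = validate_fd(f, x0, g, step=1e-3)
        rich, _ = validate_fd(f, x0, g, step=1e-3, richardson=True)
        assert rich < plain

    def test_nonfinite_energy_reported(self):
        def f(x):
            return np.inf if x.ravel()[0] > 1.0 else 0.0

        with pytest.raises(FloatingPointError, match="displaced"):
            validate_fd(f, np.array([1.0]), np.array([0.0]), step=0.1)


class TestOptimizer:
    def two_charge_trap(self):
        mm = build_system(
            [MMSite(index=0, position=[-5, 0, 0], charge=1.0),
             MMSite(index=1, position=[5, 0, 0], charge=1.0)]
        )
        prov = bare_charge_provider([1.7, 0.0, 0.0])
        mask = np.array([[False, True, True]])  # 1-D problem along x
        return mm, prov, mask

    def test_converges_to_analytic_midpoint(self):
        mm, prov, mask = self.two_charge_trap()
        res = optimize_qm(mm, prov, frozen_mask=mask, gtol=1e-7)
        assert abs(res.positions[0, 0]) < 1e-5
        assert res.converged

    def test_energy_nonincreasing_over_accepted_steps(self):
        mm, prov, mask = self.two_charge_trap()
        res = optimize_qm(mm, prov, frozen_mask=mask, gtol=1e-7)
        assert all(np.diff(res.energies) <= 1e-14)

    def test_zero_steps_from_converged_minimum(self):
        mm, prov, mask = self.two_charge_trap()
        res = optimize_qm(mm, prov, initial_positions=[[0.0, 0.0, 0.0]],
                          frozen_mask=mask, gtol=1e-6)
        assert res.n_steps == 0

    def test_dihedral_restraint_gradient_matches_fd(self):
        rng = np.random.default_rng(0)
        pos = 2.0 * rng.standard_normal((4, 3))
        r = DihedralRestraint(atoms=(0, 1, 2, 3), target=0.3, force_k=0.5)
        e, g = r.energy_and_gradient(pos)
        dev, _ = validate_fd(lambda p: r.energy_and_gradient(p)[0], pos, g,
                             step=1e-5)
        assert dev < 1e-8

    def test_restraint_gradient_translation_invariant(self):
        rng = np.random.default_rng(1)
        pos = 2.0 * rng.standard_normal((4, 3))
        r = DihedralRestraint(atoms=(0, 1, 2, 3), target=1.0, force_k=1.0)
        _, g = r.energy_and_gradient(pos)
        assert np.max(np.abs(g.sum(axis=0))) < 1e-12
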