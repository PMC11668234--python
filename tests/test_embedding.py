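"""QM-MM coupling: electrostatic energy, the SCF loop against a monolithic
linear-algebra oracle, and the state-specific correction."""

import dataclasses

import numpy as np
import pytest

from polembed.embedding import (
    ContractError,
    FixedDensityProvider,
    ModelQM,
    QMRegion,
    corrected_excitation,
    electrostatic_energy,
    excitation_energies,
    induced_dipole_potential,
    qm_field_at_polarizable_sites,
    scf_loop,
    state_specific_correction,
    total_energy,
)
from polembed.fixtures import make_model_qm_case, make_random_cluster
from polembed.mmsystem import MMSite, QMDensity, ValidationError, build_system

from helpers import monolithic_fixed_point


def point_density(nuc_pos, nuc_q, dens_pos=(), dens_q=(), label="SA"):
    return QMDensity(
        nuclei_positions=np.asarray(nuc_pos, dtype=float).reshape(-1, 3),
        nuclear_charges=nuc_q,
        density_positions=np.asarray(dens_pos, dtype=float).reshape(-1, 3),
        density_charges=dens_q,
        label=label,
    )


class TestElectrostaticEnergy:
    def test_charge_nucleus(self):
        s = build_system([MMSite(index=0, position=[0, 0, 0], charge=1.0)])
        d = point_density([[2, 0, 0]], [1.0])
        assert electrostatic_energy(s, d) == pytest.approx(0.5, abs=1e-14)

    def test_neutral_atom_at_nucleus(self):
        s = build_system([MMSite(index=0, position=[0, 0, 0], charge=1.0)])
        d = point_density([[2, 0, 0]], [1.0], [[2, 0, 0]], [-1.0])
        assert electrostatic_energy(s, d) == pytest.approx(0.0, abs=1e-14)

    def test_mm_dipole_vs_qm_charge(self):
        s = build_system([MMSite(index=0, position=[0, 0, 0], dipole=[0, 0, 1.0])])
        d = point_density([[0, 0, 2]], [1.0])
        assert electrostatic_energy(s, d) == pytest.approx(0.25, abs=1e-14)

    def test_action_reaction_symmetry(self, random_cluster):
        # MM potentials at QM points vs QM potentials at MM multipoles
        rng = np.random.default_rng(11)
        pts = rng.uniform(14, 18, (4, 3))
        qs = rng.uniform(-1, 1, 4)
        d = point_density(pts, qs)
        e_route_a = electrostatic_energy(random_cluster, d)

        from polembed.electrostatics import source_potential_derivs

        e_route_b = 0.0
        for k in range(random_cluster.n_sites):
            acc = [0.0, np.zeros(3), np.zeros((3, 3))]
            for c in range(len(qs)):
                v = source_potential_derivs(
                    random_cluster.positions[k] - pts[c], qs[c],
                    np.zeros(3), np.zeros((3, 3)), 2,
                )
                for n in range(3):
                    acc[n] = acc[n] + v[n]
            e_route_b += (
                random_cluster.charges[k] * acc[0]
                + random_cluster.dipoles[k] @ acc[1]
                + float(np.tensordot(random_cluster.quadrupoles[k], acc[2]))
            )
        assert e_route_a == pytest.approx(e_route_b, abs=1e-10)


class TestQMField:
    def test_lone_nucleus(self):
        s = build_system([MMSite(index=0, position=[10, 0, 0], polarizability=1.0)])
        d = point_density([[0, 0, 0]], [1.0])
        np.testing.assert_allclose(
            qm_field_at_polarizable_sites(d, s).at_sites, [[0.01, 0, 0]], atol=1e-15
        )

    def test_colocated_neutral_pair(self):
        s = build_system([MMSite(index=0, position=[10, 0, 0], polarizability=1.0)])
        d = point_density([[0, 0, 0]], [1.0], [[0, 0, 0]], [-1.0])
        assert np.all(qm_field_at_polarizable_sites(d, s).at_sites == 0.0)

    def test_matches_brute_force(self, random_cluster):
        rng = np.random.default_rng(2)
        pts = rng.uniform(13, 17, (5, 3))
        qs = rng.uniform(-1, 1, 5)
        d = point_density(pts, qs)
        ours = qm_field_at_polarizable_sites(d, random_cluster).at_sites
        pol = random_cluster.polarizable_indices
        brute = np.zeros((len(pol), 3))
        for i, k in enumerate(pol):
            for c in range(len(qs)):
                x = random_cluster.positions[k] - pts[c]
                brute[i] += qs[c] * x / np.linalg.norm(x) ** 3
        assert np.max(np.abs(ours - brute)) < 1e-12


class TestSCFLoop:
    def test_static_problem_single_iteration(self):
        # non-polarizable MM + fixed density: nothing to iterate
        s = build_system([MMSite(index=0, position=[0, 0, 0], charge=1.0)])
        region = QMRegion(atom_positions=[[4.0, 0, 0]], nuclear_charges=[1.0])
        prov = FixedDensityProvider(region=region, charges={"SA": np.zeros(0)},
                                    energies={"SA": -0.4})
        st = scf_loop(s, prov)
        assert len(st.trace) == 1
        assert st.energies["total"] == pytest.approx(
            st.energies["self"] + st.energies["electrostatic"] - 0.4, abs=1e-14
        )

    def test_zero_response_two_iterations(self, model_case):
        system, model = model_case
        frozen = ModelQM(
            region=model.region,
            base_charges=model.base_charges,
            response=np.zeros_like(model.response),
            base_energies=model.base_energies,
        )
        st = scf_loop(system, frozen, "SA")
        assert len(st.trace) <= 2
        assert st.converged

    def test_fixed_point_matches_monolithic_solve(self, model_case):
        system, model = model_case
        st = scf_loop(system, model, "SA", tol_e=1e-13, tol_mu=1e-11)
        mu_d, mu_p, charges = monolithic_fixed_point(system, model, "SA")
        assert np.max(np.abs(st.dipoles.mu_d - mu_d)) < 1e-8
        assert np.max(np.abs(st.dipoles.mu_p - mu_p)) < 1e-8
        assert np.max(np.abs(st.density.density_charges - charges)) < 1e-8

    def test_fixed_point_independent_of_initial_guess(self, model_case):
        system, model = model_case
        st1 = scf_loop(system, model, "SA", tol_e=1e-13, tol_mu=1e-11)
        q0 = model.base_charges["SA"]
        perturbed = q0 + np.array([0.2, -0.2, 0.0])
        st2 = scf_loop(system, model, "SA", tol_e=1e-13, tol_mu=1e-11,
                       initial_charges=perturbed)
        assert np.max(np.abs(st1.density.density_charges
                             - st2.density.density_charges)) < 1e-8
        assert st1.energies["total"] == pytest.approx(
            st2.energies["total"], abs=1e-10
        )

    def test_energy_decomposition_sums_to_total(self, model_case):
        system, model = model_case
        st = scf_loop(system, model, "SA")
        e = st.energies
        assert e["total"] == pytest.approx(
            e["self"] + e["electrostatic"] + e["polarization"] + e["qm_internal"],
            abs=1e-14,
        )
        assert total_energy(st) == pytest.approx(e["total"], abs=1e-14)

    def test_penalty_small_at_fixed_point(self, model_case):
        system, model = model_case
        st = scf_loop(system, model, "SA", tol_e=1e-12, tol_mu=1e-10)
        assert abs(st.lagrangian_penalty) < 1e-10

    def test_charge_conservation_contract_enforced(self, model_case):
        system, model = model_case

        @dataclasses.dataclass
        class Leaky:
            region: object
            calls: int = 0

            def state_labels(self):
                return ("SA",)

            def respond(self, label, potentials):
                self.calls += 1
                q = model.respond("SA", potentials)
                return q + (0.0 if self.calls == 1 else 0.1)  # leaks charge

            def internal_energy(self, label, charges):
                return 0.0

        with pytest.raises(ContractError, match="charge conservation"):
            scf_loop(system, Leaky(region=model.region), "SA")


class TestModelQMValidation:
    def region(self, m=2):
        return QMRegion(
            atom_positions=np.zeros((m, 3)) + np.arange(m)[:, None],
            nuclear_charges=np.ones(m),
            site_atoms=np.arange(m),
            site_offsets=np.zeros((m, 3)),
        )

    def test_asymmetric_response_rejected(self):
        K = np.array([[-1.0, 1.0], [0.9, -0.9]])
        with pytest.raises(ValidationError, match="symmetric"):
            ModelQM(region=self.region(), base_charges={"SA": [-1, -1]}, response=K)

    def test_nonzero_row_sums_rejected(self):
        K = -np.eye(2)
        with pytest.raises(ValidationError, match="sum to zero"):
            ModelQM(region=self.region(), base_charges={"SA": [-1, -1]}, response=K)

    def test_positive_definite_rejected(self):
        K = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValidationError, match="negative semidefinite"):
            ModelQM(region=self.region(), base_charges={"SA": [-1, -1]}, response=K)

    def test_response_conserves_charge(self, model_case):
        _, model = model_case
        rng = np.random.default_rng(0)
        v = rng.standard_normal(model.region.n_sites)
        q = model.respond("SA", v)
        assert q.sum() == pytest.approx(model.base_charges["SA"].sum(), abs=1e-12)


class TestStateSpecificCorrection:
    def test_identical_densities_zero_correction(self, model_case):
        system, model = model_case
        region = model.region
        d = region.density(model.base_charges["S0"], label="S0")
        ci, cf, dc = state_specific_correction(system, d, d, d)
        assert ci == 0.0 and cf == 0.0 and dc == 0.0

    def test_nonpolarizable_environment_zero_correction(self, model_case):
        _, model = model_case
        bare = build_system([MMSite(index=0, position=[20, 0, 0], charge=0.3)])
        region = model.region
        dI = region.density(model.base_charges["S0"], label="S0")
        dF = region.density(model.base_charges["S1"], label="S1")
        dA = region.density(model.base_charges["SA"], label="SA")
        assert state_specific_correction(bare, dI, dF, dA) == (0.0, 0.0, 0.0)

    def test_matches_brute_force_dense_solves(self, model_case):
        system, model = model_case
        region = model.region
        dI = region.density(model.base_charges["S0"], label="S0")
        dF = region.density(model.base_charges["S1"], label="S1")
        dA = region.density(model.base_charges["SA"], label="SA")
        ci, cf, dc = state_specific_correction(system, dI, dF, dA)

        from helpers import brute_T
        from polembed.electrostatics import multipole_field

        T = brute_T(system)
        e_d = multipole_field(system, "d").at_sites.ravel()
        e_p = multipole_field(system, "p").at_sites.ravel()

        def solve_mu_d(dens):
            f = qm_field_at_polarizable_sites(dens, system).at_sites.ravel()
            return np.linalg.solve(T, f + e_d), f

        def elepol(dens, mu_d):
            f = qm_field_at_polarizable_sites(dens, system).at_sites.ravel()
            return electrostatic_energy(system, dens) - 0.5 * mu_d @ (f + e_p)

        mu_avg, _ = solve_mu_d(dA)
        expected = {}
        for key, dens in (("I", dI), ("F", dF)):
            mu_x, _ = solve_mu_d(dens)
            expected[key] = elepol(dens, mu_x) - elepol(dens, mu_avg)
        assert ci == pytest.approx(expected["I"], abs=1e-10)
        assert cf == pytest.approx(expected["F"], abs=1e-10)
        assert dc == pytest.approx(expected["F"] - expected["I"], abs=1e-10)

    def test_corrections_never_raise_energy(self, model_case):
        # relaxing dipoles to the state's own density is variational
        system, model = model_case
        region = model.region
        dI = region.density(model.base_charges["S0"], label="S0")
        dF = region.density(model.base_charges["S1"], label="S1")
        dA = region.density(model.base_charges["SA"], label="SA")
        ci, cf, _ = state_specific_correction(system, dI, dF, dA)
        assert ci <= 1e-15 and cf <= 1e-15

    def test_mismatched_layouts_rejected(self, model_case):
        system, model = model_case
        region = model.region
        d = region.density(model.base_charges["S0"])
        other = point_density([[0, 0, 0]], [1.0])
        with pytest.raises(ValidationError, match="layout"):
            state_specific_correction(system, d, other, d)


class TestCorrectedExcitation:
    @pytest.mark.parametrize("sa, corr, expected",
                             [(3.50, 0.08, 3.58), (3.63, 0.02, 3.65), (2.0, 0.0, 2.0)])
    def test_arithmetic_in_ev(self, sa, corr, expected):
        assert corrected_excitation(sa, corr) == pytest.approx(expected, abs=1e-12)

    def test_hartree_conversion_boundary(self):
        from polembed.units import EV_PER_HARTREE

        assert corrected_excitation(0.1, 0.01, unit="hartree") == pytest.approx(
            0.11 * EV_PER_HARTREE
        )

    def test_full_pipeline_consistency(self, model_case):
        system, model = model_case
        out = excitation_energies(system, model, "S0", "S1",
                                  tol_e=1e-12, tol_mu=1e-10)
        assert out["dE_SS_eV"] == pytest.approx(
            corrected_excitation(out["dE_SA_eV"], out["dE_corr_eV"]), abs=1e-12
        )
        # the SS correction of the identical-density pair is exactly zero
        same = excitation_energies(system, model, "S0", "S0",
                                   tol_e=1e-12, tol_mu=1e-10)
        assert same["dE_corr_eV"] == pytest.approx(0.0, abs=1e-12)
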