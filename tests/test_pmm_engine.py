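import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from excitonkit._reference import eig_sym_brute
from excitonkit.datamodel import (
    BOHR_PER_ANGSTROM,
    HARTREE_TO_EV,
    PerturbationField,
    UnperturbedElectronicData,
)
from excitonkit.errors import ContractViolation, NumericalSafetyError, PipelineError
from excitonkit.pmm_engine import (
    build_perturbed_hamiltonian,
    compute_potential_and_field,
    diagonalize_perturbed,
    oscillator_strength,
    perturbed_transition_dipole,
    run_site_energy_stage,
    site_energy,
)

from conftest import make_frame, make_two_state_qc

BOHR = 1.0 / BOHR_PER_ANGSTROM  # one bohr in Angstrom


class TestPotentialAndField:
    def test_empty_environment(self, two_state_qc):
        frame = make_frame([(0, 0, 0)], [], [])
        pf = compute_potential_and_field(frame, two_state_qc)
        assert pf.potential == 0.0
        assert np.allclose(pf.field, 0.0)
        assert np.allclose(pf.evaluation_point, [0, 0, 0])

    def test_single_charge_coulomb(self, two_state_qc):
        frame = make_frame([(0, 0, 0)], [(10 * BOHR, 0, 0)], [1.0])
        pf = compute_potential_and_field(frame, two_state_qc)
        assert pf.potential == pytest.approx(0.1, rel=1e-12)
        assert np.allclose(pf.field, [-0.01, 0, 0], atol=1e-14)

    def test_superposition_dipole_pair(self, two_state_qc):
        frame = make_frame(
            [(0, 0, 0)], [(BOHR, 0, 0), (-BOHR, 0, 0)], [1.0, -1.0]
        )
        pf = compute_potential_and_field(frame, two_state_qc)
        assert pf.potential == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(pf.field, [-2.0, 0, 0], atol=1e-12)

    def test_close_contact_guard_names_atom(self, two_state_qc):
        frame = make_frame([(0, 0, 0)], [(0.3, 0, 0)], [1.0])
        with pytest.raises(NumericalSafetyError, match="atom 1"):
            compute_potential_and_field(frame, two_state_qc)

    def test_other_qc_atoms_are_environment(self):
        # each QC's own atom excluded, the other's included with its charge
        qc1 = make_two_state_qc("Q1", atom_xyz=(0, 0, 0))
        qc2 = make_two_state_qc("Q2", atom_xyz=(10 * BOHR, 0, 0))
        frame = make_frame(
            [(0, 0, 0), (10 * BOHR, 0, 0)], [], [],
            qc_ids=["Q1", "Q2"], qc_charges=[0.5, 1.0],
        )
        pf1 = compute_potential_and_field(frame, qc1)
        pf2 = compute_potential_and_field(frame, qc2)
        assert pf1.potential == pytest.approx(0.1, rel=1e-12)  # sees Q2's +1.0
        assert pf2.potential == pytest.approx(0.05, rel=1e-12)  # sees Q1's +0.5


class TestHamiltonian:
    def test_zero_perturbation_is_unperturbed(self, two_state_qc):
        pf = PerturbationField(0.0, np.zeros(3), np.zeros(3))
        h = build_perturbed_hamiltonian(two_state_qc.electronic, 0, pf)
        assert np.allclose(h, np.diag([0.0, 0.07]))

    def test_neutral_qc_ignores_potential(self, two_state_qc):
        pf = PerturbationField(5.0, np.zeros(3), np.zeros(3))
        h = build_perturbed_hamiltonian(two_state_qc.electronic, 0, pf)
        assert np.allclose(h, np.diag([0.0, 0.07]))

    def test_direct_substitution(self, two_state_qc):
        pf = PerturbationField(0.0, np.array([0.001, 0, 0]), np.zeros(3))
        h = build_perturbed_hamiltonian(two_state_qc.electronic, 0, pf)
        assert np.allclose(h, [[0.0, -0.001], [-0.001, 0.07]])

    def test_charged_qc_shifts_all_levels(self, two_state_qc):
        pf = PerturbationField(0.2, np.zeros(3), np.zeros(3))
        h = build_perturbed_hamiltonian(two_state_qc.electronic, -1, pf)
        assert np.allclose(np.diag(h), np.array([0.0, 0.07]) - 0.2)
        # gaps unchanged
        st_ = diagonalize_perturbed(h)
        assert site_energy(st_) == pytest.approx(0.07 * HARTREE_TO_EV, rel=1e-12)

    def test_orthogonal_field_keeps_diagonal(self, two_state_qc):
        pf = PerturbationField(0.0, np.array([0, 0, 0.01]), np.zeros(3))
        h = build_perturbed_hamiltonian(two_state_qc.electronic, 0, pf)
        assert np.allclose(h, np.diag([0.0, 0.07]))

    def test_trace_identity(self, rng):
        # trace(H) = trace(H0) + n qT V - E . sum_i mu_ii
        n = 4
        energies = np.sort(rng.normal(size=n))
        dip = rng.normal(size=(n, n, 3))
        dip = (dip + np.swapaxes(dip, 0, 1)) / 2
        el = UnperturbedElectronicData(energies, dip)
        pf = PerturbationField(rng.normal(), rng.normal(size=3), np.zeros(3))
        q_t = 2
        h = build_perturbed_hamiltonian(el, q_t, pf)
        expected = (energies.sum() + n * q_t * pf.potential
                    - pf.field @ dip[np.arange(n), np.arange(n)].sum(axis=0))
        assert np.trace(h) == pytest.approx(expected, rel=1e-12)


class TestDiagonalize:
    def test_diagonal_input(self):
        st_ = diagonalize_perturbed(np.diag([0.0, 0.07, 0.09]))
        assert np.allclose(st_.energies, [0.0, 0.07, 0.09])
        assert np.allclose(st_.eigenvectors, np.eye(3))

    def test_two_by_two_closed_form(self):
        h = np.array([[0.0, -0.001], [-0.001, 0.07]])
        st_ = diagonalize_perturbed(h)
        delta = np.sqrt(0.035**2 + 1e-6)
        assert np.allclose(st_.energies, [0.035 - delta, 0.035 + delta], atol=1e-14)
        gap = st_.energies[1] - st_.energies[0]
        assert gap == pytest.approx(np.sqrt(0.07**2 + 4e-6), rel=1e-12)
        assert gap == pytest.approx(0.0700286, abs=1e-7)

    def test_matches_charpoly_oracle(self, rng):
        a = rng.normal(size=(5, 5))
        a = (a + a.T) / 2
        st_ = diagonalize_perturbed(a)
        assert np.allclose(st_.energies, eig_sym_brute(a), atol=1e-8)

    def test_rejects_asymmetric(self):
        with pytest.raises(ContractViolation):
            diagonalize_perturbed(np.array([[0.0, 1e-3], [0.0, 1.0]]))

    @given(arrays(float, (6, 6), elements=st.floats(-1, 1)))
    @settings(max_examples=30, deadline=None)
    def test_oracle_agreement_property(self, a):
        from hypothesis import assume

        a = (a + a.T) / 2
        st_ = diagonalize_perturbed(a)
        # characteristic-polynomial roots are ill-conditioned for (near-)
        # degenerate spectra; the oracle contract covers separated eigenvalues
        assume(np.min(np.diff(st_.energies), initial=np.inf) > 1e-3)
        assert np.allclose(st_.energies, eig_sym_brute(a), atol=1e-8)


class TestSiteEnergyAndDipole:
    def test_unperturbed_gap(self, two_state_qc):
        st_ = diagonalize_perturbed(np.diag(two_state_qc.electronic.energies))
        assert site_energy(st_) == pytest.approx(1.9048, abs=1e-4)

    def test_perturbed_gap(self):
        st_ = diagonalize_perturbed(np.array([[0.0, -0.001], [-0.001, 0.07]]))
        assert site_energy(st_) == pytest.approx(27.2114 * 0.0700286, abs=1e-3)

    def test_degenerate_gap_warns(self):
        st_ = diagonalize_perturbed(np.diag([0.1, 0.1]))
        with pytest.warns(UserWarning, match="degenerate"):
            assert site_energy(st_) == 0.0

    def test_identity_eigenvectors_return_input_dipole(self, two_state_qc):
        st_ = diagonalize_perturbed(np.diag([0.0, 0.07]))
        mu = perturbed_transition_dipole(two_state_qc.electronic, st_)
        assert np.allclose(mu, [1, 0, 0])

    def test_sign_flip_property(self, two_state_qc):
        st_ = diagonalize_perturbed(np.array([[0.0, -0.002], [-0.002, 0.07]]))
        mu = perturbed_transition_dipole(two_state_qc.electronic, st_)
        flipped = type(st_)(
            st_.hamiltonian, st_.energies,
            st_.eigenvectors * np.array([1, -1]),
        )
        mu2 = perturbed_transition_dipole(two_state_qc.electronic, flipped)
        assert np.allclose(mu2, -mu)
        assert np.linalg.norm(mu2) == pytest.approx(np.linalg.norm(mu), rel=1e-14)

    @pytest.mark.parametrize("theta", np.linspace(0.0, np.pi / 2, 7))
    def test_mixing_angle_cos2theta(self, theta, two_state_qc):
        c, s = np.cos(theta), np.sin(theta)
        vectors = np.array([[c, -s], [s, c]])
        # brute-force sandwich product per Cartesian component
        dip = two_state_qc.electronic.dipole_matrix
        expected = np.array([
            vectors[:, 0] @ dip[:, :, k] @ vectors[:, 1] for k in range(3)
        ])
        assert np.linalg.norm(expected) == pytest.approx(abs(np.cos(2 * theta)), abs=1e-12)


class TestOscillatorStrength:
    def test_arithmetic(self):
        gap_ev = 0.07 * HARTREE_TO_EV
        assert oscillator_strength(gap_ev, [np.sqrt(3), 0, 0]) == pytest.approx(0.14, rel=1e-12)

    def test_zero_dipole(self):
        assert oscillator_strength(1.9, [0, 0, 0]) == 0.0

    def test_inverse_round_trip(self):
        # f = 0.19 at 1.846 eV implies |mu| ~ 2.05 a.u.
        mu2 = 3 * 0.19 / (2 * 1.846 / HARTREE_TO_EV)
        mu = np.sqrt(mu2)
        assert mu == pytest.approx(2.05, abs=0.01)
        assert oscillator_strength(1.846, [mu, 0, 0]) == pytest.approx(0.19, rel=1e-12)


class TestRunStage:
    def test_zero_charges_constant_trace(self, two_state_qc):
        frames = [
            make_frame([(0, 0, 0)], [(5.0, 1.0 * i, 0)], [0.0], frame_index=i)
            for i in range(10)
        ]
        traces = run_site_energy_stage(frames, [two_state_qc])
        tr = traces["Q1"]
        assert len(tr) == 10
        assert np.allclose(tr.site_energies_ev, 0.07 * HARTREE_TO_EV)
        assert np.allclose(tr.transition_dipoles, [[1, 0, 0]] * 10)

    def test_exclusion_contract(self):
        qc1 = make_two_state_qc("Q1", atom_xyz=(0, 0, 0))
        qc2 = make_two_state_qc("Q2", atom_xyz=(8.0, 0, 0), mu01=(0, 1, 0))
        frame = make_frame(
            [(0, 0, 0), (8.0, 0, 0)], [], [],
            qc_ids=["Q1", "Q2"], qc_charges=[0.0, 0.4],
        )
        traces = run_site_energy_stage([frame], [qc1, qc2])
        # Q2 carries the only charge: Q1 is perturbed, Q2 (its own atom) is not
        assert traces["Q2"].site_energies_ev[0] == pytest.approx(
            0.07 * HARTREE_TO_EV, rel=1e-12
        )
        assert traces["Q1"].site_energies_ev[0] != pytest.approx(
            0.07 * HARTREE_TO_EV, abs=1e-9
        )

    def test_missing_qc_in_frame(self, two_state_qc):
        frame = make_frame([(0, 0, 0)], [], [], qc_ids=["other"])
        with pytest.raises(PipelineError, match="Q1"):
            run_site_energy_stage([frame], [two_state_qc])

    def test_skip_bad_frames(self, two_state_qc):
        good = make_frame([(0, 0, 0)], [(5.0, 0, 0)], [0.1], frame_index=0)
        bad = make_frame([(0, 0, 0)], [(0.1, 0, 0)], [0.1], frame_index=1)
        with pytest.raises(NumericalSafetyError):
            run_site_energy_stage([good, bad], [two_state_qc])
        traces = run_site_energy_stage([good, bad], [two_state_qc],
                                       skip_bad_frames=True)
        assert list(traces["Q1"].frame_indices) == [0]

    def test_constant_potential_invariance_for_neutral_qc(self, two_state_qc):
        # far shell of like charges raises V but leaves the neutral QC's gap alone
        shell = [(100.0 * np.cos(t), 100.0 * np.sin(t), 0.0)
                 for t in np.linspace(0, 2 * np.pi, 12, endpoint=False)]
        frame = make_frame([(0, 0, 0)], shell, [0.5] * 12)
        traces = run_site_energy_stage([frame], [two_state_qc])
        assert traces["Q1"].site_energies_ev[0] == pytest.approx(
            0.07 * HARTREE_TO_EV, abs=1e-9
        )
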