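"""Per-frame perturbed Hamiltonians for quantum centers.

For every environment configuration the electrostatic potential V and field E
exerted by the environment are evaluated at the QC center of mass, the
perturbed Hamiltonian

    H_ij = E_i^0 delta_ij + q_T V delta_ij - E . mu_ij

is assembled in the unperturbed eigenbasis (multipolar expansion truncated at
the dipole term) and diagonalized.  The site energy is the gap between the
perturbed first-excited and ground states.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import scipy.linalg

from .datamodel import (
    BOHR_PER_ANGSTROM,
    HARTREE_TO_EV,
    EnvironmentFrame,
    PerturbationField,
    QuantumCenter,
    SiteEnergyTrace,
    UnperturbedElectronicData,
    center_of_mass,
)
from .errors import ContractViolation, NumericalSafetyError, PipelineError

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-10
DEFAULT_MIN_DISTANCE = 0.5  # Angstrom, guard against charge-on-top singularities


@dataclass
class PerturbedState:
    """Eigen-decomposition of a perturbed QC Hamiltonian (Hartree)."""

    hamiltonian: np.ndarray
    energies: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self) -> None:
        self.hamiltonian = np.asarray(self.hamiltonian, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(np.diff(self.energies) < -1e-14):
            raise ContractViolation("perturbed energies must be ascending")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(len(self.energies)), atol=1e-10, rtol=0.0):
            raise ContractViolation("eigenvectors must be orthonormal to 1e-10")


def frame_center_of_mass(frame: EnvironmentFrame, qc: QuantumCenter) -> np.ndarray:
    """Per-frame center of mass of the QC's atoms (Angstrom)."""
    idx = frame.qc_atom_map[qc.id]
    if len(idx) != qc.n_atoms:
        raise PipelineError(
            f"frame {frame.frame_index}: QC {qc.id!r} maps {len(idx)} atoms, "
            f"property file declares {qc.n_atoms}"
        )
    coords = frame.coordinates[idx]
    return center_of_mass([(el, xyz) for (el, _), xyz in zip(qc.atoms, coords)])


def compute_potential_and_field(
    frame: EnvironmentFrame,
    qc: QuantumCenter,
    *,
    min_distance: float = DEFAULT_MIN_DISTANCE,
) -> PerturbationField:
    """Potential and field (a.u.) from all environment atoms at the QC COM.

    Atoms belonging to the QC itself are excluded; atoms of other QCs are
    included with their fixed charges.

    Raises
    ------
    NumericalSafetyError
        If any environment atom lies within ``min_distance`` (Angstrom) of the
        evaluation point.
    """
    com = frame_center_of_mass(frame, qc)
    own = frame.qc_atom_map[qc.id]
    mask = np.ones(frame.n_atoms, dtype=bool)
    mask[own] = False
    pos = frame.coordinates[mask]
    q = frame.charges[mask]
    if pos.shape[0] == 0:
        return PerturbationField(0.0, np.zeros(3), com)
    # a.u. throughout: distances in bohr
    d = (com - pos) * BOHR_PER_ANGSTROM  # r0 - r_j
    r = np.linalg.norm(d, axis=1)
    r_min_bohr = min_distance * BOHR_PER_ANGSTROM
    if np.any(r < r_min_bohr):
        offender = int(np.flatnonzero(mask)[np.argmin(r)])
        raise NumericalSafetyError(
            f"frame {frame.frame_index}: environment atom {offender} is "
            f"{r.min() / BOHR_PER_ANGSTROM:.3f} A from the COM of QC {qc.id!r} "
            f"(minimum allowed {min_distance} A)"
        )
    potential = float(np.sum(q / r))
    field = (q[:, None] * d / r[:, None] ** 3).sum(axis=0)
    return PerturbationField(potential, field, com)


def build_perturbed_hamiltonian(
    electronic: UnperturbedElectronicData,
    q_T: int,
    pf: PerturbationField,
) -> np.ndarray:
    """Assemble ``H = diag(E^0) + q_T V I - E . mu`` in Hartree."""
    n = electronic.n_states
    h = np.diag(electronic.energies).astype(float)
    h += q_T * pf.potential * np.eye(n)
    h -= np.tensordot(electronic.dipole_matrix, pf.field, axes=([2], [0]))
    return h


def fix_phase(vectors: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude component positive (in place-safe copy).

    Ties resolve to the first such component, giving a deterministic sign.
    """
    v = vectors.copy()
    for a in range(v.shape[1]):
        i = int(np.argmax(np.abs(v[:, a])))
        if v[i, a] < 0:
            v[:, a] = -v[:, a]
    return v


def diagonalize_perturbed(hamiltonian: np.ndarray) -> PerturbedState:
    """Eigen-decompose a symmetric perturbed Hamiltonian.

    Eigenvalues ascending; the phase convention of :func:`fix_phase` is
    applied to the eigenvectors.
    """
    h = np.asarray(hamiltonian, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ContractViolation("Hamiltonian must be a square matrix")
    if np.max(np.abs(h - h.T)) > SYMMETRY_TOL:
        raise ContractViolation("Hamiltonian is not symmetric within 1e-10")
    energies, vectors = scipy.linalg.eigh(h)
    return PerturbedState(h, energies, fix_phase(vectors))


def site_energy(state: PerturbedState) -> float:
    """Gap between perturbed first-excited and ground states, in eV."""
    if len(state.energies) < 2:
        raise ContractViolation("site energy requires at least 2 states")
    gap = (state.energies[1] - state.energies[0]) * HARTREE_TO_EV
    if gap == 0.0:
        warnings.warn("degenerate perturbed ground/excited states: site energy 0",
                      stacklevel=2)
    return float(gap)


def perturbed_transition_dipole(
    electronic: UnperturbedElectronicData,
    state: PerturbedState,
) -> np.ndarray:
    """Ground -> first-excited transition dipole in the perturbed eigenbasis.

    ``mu'_01 = c_0^T M c_1`` applied to each Cartesian slice of the dipole
    matrix, with phase-fixed eigenvectors ``c_0`` and ``c_1``.
    """
    c0 = state.eigenvectors[:, 0]
    c1 = state.eigenvectors[:, 1]
    return np.einsum("i,ijk,j->k", c0, electronic.dipole_matrix, c1)


def oscillator_strength(gap_ev: float, mu_au: Sequence[float]) -> float:
    """Length-gauge oscillator strength ``f = (2/3) dE(Ha) |mu|^2``."""
    if gap_ev < 0:
        raise ContractViolation("oscillator strength requires a non-negative gap")
    mu = np.asarray(mu_au, dtype=float)
    return float(2.0 / 3.0 * (gap_ev / HARTREE_TO_EV) * np.dot(mu, mu))


def run_site_energy_stage(
    frames: Iterable[EnvironmentFrame],
    qcs: Sequence[QuantumCenter],
    *,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    skip_bad_frames: bool = False,
) -> Dict[str, SiteEnergyTrace]:
    """Field -> Hamiltonian -> diagonalization for every QC in every frame.

    The QC geometry enters only through its per-frame center of mass; the
    electronic data stay fixed at the reference-geometry values.

    Returns a mapping from QC id to its :class:`SiteEnergyTrace`.  With
    ``skip_bad_frames`` numerically unsafe frames are dropped (and logged)
    instead of aborting the run.
    """
    frames = list(frames)
    if not frames:
        raise PipelineError("site-energy stage requires at least one frame")
    records: Dict[str, List[tuple]] = {qc.id: [] for qc in qcs}
    skipped: List[int] = []
    for frame in frames:
        for qc in qcs:
            if qc.id not in frame.qc_atom_map:
                raise PipelineError(
                    f"frame {frame.frame_index}: QC {qc.id!r} not resolvable"
                )
        try:
            frame_rows = []
            for qc in qcs:
                pf = compute_potential_and_field(frame, qc, min_distance=min_distance)
                h = build_perturbed_hamiltonian(qc.electronic, qc.total_charge, pf)
                state = diagonalize_perturbed(h)
                e_site = site_energy(state)
                mu = perturbed_transition_dipole(qc.electronic, state)
                f = oscillator_strength(max(e_site, 0.0), mu)
                frame_rows.append(
                    (qc.id, frame.frame_index, e_site,
                     state.energies[0], state.energies[1], mu, f)
                )
        except NumericalSafetyError as err:
            if skip_bad_frames:
                logger.warning("skipping frame %d: %s", frame.frame_index, err)
                skipped.append(frame.frame_index)
                continue
            raise
        for qc_id, *row in frame_rows:
            records[qc_id].append(tuple(row))
    if skipped:
        logger.info("skipped %d of %d frames", len(skipped), len(frames))
    traces = {}
    for qc in qcs:
        rows = records[qc.id]
        if not rows:
            raise PipelineError(f"QC {qc.id!r}: no frames survived processing")
        idx, e_site, e0, e1, mus, fs = zip(*rows)
        traces[qc.id] = SiteEnergyTrace(
            qc_id=qc.id,
            frame_indices=np.array(idx),
            site_energies_ev=np.array(e_site),
            ground_energies_hartree=np.array(e0),
            excited_energies_hartree=np.array(e1),
            transition_dipoles=np.array(mus),
            oscillator_strengths=np.array(fs),
        )
    return traces
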