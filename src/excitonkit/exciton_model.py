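"""Point-dipole couplings and per-frame exciton diagonalization.

The excitation matrix carries the perturbed site energies on its diagonal and
point-dipole-approximation (PDA) couplings off-diagonal.  Couplings use the
perturbed transition dipoles of the frame and the per-frame centers of mass;
only the neutral dipolar term is implemented (monopole terms of the general
charged-QC expression are out of scope).
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    BOHR_PER_ANGSTROM,
    HARTREE_TO_CM,
    HARTREE_TO_EV,
    EnvironmentFrame,
    ExcitonSolution,
    QuantumCenter,
    SiteEnergyTrace,
)
from .errors import ContractViolation, DomainError, PipelineError
from .pmm_engine import fix_phase, frame_center_of_mass

import scipy.linalg


def pda_coupling(
    mu_k: Sequence[float],
    mu_kp: Sequence[float],
    r_k: Sequence[float],
    r_kp: Sequence[float],
    *,
    units: str = "angstrom",
    screening: float = 1.0,
) -> float:
    """Point-dipole coupling in Hartree.

    ``V = s * [mu_k . mu_k' - 3 (mu_k . n)(mu_k' . n)] / R^3`` with ``R`` the
    center-of-mass separation in bohr and ``n`` the unit separation vector.
    Dipoles are in a.u.; positions in Angstrom by default (``units='bohr'``
    to pass bohr directly).  ``screening`` is an optional scalar factor,
    1.0 (vacuum PDA) by default.
    """
    mu_k = np.asarray(mu_k, dtype=float)
    mu_kp = np.asarray(mu_kp, dtype=float)
    rvec = np.asarray(r_k, dtype=float) - np.asarray(r_kp, dtype=float)
    if units == "angstrom":
        rvec = rvec * BOHR_PER_ANGSTROM
    elif units != "bohr":
        raise DomainError(f"unknown length unit {units!r}")
    r = float(np.linalg.norm(rvec))
    if r == 0.0:
        raise DomainError("coincident chromophore centers in PDA coupling")
    n = rvec / r
    return float(
        screening * (mu_k @ mu_kp - 3.0 * (mu_k @ n) * (mu_kp @ n)) / r**3
    )


def build_excitation_matrix(
    site_energies: Sequence[float],
    couplings: np.ndarray,
    *,
    site_unit: str = "eV",
    coupling_unit: str = "hartree",
) -> np.ndarray:
    """Assemble the excitation matrix in Hartree.

    Diagonal: perturbed site energies; off-diagonal: excitonic couplings.
    The coupling input must be symmetric with zero diagonal.
    """
    from .datamodel import convert_energy

    e = np.asarray(
        [convert_energy(x, site_unit, "hartree") for x in np.asarray(site_energies, float)]
    )
    v = np.asarray(couplings, dtype=float)
    if v.shape != (len(e), len(e)):
        raise ContractViolation(
            f"couplings shape {v.shape} does not match {len(e)} site energies"
        )
    if np.max(np.abs(v - v.T)) > 1e-10 * max(1.0, np.max(np.abs(v))):
        raise ContractViolation("coupling matrix must be symmetric")
    if np.max(np.abs(np.diag(v))) > 0:
        raise ContractViolation("coupling matrix must have a zero diagonal")
    if coupling_unit != "hartree":
        v = np.asarray(convert_energy(v, coupling_unit, "hartree"))
    return np.diag(e) + v


def diagonalize_exciton(
    excitation_matrix: np.ndarray,
    basis_ids: Sequence[str],
    *,
    frame_index: int = -1,
    transition_dipoles: np.ndarray | None = None,
) -> ExcitonSolution:
    """Diagonalize an excitation matrix (Hartree) into an :class:`ExcitonSolution`."""
    h = np.asarray(excitation_matrix, dtype=float)
    if np.max(np.abs(h - h.T)) > 1e-10:
        raise ContractViolation("excitation matrix is not symmetric")
    energies, vectors = scipy.linalg.eigh(h)
    vectors = fix_phase(vectors)
    couplings_cm = (h - np.diag(np.diag(h))) * HARTREE_TO_CM
    return ExcitonSolution(
        frame_index=frame_index,
        basis_ids=list(basis_ids),
        site_energies_ev=np.diag(h) * HARTREE_TO_EV,
        coupling_matrix_cm=couplings_cm,
        exciton_energies_ev=energies * HARTREE_TO_EV,
        eigenvectors=vectors,
        contributions=vectors**2,
        transition_dipoles=transition_dipoles,
    )


def run_exciton_stage(
    traces: Dict[str, SiteEnergyTrace],
    frames: Iterable[EnvironmentFrame],
    basis: Sequence[QuantumCenter],
    *,
    screening: float = 1.0,
) -> List[ExcitonSolution]:
    """Per-frame excitation matrices from perturbed dipoles and per-frame COMs.

    Every basis QC must have a trace record for every frame.  Charged QCs are
    rejected: the monopole terms of the general coupling expression are not
    implemented.
    """
    for qc in basis:
        if qc.total_charge != 0:
            raise NotImplementedError(
                f"QC {qc.id!r} carries total charge {qc.total_charge}: monopole "
                "coupling terms for charged QCs are not implemented (neutral "
                "dipolar PDA only)"
            )
    frames = list(frames)
    if not frames:
        raise PipelineError("exciton stage requires at least one frame")
    lookup: Dict[str, Dict[int, int]] = {}
    for qc in basis:
        if qc.id not in traces:
            raise PipelineError(f"no site-energy trace for basis QC {qc.id!r}")
        tr = traces[qc.id]
        lookup[qc.id] = {int(f): i for i, f in enumerate(tr.frame_indices)}
    n = len(basis)
    solutions: List[ExcitonSolution] = []
    for frame in frames:
        mus = np.empty((n, 3))
        coms = np.empty((n, 3))
        e_site = np.empty(n)
        for i, qc in enumerate(basis):
            try:
                row = lookup[qc.id][frame.frame_index]
            except KeyError:
                raise PipelineError(
                    f"QC {qc.id!r} has no trace record for frame {frame.frame_index}"
                ) from None
            tr = traces[qc.id]
            mus[i] = tr.transition_dipoles[row]
            e_site[i] = tr.site_energies_ev[row]
            coms[i] = frame_center_of_mass(frame, qc)
        v = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                v[i, j] = v[j, i] = pda_coupling(
                    mus[i], mus[j], coms[i], coms[j], screening=screening
                )
        h = build_excitation_matrix(e_site, v)
        solutions.append(
            diagonalize_exciton(
                h, [qc.id for qc in basis],
                frame_index=frame.frame_index,
                transition_dipoles=mus,
            )
        )
    return solutions


def coupling_statistics(
    solutions: Sequence[ExcitonSolution],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Element-wise ensemble mean and sample std of the coupling matrices (cm^-1)."""
    if len(solutions) < 2:
        raise DomainError("coupling statistics require at least 2 frames")
    ids = solutions[0].basis_ids
    for s in solutions:
        if s.basis_ids != ids:
            raise PipelineError("inconsistent basis across exciton solutions")
    stack = np.stack([s.coupling_matrix_cm for s in solutions])
    mean = pd.DataFrame(stack.mean(axis=0), index=ids, columns=ids)
    std = pd.DataFrame(stack.std(axis=0, ddof=1), index=ids, columns=ids)
    return mean, std
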