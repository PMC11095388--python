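"""Core domain types, the unit system and geometric primitives.

Internal unit system is atomic units (Hartree, bohr, electron charge);
coordinates are carried in Angstrom and converted to bohr at the point of
use.  User-facing energies are reported in eV / meV / cm^-1 / nm.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import constants as _const

from .errors import ConfigurationError, ContractViolation, DomainError

# ---------------------------------------------------------------------------
# Physical constants (CODATA via scipy)
# ---------------------------------------------------------------------------

HARTREE_TO_EV: float = _const.value("Hartree energy in eV")
#: eV -> cm^-1
EV_TO_CM: float = _const.value("electron volt-inverse meter relationship") / 100.0
#: h*c in eV*nm, for the reciprocal wavelength/energy relation
HC_EV_NM: float = _const.value("Planck constant in eV/Hz") * _const.c * 1e9
#: 1 Angstrom expressed in bohr
BOHR_PER_ANGSTROM: float = 1e-10 / _const.value("Bohr radius")
HARTREE_TO_CM: float = HARTREE_TO_EV * EV_TO_CM

# Standard atomic weights (isotope-averaged), u.  Hydrogens count.
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Mn": 54.938, "Fe": 55.845, "Cu": 63.546, "Zn": 65.38,
}

Atom = Tuple[str, np.ndarray]  # (element symbol, xyz in Angstrom)


def center_of_mass(atoms: Sequence[Tuple[str, Sequence[float]]]) -> np.ndarray:
    """Mass-weighted mean position of ``atoms`` (Angstrom in, Angstrom out).

    Parameters
    ----------
    atoms
        Sequence of ``(element, (x, y, z))`` pairs.  Element symbols must be
        present in :data:`ATOMIC_MASSES`.

    Raises
    ------
    ConfigurationError
        If the list is empty or an element symbol is not recognized.
    """
    if len(atoms) == 0:
        raise ConfigurationError("center_of_mass requires a non-empty atom list")
    masses = []
    coords = []
    for element, xyz in atoms:
        try:
            masses.append(ATOMIC_MASSES[element])
        except KeyError:
            raise ConfigurationError(
                f"unknown element symbol {element!r}; known symbols: "
                f"{sorted(ATOMIC_MASSES)}"
            ) from None
        coords.append(np.asarray(xyz, dtype=float))
    m = np.asarray(masses)
    c = np.asarray(coords)
    return (m[:, None] * c).sum(axis=0) / m.sum()


# ---------------------------------------------------------------------------
# Energy-unit conversion
# ---------------------------------------------------------------------------

_UNIT_ALIASES = {
    "hartree": "hartree", "ha": "hartree", "au": "hartree",
    "ev": "eV", "mev": "meV",
    "cm-1": "cm-1", "cm^-1": "cm-1", "1/cm": "cm-1", "cm⁻¹": "cm-1",
    "cm−1": "cm-1",
    "nm": "nm",
}

# factors to eV for the linear units
_TO_EV = {
    "hartree": HARTREE_TO_EV,
    "eV": 1.0,
    "meV": 1e-3,
    "cm-1": 1.0 / EV_TO_CM,
}


def _canonical_unit(unit: str) -> str:
    key = unit.strip().lower().replace("−", "-")
    try:
        return _UNIT_ALIASES[key]
    except KeyError:
        raise DomainError(f"unknown energy unit {unit!r}") from None


def convert_energy(value, from_unit: str, to_unit: str):
    """Convert ``value`` between Hartree, eV, meV, cm^-1 and nm.

    nm conversions use the reciprocal relation ``lambda = hc / E`` and
    require strictly positive values.
    """
    src = _canonical_unit(from_unit)
    dst = _canonical_unit(to_unit)
    v = np.asarray(value, dtype=float)
    if src == dst:
        return value
    if src == "nm":
        if np.any(v <= 0):
            raise DomainError("wavelength must be positive for nm conversion")
        ev = HC_EV_NM / v
    else:
        ev = v * _TO_EV[src]
    if dst == "nm":
        if np.any(ev <= 0):
            raise DomainError("energy must be positive for nm conversion")
        out = HC_EV_NM / ev
    else:
        out = ev / _TO_EV[dst]
    return float(out) if np.isscalar(value) or np.ndim(value) == 0 else out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class UnperturbedElectronicData:
    """State energies and the full dipole matrix of an isolated quantum center.

    ``energies`` are eigenvalues of the unperturbed electronic Hamiltonian in
    Hartree, sorted ascending.  ``dipole_matrix`` has shape
    ``(n_states, n_states, 3)`` in atomic units; diagonal entries are the
    permanent dipoles, off-diagonal entries the transition dipoles, and the
    matrix is symmetric component-wise.
    """

    energies: np.ndarray
    dipole_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.dipole_matrix = np.asarray(self.dipole_matrix, dtype=float)
        n = self.energies.shape[0]
        if n < 2:
            raise ContractViolation("at least 2 electronic states are required")
        if self.dipole_matrix.shape != (n, n, 3):
            raise ContractViolation(
                f"dipole matrix shape {self.dipole_matrix.shape} does not match "
                f"{n} states"
            )
        if np.any(np.diff(self.energies) < 0):
            raise ContractViolation("state energies must be sorted ascending")
        if not np.allclose(
            self.dipole_matrix, np.swapaxes(self.dipole_matrix, 0, 1),
            atol=1e-12, rtol=0.0,
        ):
            raise ContractViolation("dipole matrix must be symmetric")

    @property
    def n_states(self) -> int:
        return int(self.energies.shape[0])


@dataclass
class QuantumCenter:
    """A pigment (monomer or dimer) treated quantum mechanically.

    ``atoms`` holds the reference geometry used to compute the unperturbed
    electronic data; the per-frame geometry lives in the environment frames.
    """

    id: str
    atoms: List[Atom]
    total_charge: int
    electronic: UnperturbedElectronicData
    kind: str = "monomer"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ConfigurationError(f"QC {self.id!r}: atom list must be non-empty")
        if self.kind not in ("monomer", "dimer"):
            raise ConfigurationError(
                f"QC {self.id!r}: kind must be 'monomer' or 'dimer', got {self.kind!r}"
            )
        self.total_charge = int(self.total_charge)
        self.atoms = [(el, np.asarray(xyz, dtype=float)) for el, xyz in self.atoms]
        # validates element symbols eagerly
        self._reference_com = center_of_mass(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def reference_center_of_mass(self) -> np.ndarray:
        return self._reference_com


@dataclass
class EnvironmentFrame:
    """One configuration: all atom coordinates (Angstrom) plus fixed charges (e).

    ``qc_atom_map`` maps each QC id to the indices of its own atoms within
    ``coordinates``; those atoms are excluded from that QC's perturbation and
    locate its instantaneous geometry.
    """

    frame_index: int
    coordinates: np.ndarray
    charges: np.ndarray
    qc_atom_map: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        if self.coordinates.shape[0] != self.charges.shape[0]:
            raise ContractViolation(
                f"frame {self.frame_index}: {self.coordinates.shape[0]} coordinates "
                f"vs {self.charges.shape[0]} charges"
            )
        seen: set[int] = set()
        clean = {}
        for qc_id, idx in self.qc_atom_map.items():
            idx = np.asarray(idx, dtype=int)
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ConfigurationError(
                    f"frame {self.frame_index}: QC atom sets overlap at indices "
                    f"{sorted(overlap)}"
                )
            seen.update(idx.tolist())
            clean[qc_id] = idx
        self.qc_atom_map = clean

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[0])

    def qc_coordinates(self, qc_id: str) -> np.ndarray:
        return self.coordinates[self.qc_atom_map[qc_id]]


@dataclass
class PerturbationField:
    """Electrostatic potential and field (a.u.) at a QC's center of mass."""

    potential: float
    field: np.ndarray
    evaluation_point: np.ndarray  # Angstrom

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float).reshape(3)
        self.evaluation_point = np.asarray(self.evaluation_point, dtype=float).reshape(3)
        if not (np.isfinite(self.potential) and np.all(np.isfinite(self.field))):
            raise ContractViolation("perturbation field contains non-finite values")


@dataclass
class SiteEnergyTrace:
    """Per-frame perturbed site energies and transition dipoles of one QC."""

    qc_id: str
    frame_indices: np.ndarray
    site_energies_ev: np.ndarray
    ground_energies_hartree: np.ndarray
    excited_energies_hartree: np.ndarray
    transition_dipoles: np.ndarray  # (n_frames, 3), a.u.
    oscillator_strengths: np.ndarray

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.site_energies_ev = np.asarray(self.site_energies_ev, dtype=float)
        self.ground_energies_hartree = np.asarray(self.ground_energies_hartree, dtype=float)
        self.excited_energies_hartree = np.asarray(self.excited_energies_hartree, dtype=float)
        self.transition_dipoles = np.asarray(self.transition_dipoles, dtype=float).reshape(-1, 3)
        self.oscillator_strengths = np.asarray(self.oscillator_strengths, dtype=float)
        n = len(self.frame_indices)
        for name in ("site_energies_ev", "ground_energies_hartree",
                     "excited_energies_hartree", "oscillator_strengths"):
            if len(getattr(self, name)) != n:
                raise ContractViolation(f"trace {self.qc_id!r}: {name} length mismatch")
        if self.transition_dipoles.shape[0] != n:
            raise ContractViolation(f"trace {self.qc_id!r}: transition_dipoles length mismatch")
        gaps = (self.excited_energies_hartree - self.ground_energies_hartree) * HARTREE_TO_EV
        if not np.allclose(gaps, self.site_energies_ev, atol=1e-9, rtol=0.0):
            raise ContractViolation(
                f"trace {self.qc_id!r}: site energies inconsistent with perturbed levels"
            )
        if np.any(self.site_energies_ev <= 0):
            warnings.warn(
                f"trace {self.qc_id!r} contains non-positive site energies",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.frame_indices)


@dataclass
class ExcitonSolution:
    """Exciton energies, eigenvectors and contribution weights for one frame.

    ``contributions[i, a]`` is the squared coefficient of basis QC ``i`` in
    exciton ``a``; each column sums to one.  The coupling matrix is stored in
    cm^-1 for display; internal assembly happens in Hartree.
    """

    frame_index: int
    basis_ids: List[str]
    site_energies_ev: np.ndarray
    coupling_matrix_cm: np.ndarray
    exciton_energies_ev: np.ndarray
    eigenvectors: np.ndarray
    contributions: np.ndarray
    transition_dipoles: np.ndarray | None = None  # per-basis perturbed dipoles, a.u.

    def __post_init__(self) -> None:
        self.site_energies_ev = np.asarray(self.site_energies_ev, dtype=float)
        self.coupling_matrix_cm = np.asarray(self.coupling_matrix_cm, dtype=float)
        self.exciton_energies_ev = np.asarray(self.exciton_energies_ev, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.contributions = np.asarray(self.contributions, dtype=float)
        n = len(self.basis_ids)
        if not np.allclose(self.coupling_matrix_cm, self.coupling_matrix_cm.T,
                           atol=1e-9, rtol=0.0):
            raise ContractViolation("coupling matrix must be symmetric")
        col_sums = self.contributions.sum(axis=0)
        if not np.allclose(col_sums, np.ones(n), atol=1e-10, rtol=0.0):
            raise ContractViolation("contribution columns must sum to 1 (1e-10)")
        if abs(self.exciton_energies_ev.sum() - self.site_energies_ev.sum()) > 1e-9:
            raise ContractViolation(
                "sum of exciton energies must equal sum of site energies (1e-9 eV)"
            )
        if np.any(np.diff(self.exciton_energies_ev) < -1e-12):
            raise ContractViolation("exciton energies must be ascending")

    @property
    def n_basis(self) -> int:
        return len(self.basis_ids)
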