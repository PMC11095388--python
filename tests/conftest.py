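import numpy as np
import pytest

from excitonkit.datamodel import (
    EnvironmentFrame,
    QuantumCenter,
    UnperturbedElectronicData,
)


def make_two_state_qc(qc_id="Q1", gap_hartree=0.07, mu01=(1.0, 0.0, 0.0),
                      permanent=None, total_charge=0, atom_xyz=(0.0, 0.0, 0.0)):
    """Two-state QC with configurable gap and transition dipole."""
    dip = np.zeros((2, 2, 3))
    dip[0, 1] = dip[1, 0] = np.asarray(mu01, dtype=float)
    if permanent is not None:
        dip[0, 0] = np.asarray(permanent[0], dtype=float)
        dip[1, 1] = np.asarray(permanent[1], dtype=float)
    return QuantumCenter(
        id=qc_id,
        atoms=[("C", np.asarray(atom_xyz, dtype=float))],
        total_charge=total_charge,
        electronic=UnperturbedElectronicData(
            energies=np.array([0.0, gap_hartree]), dipole_matrix=dip
        ),
    )


def make_frame(qc_positions, env_positions, env_charges, qc_ids=None,
               frame_index=0, qc_charges=None):
    """Frame with one atom per QC (listed first) followed by environment atoms."""
    qc_positions = np.asarray(qc_positions, dtype=float).reshape(-1, 3)
    env_positions = (np.asarray(env_positions, dtype=float).reshape(-1, 3)
                     if len(env_positions) else np.empty((0, 3)))
    n_qc = qc_positions.shape[0]
    if qc_ids is None:
        qc_ids = [f"Q{i + 1}" for i in range(n_qc)]
    if qc_charges is None:
        qc_charges = np.zeros(n_qc)
    coords = np.vstack([qc_positions, env_positions])
    charges = np.concatenate([np.asarray(qc_charges, float),
                              np.asarray(env_charges, float)])
    qc_map = {qc_id: np.array([i]) for i, qc_id in enumerate(qc_ids)}
    return EnvironmentFrame(frame_index=frame_index, coordinates=coords,
                            charges=charges, qc_atom_map=qc_map)


@pytest.fixture
def two_state_qc():
    return make_two_state_qc()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
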