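"""Independent brute-force reference implementations.

These routines re-derive every per-frame quantity of the pipeline with plain
loops, an eigenvalue solver based on characteristic-polynomial roots
(Faddeev-LeVerrier coefficients + companion-matrix roots) and SVD null-space
eigenvectors.  They deliberately share no code path with ``pmm_engine`` /
``exciton_model`` and exist only as oracles for tests and ground-truth checks.
"""
from __future__ import annotations

import math
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .datamodel import ATOMIC_MASSES, BOHR_PER_ANGSTROM


def charpoly_coefficients(a: np.ndarray) -> np.ndarray:
    """Characteristic-polynomial coefficients by the Faddeev-LeVerrier recursion."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    m = np.eye(n)
    coeffs = [1.0]
    for k in range(1, n + 1):
        m = a @ m
        c = -np.trace(m) / k
        coeffs.append(c)
        m = m + c * np.eye(n)
    return np.array(coeffs)


def eig_sym_brute(a: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of a symmetric matrix from charpoly roots."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    shift = np.trace(a) / n
    b = a - shift * np.eye(n)
    scale = max(float(np.abs(b).max()), 1e-300)
    roots = np.roots(charpoly_coefficients(b / scale))
    return np.sort(roots.real) * scale + shift


def eigvec_brute(a: np.ndarray, eigenvalue: float) -> np.ndarray:
    """Unit null vector of ``a - lambda I`` via SVD, phase-fixed like the pipeline
    convention (largest-magnitude component positive)."""
    a = np.asarray(a, dtype=float)
    _, _, vt = np.linalg.svd(a - eigenvalue * np.eye(a.shape[0]))
    v = vt[-1]
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return v


def _com(elements: Sequence[str], coords: np.ndarray) -> np.ndarray:
    total = 0.0
    acc = np.zeros(3)
    for el, xyz in zip(elements, coords):
        m = ATOMIC_MASSES[el]
        total += m
        acc = acc + m * np.asarray(xyz, dtype=float)
    return acc / total


def _potential_field(coords, charges, own_idx, com):
    """Loop evaluation of V and E (a.u.) at ``com`` (Angstrom in)."""
    own = set(int(i) for i in own_idx)
    com_b = np.asarray(com, dtype=float) * BOHR_PER_ANGSTROM
    v = 0.0
    ex = ey = ez = 0.0
    for j in range(len(charges)):
        if j in own:
            continue
        pj = coords[j] * BOHR_PER_ANGSTROM
        dx = com_b[0] - pj[0]
        dy = com_b[1] - pj[1]
        dz = com_b[2] - pj[2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        q = charges[j]
        v += q / r
        r3 = r * r * r
        ex += q * dx / r3
        ey += q * dy / r3
        ez += q * dz / r3
    return v, np.array([ex, ey, ez])


def reference_site_records(frames, qcs) -> Dict[str, List[dict]]:
    """Per-frame perturbed levels, gaps and transition dipoles for every QC."""
    out: Dict[str, List[dict]] = {qc.id: [] for qc in qcs}
    for frame in frames:
        for qc in qcs:
            idx = frame.qc_atom_map[qc.id]
            elements = [el for el, _ in qc.atoms]
            com = _com(elements, frame.coordinates[idx])
            v, e_field = _potential_field(frame.coordinates, frame.charges, idx, com)
            n = qc.electronic.n_states
            h = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    mu = qc.electronic.dipole_matrix[i, j]
                    h[i, j] = -(e_field[0] * mu[0] + e_field[1] * mu[1]
                                + e_field[2] * mu[2])
                    if i == j:
                        h[i, j] += qc.electronic.energies[i] + qc.total_charge * v
            levels = eig_sym_brute(h)
            c0 = eigvec_brute(h, levels[0])
            c1 = eigvec_brute(h, levels[1])
            mu01 = np.zeros(3)
            for i in range(n):
                for j in range(n):
                    mu01 += c0[i] * c1[j] * qc.electronic.dipole_matrix[i, j]
            out[qc.id].append({
                "frame": frame.frame_index,
                "com": com,
                "e0_hartree": float(levels[0]),
                "e1_hartree": float(levels[1]),
                "gap_hartree": float(levels[1] - levels[0]),
                "mu01": mu01,
            })
    return out


def reference_exciton(
    frames,
    qcs,
    site_records: Mapping[str, List[dict]],
) -> List[dict]:
    """Per-frame coupling matrices and exciton energies (Hartree), brute force."""
    order = [qc.id for qc in qcs]
    by_frame: Dict[int, Dict[str, dict]] = {}
    for qc_id, recs in site_records.items():
        for rec in recs:
            by_frame.setdefault(rec["frame"], {})[qc_id] = rec
    results = []
    for frame in frames:
        recs = by_frame[frame.frame_index]
        n = len(order)
        h = np.zeros((n, n))
        for i in range(n):
            h[i, i] = recs[order[i]]["gap_hartree"]
        for i in range(n):
            for j in range(i + 1, n):
                ri = recs[order[i]]["com"] * BOHR_PER_ANGSTROM
                rj = recs[order[j]]["com"] * BOHR_PER_ANGSTROM
                dvec = ri - rj
                r = math.sqrt(dvec @ dvec)
                nhat = dvec / r
                mi = recs[order[i]]["mu01"]
                mj = recs[order[j]]["mu01"]
                v = (mi @ mj - 3.0 * (mi @ nhat) * (mj @ nhat)) / r**3
                h[i, j] = h[j, i] = v
        results.append({
            "frame": frame.frame_index,
            "matrix_hartree": h,
            "exciton_energies_hartree": eig_sym_brute(h),
        })
    return results
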