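"""Readers and writers: environment ensembles, QC property files, tables, results.

Coordinate ensembles are multi-frame XYZ or multi-MODEL PDB (read through
MDAnalysis), charges come from a separate plain-text table, QC properties are
JSON documents, and the tabulated site-energy/coupling tables are plain CSV.
"""
from __future__ import annotations

import json
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    EnvironmentFrame,
    ExcitonSolution,
    QuantumCenter,
    SiteEnergyTrace,
    UnperturbedElectronicData,
)
from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

SITE_TABLE_COLUMNS = [
    "gas_energy_ev", "gas_fosc",
    "isolated_energy_ev", "isolated_fosc", "isolated_shift_mev",
    "full_energy_ev", "full_fosc", "full_shift_mev",
    "pmm_mean_ev", "pmm_std_ev",
]


# ---------------------------------------------------------------------------
# Environment ensembles
# ---------------------------------------------------------------------------


def _read_charge_table(path) -> np.ndarray:
    try:
        raw = np.loadtxt(path, dtype=float, ndmin=2, comments="#")
    except ValueError as err:
        raise FormatError(f"charge table {path}: {err}") from None
    if raw.shape[1] == 1:
        return raw[:, 0]
    if raw.shape[1] == 2:
        order = np.argsort(raw[:, 0].astype(int))
        return raw[order, 1]
    raise FormatError(
        f"charge table {path}: expected 1 (charge) or 2 (index, charge) columns, "
        f"got {raw.shape[1]}"
    )


def read_environment_ensemble(
    coordinates_path,
    charge_table_path,
    qc_definitions: Mapping[str, Sequence[int]],
) -> List[EnvironmentFrame]:
    """Load a coordinate ensemble plus its fixed per-atom charge table.

    ``qc_definitions`` maps each QC id to the 0-based indices of its atoms in
    the coordinate files; the index sets must be disjoint.
    """
    import MDAnalysis as mda

    charges = _read_charge_table(charge_table_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses masses/elements noisily
        universe = mda.Universe(str(coordinates_path))
        if universe.atoms.n_atoms != len(charges):
            raise FormatError(
                f"{coordinates_path}: frames have {universe.atoms.n_atoms} atoms but "
                f"the charge table lists {len(charges)} entries"
            )
        qc_map = {qc_id: np.asarray(idx, dtype=int) for qc_id, idx in qc_definitions.items()}
        frames = []
        for i, _ts in enumerate(universe.trajectory):
            frames.append(
                EnvironmentFrame(
                    frame_index=i,
                    coordinates=universe.atoms.positions.astype(float).copy(),
                    charges=charges.copy(),
                    qc_atom_map=qc_map,
                )
            )
    return frames


def write_xyz_ensemble(frames: Sequence[EnvironmentFrame], elements: Sequence[str], path) -> None:
    """Write frames as a plain multi-frame XYZ file (Angstrom, %.8f)."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_atoms}\n")
            fh.write(f"frame {frame.frame_index}\n")
            for el, (x, y, z) in zip(elements, frame.coordinates):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


def write_charge_table(charges: Sequence[float], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# atom_index charge_e\n")
        for i, q in enumerate(charges):
            fh.write(f"{i} {q:.17g}\n")  # full precision: charges round-trip exactly


def subsample_frames(
    frames: Sequence[EnvironmentFrame],
    start_time: float,
    end_time: float,
    stride: float,
    *,
    frame_spacing: float,
) -> List[EnvironmentFrame]:
    """Pick frames at times ``start + k*stride`` within ``(start, end]`` (ps).

    The window is half-open at the start, so a 30 ns span sampled at a 10 ps
    stride yields exactly 3000 frames.  ``frame_spacing`` declares the time
    between consecutive stored frames (the files themselves carry no time).
    """
    if stride <= 0:
        raise DomainError(f"stride must be positive, got {stride}")
    if frame_spacing <= 0:
        raise DomainError(f"frame spacing must be positive, got {frame_spacing}")
    by_index = {frame.frame_index: frame for frame in frames}
    picked: List[EnvironmentFrame] = []
    k = 1
    tol = 1e-9 * max(1.0, abs(end_time))
    while True:
        t = start_time + k * stride
        if t > end_time + tol:
            break
        idx = t / frame_spacing
        idx_int = int(round(idx))
        if abs(idx - idx_int) < 1e-9 and idx_int in by_index:
            picked.append(by_index[idx_int])
        k += 1
    if not picked:
        warnings.warn(
            f"frame selection ({start_time}, {end_time}] ps at stride {stride} ps "
            "is empty", stacklevel=2,
        )
    return picked


# ---------------------------------------------------------------------------
# QC property files
# ---------------------------------------------------------------------------


def read_qc_properties(path) -> QuantumCenter:
    """Read one QC property document (JSON) into a :class:`QuantumCenter`.

    The dipole list must contain every pair ``(i, j)`` with ``i <= j`` exactly
    once (upper triangle); the full symmetric matrix is completed on load.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise FormatError(f"{path}: not valid JSON ({err})") from None
    for key in ("id", "total_charge", "atoms", "n_states", "energies", "dipoles"):
        if key not in doc:
            raise FormatError(f"{path}: missing required key {key!r}")
    n = int(doc["n_states"])
    energies = np.asarray(doc["energies"], dtype=float)
    if energies.shape != (n,):
        raise FormatError(
            f"{path}: {len(energies)} energies for n_states={n}"
        )
    if np.any(np.diff(energies) < 0):
        raise FormatError(f"{path}: state energies are not ascending")
    dip = np.zeros((n, n, 3))
    seen = set()
    for entry in doc["dipoles"]:
        i, j = int(entry[0]), int(entry[1])
        if not (0 <= i < n and 0 <= j < n):
            raise FormatError(f"{path}: dipole index ({i},{j}) out of range")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise FormatError(f"{path}: duplicate dipole entry for pair {key}")
        seen.add(key)
        vec = np.asarray(entry[2:5], dtype=float)
        dip[key[0], key[1]] = vec
        dip[key[1], key[0]] = vec
    missing = [
        (i, j) for i in range(n) for j in range(i, n) if (i, j) not in seen
    ]
    if missing:
        raise FormatError(f"{path}: missing dipole entries for pairs {missing}")
    atoms = [(str(a[0]), np.asarray(a[1:4], dtype=float)) for a in doc["atoms"]]
    return QuantumCenter(
        id=str(doc["id"]),
        atoms=atoms,
        total_charge=int(doc["total_charge"]),
        electronic=UnperturbedElectronicData(energies=energies, dipole_matrix=dip),
        kind=str(doc.get("kind", "monomer")),
    )


def write_qc_properties(qc: QuantumCenter, path) -> None:
    """Write a QC back to the JSON property-file schema (upper-triangle dipoles)."""
    n = qc.electronic.n_states
    dipoles = [
        [i, j, *np.asarray(qc.electronic.dipole_matrix[i, j], dtype=float).tolist()]
        for i in range(n) for j in range(i, n)
    ]
    doc = {
        "id": qc.id,
        "kind": qc.kind,
        "total_charge": qc.total_charge,
        "atoms": [[el, *xyz.tolist()] for el, xyz in qc.atoms],
        "n_states": n,
        "energies": qc.electronic.energies.tolist(),
        "dipoles": dipoles,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# Tabulated site-energy / coupling tables
# ---------------------------------------------------------------------------


def _normalize_minus(text: str) -> str:
    return text.replace("−", "-").replace("–", "-")


def read_site_table(csv_path) -> pd.DataFrame:
    """Read a per-pigment site-energy table into a DataFrame indexed by label.

    Expected columns (after the ``site`` label column): gas-phase energy and
    oscillator strength, isolated-complex energy/f_osc/shift, full-complex
    energy/f_osc/shift, ensemble mean and std.  Unicode minus signs are
    normalized on ingest.
    """
    raw = _normalize_minus(Path(csv_path).read_text())
    from io import StringIO

    df = pd.read_csv(StringIO(raw))
    if "site" not in df.columns:
        raise FormatError(f"{csv_path}: missing 'site' column")
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing columns {missing}")
    df = df.set_index("site")
    for col in SITE_TABLE_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad) or converted.isna().any():
            row = bad[0] if len(bad) else df.index[converted.isna()][0]
            raise FormatError(
                f"{csv_path}: non-numeric value in column {col!r}, row {row!r}"
            )
        df[col] = converted
    return df


def read_coupling_table(csv_path) -> pd.DataFrame:
    """Read a labeled coupling matrix (cm^-1), symmetrize, zero the diagonal.

    The CSV may be upper-triangular (blank cells below the diagonal) or full;
    a full matrix must be consistent with its transpose.
    """
    raw = _normalize_minus(Path(csv_path).read_text())
    from io import StringIO

    df = pd.read_csv(StringIO(raw), index_col=0)
    labels = [str(c).strip() for c in df.columns]
    df.columns = labels
    df.index = [str(i).strip() for i in df.index]
    for col in labels:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"{csv_path}: non-numeric value at row {df.index[bad.argmax()]!r}, "
                f"column {col!r}"
            )
        df[col] = converted
    all_labels = list(dict.fromkeys(list(df.index) + labels))
    m = pd.DataFrame(np.nan, index=all_labels, columns=all_labels, dtype=float)
    for i in df.index:
        for j in labels:
            m.loc[i, j] = df.loc[i, j]
    a = m.to_numpy()
    n = len(all_labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            up, lo = a[i, j], a[j, i]
            if np.isnan(up) and np.isnan(lo):
                val = 0.0
            elif np.isnan(lo):
                val = up
            elif np.isnan(up):
                val = lo
            else:
                if abs(up - lo) > 1e-9 * max(1.0, abs(up)):
                    raise FormatError(
                        f"{csv_path}: asymmetric entries for ({all_labels[i]}, "
                        f"{all_labels[j]}): {up} vs {lo}"
                    )
                val = up
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=all_labels, columns=all_labels)


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("excitonkit.data").joinpath(name)


def load_reference_site_table() -> pd.DataFrame:
    """Published per-chlorophyll site-energy table for the CP43 antenna."""
    with resources.as_file(_data_path("cp43_site_energies.csv")) as p:
        return read_site_table(p)


def load_reference_coupling_table() -> pd.DataFrame:
    """Published CP43 excitonic coupling matrix (cm^-1)."""
    with resources.as_file(_data_path("cp43_couplings.csv")) as p:
        return read_coupling_table(p)


def load_reference_dimer_states() -> pd.DataFrame:
    """Published low-lying excited-state energies (eV) of CP43 chlorophyll dimers."""
    with resources.as_file(_data_path("cp43_dimer_states.csv")) as p:
        df = pd.read_csv(p)
    return df


# ---------------------------------------------------------------------------
# Result export
# ---------------------------------------------------------------------------


def write_results(
    traces: Mapping[str, SiteEnergyTrace],
    solutions: Sequence[ExcitonSolution],
    out_dir,
    *,
    eigenvector_dump: bool = False,
) -> Dict[str, Path]:
    """Write per-frame CSVs, summary CSVs and a JSON exciton summary.

    With ``eigenvector_dump`` the full per-frame eigenvector stack is written
    to an HDF5 container as well (binary; meant for scratch use).
    """
    if not traces:
        raise DomainError("write_results: no site-energy traces given")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    rows = []
    for qc_id, tr in traces.items():
        for i in range(len(tr)):
            rows.append({
                "frame": int(tr.frame_indices[i]),
                "qc": qc_id,
                "E_site_eV": tr.site_energies_ev[i],
                "mu_x": tr.transition_dipoles[i, 0],
                "mu_y": tr.transition_dipoles[i, 1],
                "mu_z": tr.transition_dipoles[i, 2],
                "f_osc": tr.oscillator_strengths[i],
            })
    site_df = pd.DataFrame(rows)
    paths["site_energies"] = out_dir / "site_energies.csv"
    site_df.to_csv(paths["site_energies"], index=False, float_format="%.12g")

    summary = pd.DataFrame({
        "qc": list(traces),
        "mean_eV": [t.site_energies_ev.mean() for t in traces.values()],
        "std_eV": [
            t.site_energies_ev.std(ddof=1) if len(t) > 1 else 0.0
            for t in traces.values()
        ],
        "n_frames": [len(t) for t in traces.values()],
    })
    paths["site_summary"] = out_dir / "site_summary.csv"
    summary.to_csv(paths["site_summary"], index=False, float_format="%.12g")

    if solutions:
        from .exciton_model import coupling_statistics

        if len(solutions) >= 2:
            mean, std = coupling_statistics(solutions)
            paths["coupling_mean"] = out_dir / "coupling_mean.csv"
            paths["coupling_std"] = out_dir / "coupling_std.csv"
            mean.to_csv(paths["coupling_mean"], float_format="%.12g")
            std.to_csv(paths["coupling_std"], float_format="%.12g")
        summary_doc = {
            "basis_ids": solutions[0].basis_ids,
            "n_frames": len(solutions),
            "frames": [
                {
                    "frame": int(s.frame_index),
                    "exciton_energies_ev": s.exciton_energies_ev.tolist(),
                    "first_exciton_contributions": dict(
                        zip(s.basis_ids, s.contributions[:, 0].tolist())
                    ),
                }
                for s in solutions
            ],
        }
        paths["excitons"] = out_dir / "excitons.json"
        paths["excitons"].write_text(json.dumps(summary_doc, indent=1))
        if eigenvector_dump:
            import h5py

            paths["eigenvectors"] = out_dir / "eigenvectors.h5"
            with h5py.File(paths["eigenvectors"], "w") as h5:
                h5.create_dataset(
                    "eigenvectors", data=np.stack([s.eigenvectors for s in solutions])
                )
                h5.create_dataset(
                    "frame_indices", data=np.array([s.frame_index for s in solutions])
                )
    return paths
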