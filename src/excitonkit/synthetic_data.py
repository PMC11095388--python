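"""Synthetic QC property files and environment ensembles with known ground truth.

Two generation modes share one spec:

* the default mode scatters Gaussian-charged environment atoms around the QCs
  and jitters all positions per frame, giving roughly Gaussian site-energy
  distributions of meV-scale width;
* the calibrated mode places, for each QC, a symmetric pair of equal point
  charges on the QC's local x axis and jitters only their axial distances.
  With transition dipoles along z and permanent-dipole differences along x the
  perturbed Hamiltonian stays exactly diagonal, so the site energy is exactly
  ``gap + q*dp*(1/x_right^2 - 1/x_left^2)``: Gaussian to first order with an
  expectation value of exactly the unperturbed gap.  This mode provides
  analytic ground truth for parameter-recovery tests.

The optional two-basin switch alternates, in blocks of frames, the resting
geometry of one charge (calibrated: the right axial charge's base distance;
default mode: a displaced charge group), producing bimodal first-exciton
energies with known basin means.

Randomness comes exclusively from ``numpy.random.default_rng(seed)`` (PCG64),
so a fixed seed reproduces every file byte for byte.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .datamodel import (
    BOHR_PER_ANGSTROM,
    HARTREE_TO_EV,
    EnvironmentFrame,
    QuantumCenter,
    UnperturbedElectronicData,
)
from .errors import ConfigurationError, GenerationError
from . import _reference
from .trajectory_io import write_charge_table, write_qc_properties, write_xyz_ensemble

_PERMANENT_DIPOLE_DELTA = 1.0  # a.u., excited-minus-ground dipole along x (calibrated)


@dataclass
class TwoBasinSpec:
    """Conformational two-basin switch, alternating in blocks of frames."""

    block_length: int = 100
    qc_index: int = 0
    #: calibrated mode: base-distance offsets (bohr) of the right axial charge
    distance_offsets_bohr: Tuple[float, float] = (-1.0, 1.0)
    #: default mode: size and rigid displacement (Angstrom) of the moved group
    group_size: int = 5
    displacement: Tuple[float, float, float] = (4.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.block_length <= 0:
            raise ConfigurationError("two-basin block_length must be positive")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset.  ``seed`` is mandatory."""

    seed: int
    n_qcs: int = 3
    gaps_ev: Optional[Sequence[float]] = None  # default: spread over 1.87-1.97
    second_gap_offset_ev: float = 0.4
    dipole_magnitude: float = 2.0
    n_env_atoms: int = 60
    charge_std: float = 0.5
    jitter_sigma: float = 0.3  # Angstrom, per-frame positional jitter
    qc_jitter_sigma: float = 0.05  # Angstrom, rigid per-frame QC translation
    n_frames: int = 100
    frame_spacing_ps: float = 10.0
    qc_spacing: Optional[float] = None  # Angstrom between QC centers
    min_env_distance: float = 8.0
    env_padding: float = 8.0
    calibrated: bool = False
    target_site_std_ev: float = 0.010  # calibrated mode
    axial_distance_bohr: float = 20.0  # calibrated mode
    two_basin: Optional[TwoBasinSpec] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory for reproducibility")
        for name in ("n_qcs", "n_env_atoms", "n_frames"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.frame_spacing_ps <= 0:
            raise ConfigurationError("frame_spacing_ps must be positive")
        if self.gaps_ev is not None and len(self.gaps_ev) != self.n_qcs:
            raise ConfigurationError("gaps_ev length must equal n_qcs")

    @property
    def spacing(self) -> float:
        if self.qc_spacing is not None:
            return self.qc_spacing
        return 500.0 if self.calibrated else 25.0

    def resolved_gaps_ev(self) -> np.ndarray:
        if self.gaps_ev is not None:
            return np.asarray(self.gaps_ev, dtype=float)
        if self.n_qcs == 1:
            return np.array([1.90])
        return np.linspace(1.87, 1.97, self.n_qcs)


def _qc_center(spec: SyntheticSpec, i: int) -> np.ndarray:
    return np.array([0.0, i * spec.spacing, 0.0])


def _axial_charge_magnitude(spec: SyntheticSpec) -> float:
    """Charge magnitude giving the requested calibrated site-energy std."""
    sigma_ha = spec.target_site_std_ev / HARTREE_TO_EV
    sigma_delta = spec.jitter_sigma * BOHR_PER_ANGSTROM
    d = spec.axial_distance_bohr
    return sigma_ha * d**3 / (2.0 * np.sqrt(2.0) * sigma_delta * _PERMANENT_DIPOLE_DELTA)


def generate_qc_set(spec: SyntheticSpec) -> Tuple[List[QuantumCenter], dict]:
    """Three-state QCs with prescribed gaps; returns (QCs, ground-truth manifest)."""
    rng = np.random.default_rng(spec.seed)
    gaps = spec.resolved_gaps_ev()
    qcs: List[QuantumCenter] = []
    manifest: dict = {"seed": spec.seed, "mode": "calibrated" if spec.calibrated else "default",
                      "qcs": []}
    for i in range(spec.n_qcs):
        center = _qc_center(spec, i)
        gap1_ha = gaps[i] / HARTREE_TO_EV
        gap2_ha = (gaps[i] + spec.second_gap_offset_ev) / HARTREE_TO_EV
        energies = np.array([0.0, gap1_ha, gap2_ha])
        dip = np.zeros((3, 3, 3))
        if spec.calibrated:
            # geometry chosen so the perturbed Hamiltonian stays diagonal:
            # transition dipoles along z, permanent-dipole differences along x,
            # all charges in the z = 0 plane
            dip[0, 1] = dip[1, 0] = np.array([0.0, 0.0, spec.dipole_magnitude])
            dip[0, 2] = dip[2, 0] = np.array([0.0, 0.0, 0.3 * spec.dipole_magnitude])
            dip[1, 2] = dip[2, 1] = np.array([0.0, 0.0, 0.2 * spec.dipole_magnitude])
            dip[0, 0] = np.zeros(3)
            dip[1, 1] = np.array([_PERMANENT_DIPOLE_DELTA, 0.0, 0.0])
            dip[2, 2] = np.array([0.5 * _PERMANENT_DIPOLE_DELTA, 0.0, 0.0])
            offsets = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
            atoms = [("C", center + off) for off in offsets]
        else:
            def _unit(v):
                return v / np.linalg.norm(v)

            u01 = _unit(rng.normal(size=3))
            dip[0, 1] = dip[1, 0] = spec.dipole_magnitude * u01
            dip[0, 2] = dip[2, 0] = 0.3 * spec.dipole_magnitude * _unit(rng.normal(size=3))
            dip[1, 2] = dip[2, 1] = 0.2 * spec.dipole_magnitude * _unit(rng.normal(size=3))
            # fixed-magnitude permanent-dipole differences keep the linear
            # (electrochromic) response dominant over second-order mixing, so
            # site-energy distributions stay close to Gaussian
            base = rng.normal(scale=0.5, size=3)
            dip[0, 0] = base
            dip[1, 1] = base + 1.2 * _unit(rng.normal(size=3))
            dip[2, 2] = base + 0.6 * _unit(rng.normal(size=3))
            offsets = rng.uniform(-1.5, 1.5, size=(5, 3))
            atoms = [("C", center + off) for off in offsets]
        electronic = UnperturbedElectronicData(energies=energies, dipole_matrix=dip)
        qc = QuantumCenter(
            id=f"Q{i + 1}", atoms=atoms, total_charge=0,
            electronic=electronic, kind="monomer",
        )
        qcs.append(qc)
        manifest["qcs"].append({
            "id": qc.id,
            "center": center.tolist(),
            "gap1_ev": float(gaps[i]),
            "gap2_ev": float(gaps[i] + spec.second_gap_offset_ev),
            "mu01": dip[0, 1].tolist(),
        })
    return qcs, manifest


def _place_env_atoms(spec: SyntheticSpec, rng, qc_coms: np.ndarray) -> np.ndarray:
    lo = qc_coms.min(axis=0) - spec.env_padding
    hi = qc_coms.max(axis=0) + spec.env_padding
    placed = []
    for k in range(spec.n_env_atoms):
        for _ in range(200):
            p = rng.uniform(lo, hi)
            if np.all(np.linalg.norm(qc_coms - p, axis=1) >= spec.min_env_distance):
                placed.append(p)
                break
        else:
            raise GenerationError(
                f"could not place environment atom {k} at distance "
                f">= {spec.min_env_distance} A from every QC after 200 attempts"
            )
    return np.asarray(placed)


def generate_environment_ensemble(
    spec: SyntheticSpec,
    qcs: Sequence[QuantumCenter],
) -> Tuple[List[EnvironmentFrame], List[str], dict]:
    """Generate frames (QC atoms first, then environment atoms).

    Returns ``(frames, element_list, manifest)``; the manifest records every
    sampled base value plus, in calibrated mode, the analytic per-QC nominal
    site-energy mean/std (and per-basin means under the two-basin switch).
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_qc_atoms = sum(qc.n_atoms for qc in qcs)
    qc_atom_map: Dict[str, np.ndarray] = {}
    base_coords = []
    elements: List[str] = []
    charges = []
    pos = 0
    for qc in qcs:
        qc_atom_map[qc.id] = np.arange(pos, pos + qc.n_atoms)
        pos += qc.n_atoms
        for el, xyz in qc.atoms:
            base_coords.append(np.asarray(xyz, dtype=float))
            elements.append(el)
        if spec.calibrated:
            charges.extend([0.0] * qc.n_atoms)
        else:
            qq = rng.normal(scale=0.02, size=qc.n_atoms)
            charges.extend((qq - qq.mean()).tolist())  # keep the QC neutral

    qc_coms = np.array([qc.reference_center_of_mass for qc in qcs])
    manifest: dict = {
        "n_frames": spec.n_frames,
        "frame_spacing_ps": spec.frame_spacing_ps,
        "span_ps": spec.n_frames * spec.frame_spacing_ps,
        "span_ns": spec.n_frames * spec.frame_spacing_ps / 1000.0,
        "two_basin": None,
    }

    if spec.calibrated:
        d_ang = spec.axial_distance_bohr / BOHR_PER_ANGSTROM
        q = _axial_charge_magnitude(spec)
        env_base = []
        for com in qc_coms:
            env_base.append(com + np.array([d_ang, 0.0, 0.0]))
            env_base.append(com - np.array([d_ang, 0.0, 0.0]))
        env_base = np.asarray(env_base)
        charges.extend([q] * len(env_base))
        sigma_delta = spec.jitter_sigma * BOHR_PER_ANGSTROM
        d = spec.axial_distance_bohr
        nominal_std_ha = (2.0 * np.sqrt(2.0) * q * _PERMANENT_DIPOLE_DELTA
                          * sigma_delta / d**3)
        gaps = spec.resolved_gaps_ev()
        manifest["axial_charge"] = q
        manifest["nominal"] = {
            qc.id: {"mean_ev": float(gaps[i]),
                    "std_ev": float(nominal_std_ha * HARTREE_TO_EV)}
            for i, qc in enumerate(qcs)
        }
        if spec.two_basin is not None:
            tb = spec.two_basin
            i0 = tb.qc_index
            basin_means = []
            basin_stds = []
            for off in tb.distance_offsets_bohr:
                dr = d + off
                shift_ha = q * _PERMANENT_DIPOLE_DELTA * (1.0 / dr**2 - 1.0 / d**2)
                std_ha = (2.0 * q * _PERMANENT_DIPOLE_DELTA * sigma_delta
                          * np.sqrt(1.0 / dr**6 + 1.0 / d**6))
                basin_means.append(float(gaps[i0] + shift_ha * HARTREE_TO_EV))
                basin_stds.append(float(std_ha * HARTREE_TO_EV))
            manifest["two_basin"] = {
                "qc_id": qcs[i0].id,
                "block_length": tb.block_length,
                "basin_means_ev": basin_means,
                "basin_stds_ev": basin_stds,
            }
    else:
        env_base = _place_env_atoms(spec, rng, qc_coms)
        env_charges = rng.normal(scale=spec.charge_std, size=spec.n_env_atoms)
        charges.extend(env_charges.tolist())
        if spec.two_basin is not None:
            manifest["two_basin"] = {
                "block_length": spec.two_basin.block_length,
                "group_size": spec.two_basin.group_size,
                "displacement": list(spec.two_basin.displacement),
            }
    elements.extend(["O"] * len(env_base))
    charges = np.asarray(charges)
    manifest["base_env_coordinates"] = env_base.tolist()
    manifest["charges"] = charges.tolist()

    frames: List[EnvironmentFrame] = []
    for t in range(spec.n_frames):
        coords = np.array(base_coords)
        # rigid per-frame translation of each QC
        for qc in qcs:
            idx = qc_atom_map[qc.id]
            coords[idx] += rng.normal(scale=spec.qc_jitter_sigma, size=3)
        env = env_base.copy()
        if spec.calibrated:
            # axial distances jitter along x only; geometry stays in z = 0
            delta = rng.normal(scale=spec.jitter_sigma, size=len(env))
            signs = np.tile([1.0, -1.0], len(qcs))
            env[:, 0] += signs * delta
            if spec.two_basin is not None:
                tb = spec.two_basin
                basin = (t // tb.block_length) % 2
                off_ang = tb.distance_offsets_bohr[basin] / BOHR_PER_ANGSTROM
                env[2 * tb.qc_index, 0] += off_ang  # right charge of the chosen QC
        else:
            env += rng.normal(scale=spec.jitter_sigma, size=env.shape)
            if spec.two_basin is not None:
                tb = spec.two_basin
                basin = (t // tb.block_length) % 2
                if basin == 1:
                    env[: tb.group_size] += np.asarray(tb.displacement)
        frames.append(
            EnvironmentFrame(
                frame_index=t,
                coordinates=np.vstack([coords, env]),
                charges=charges.copy(),
                qc_atom_map=qc_atom_map,
            )
        )
    return frames, elements, manifest


def write_dataset(
    spec: SyntheticSpec,
    qcs: Sequence[QuantumCenter],
    frames: Sequence[EnvironmentFrame],
    elements: Sequence[str],
    manifest: dict,
    out_dir,
) -> Dict[str, Path]:
    """Persist the dataset in the formats the readers consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for qc in qcs:
        p = out_dir / f"qc_{qc.id}.json"
        write_qc_properties(qc, p)
        paths[f"qc_{qc.id}"] = p
    paths["ensemble"] = out_dir / "ensemble.xyz"
    write_xyz_ensemble(frames, elements, paths["ensemble"])
    paths["charges"] = out_dir / "charges.txt"
    write_charge_table(frames[0].charges, paths["charges"])
    doc = dict(manifest)
    doc["qc_atom_map"] = {
        qc_id: idx.tolist() for qc_id, idx in frames[0].qc_atom_map.items()
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(doc, indent=1))
    return paths


def generate_dataset(spec: SyntheticSpec, out_dir=None):
    """Convenience wrapper: QCs + ensemble (+ files when ``out_dir`` given)."""
    qcs, qc_manifest = generate_qc_set(spec)
    frames, elements, ens_manifest = generate_environment_ensemble(spec, qcs)
    manifest = {**qc_manifest, **ens_manifest}
    if out_dir is not None:
        write_dataset(spec, qcs, frames, elements, manifest, out_dir)
    return qcs, frames, elements, manifest


def ground_truth_check(
    qcs: Sequence[QuantumCenter],
    frames: Sequence[EnvironmentFrame],
    traces,
    solutions=None,
    *,
    tolerance: float = 1e-10,
) -> dict:
    """Compare pipeline outputs against the brute-force reference evaluation.

    The reference path re-derives per-frame site energies (and, when exciton
    solutions are given, couplings and exciton energies) with the independent
    implementation in :mod:`excitonkit._reference` and reports the maximum
    absolute deviations in Hartree.
    """
    ref = _reference.reference_site_records(frames, qcs)
    max_site = 0.0
    for qc in qcs:
        tr = traces[qc.id]
        rows = {int(f): i for i, f in enumerate(tr.frame_indices)}
        for rec in ref[qc.id]:
            i = rows[rec["frame"]]
            gap = tr.excited_energies_hartree[i] - tr.ground_energies_hartree[i]
            max_site = max(max_site, abs(gap - rec["gap_hartree"]))
    report = {
        "tolerance_hartree": tolerance,
        "max_site_energy_deviation_hartree": max_site,
    }
    if solutions is not None:
        from .datamodel import HARTREE_TO_CM

        ref_exc = _reference.reference_exciton(frames, qcs, ref)
        by_frame = {r["frame"]: r for r in ref_exc}
        max_coupling = 0.0
        max_exciton = 0.0
        for s in solutions:
            r = by_frame[s.frame_index]
            vref = r["matrix_hartree"] - np.diag(np.diag(r["matrix_hartree"]))
            vsol = s.coupling_matrix_cm / HARTREE_TO_CM
            max_coupling = max(max_coupling, float(np.max(np.abs(vref - vsol))))
            eref = r["exciton_energies_hartree"]
            esol = s.exciton_energies_ev / HARTREE_TO_EV
            max_exciton = max(max_exciton, float(np.max(np.abs(eref - esol))))
        report["max_coupling_deviation_hartree"] = max_coupling
        report["max_exciton_deviation_hartree"] = max_exciton
    report["within_tolerance"] = all(
        v <= tolerance for k, v in report.items()
        if k.endswith("deviation_hartree")
    )
    return report
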