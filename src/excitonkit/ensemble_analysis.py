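"""Ensemble statistics, subpopulation analysis and the broadened line shape."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .datamodel import HC_EV_NM, ExcitonSolution, SiteEnergyTrace
from .errors import ConfigurationError, DomainError
from .trajectory_io import SITE_TABLE_COLUMNS


def _histogram(values: np.ndarray, bins=None):
    """Freedman-Diaconis histogram by default; ``bins`` may be a fixed bin
    width in the data's units or anything ``numpy.histogram`` accepts."""
    values = np.asarray(values, dtype=float)
    if bins is None:
        if len(values) < 2 or np.ptp(values) == 0:
            return np.histogram(values, bins=1)
        return np.histogram(values, bins="fd")
    if np.isscalar(bins) and not isinstance(bins, (int, np.integer, str)):
        edges = np.arange(values.min(), values.max() + bins, bins)
        if len(edges) < 2:
            edges = np.array([values.min(), values.min() + bins])
        return np.histogram(values, bins=edges)
    return np.histogram(values, bins=bins)


def site_energy_statistics(
    traces: Mapping[str, SiteEnergyTrace],
    *,
    bins=None,
) -> Tuple[pd.DataFrame, Dict[str, Tuple[np.ndarray, np.ndarray]]]:
    """Per-QC sample mean/std (ddof=1), skewness and histogram of site energies."""
    rows = []
    histograms = {}
    for qc_id, tr in traces.items():
        e = tr.site_energies_ev
        if len(e) < 2:
            raise DomainError(f"QC {qc_id!r}: statistics require at least 2 frames")
        rows.append({
            "qc": qc_id,
            "mean_ev": float(e.mean()),
            "std_ev": float(e.std(ddof=1)),
            "skewness": float(scipy.stats.skew(e)) if e.std() > 0 else 0.0,
            "n_frames": len(e),
        })
        histograms[qc_id] = _histogram(e, bins=bins)
    return pd.DataFrame(rows).set_index("qc"), histograms


def electrochromic_shift(site_table: pd.DataFrame) -> pd.DataFrame:
    """Shifts (embedded minus gas-phase), in integer meV, per pigment.

    Returns one column per embedded context (isolated complex, full complex).
    """
    for col in ("gas_energy_ev", "isolated_energy_ev", "full_energy_ev"):
        if col not in site_table.columns:
            raise ConfigurationError(f"site table is missing column {col!r}")
    gas = site_table["gas_energy_ev"].to_numpy(dtype=float)
    out = pd.DataFrame(index=site_table.index)
    for col, name in (("isolated_energy_ev", "isolated_shift_mev"),
                      ("full_energy_ev", "full_shift_mev")):
        shift = (site_table[col].to_numpy(dtype=float) - gas) * 1000.0
        out[name] = np.rint(shift).astype(int)
    return out


def range_summary(
    values: Mapping[str, float],
) -> Tuple[Tuple[str, float], Tuple[str, float]]:
    """(label, value) of the minimum and maximum; ties break by input order."""
    if not values:
        raise DomainError("range_summary requires at least one entry")
    items = list(values.items())
    min_label, min_val = items[0]
    max_label, max_val = items[0]
    for label, v in items[1:]:
        if v < min_val:
            min_label, min_val = label, v
        if v > max_val:
            max_label, max_val = label, v
    return (min_label, float(min_val)), (max_label, float(max_val))


def first_exciton_distribution(
    solutions: Sequence[ExcitonSolution],
    *,
    bins=None,
    fit_mixture: bool = False,
    random_state: int = 0,
) -> dict:
    """Histogram of first-exciton energies plus paired contribution vectors.

    With ``fit_mixture`` a two-component Gaussian mixture summarizes the two
    subpopulations; on failure the summary falls back to a single component
    with a warning.
    """
    if not solutions:
        raise DomainError("first_exciton_distribution requires at least one solution")
    energies = np.array([s.exciton_energies_ev[0] for s in solutions])
    contributions = np.stack([s.contributions[:, 0] for s in solutions])
    counts, edges = _histogram(energies, bins=bins)
    result = {
        "energies_ev": energies,
        "contributions": contributions,
        "basis_ids": solutions[0].basis_ids,
        "histogram": (counts, edges),
    }
    if fit_mixture:
        try:
            from sklearn.mixture import GaussianMixture

            gm = GaussianMixture(
                n_components=2, random_state=random_state, n_init=5
            ).fit(energies.reshape(-1, 1))
            means = np.sort(gm.means_.ravel())
            result["mixture_means_ev"] = means
            result["mixture_weights"] = gm.weights_[np.argsort(gm.means_.ravel())]
            result["mixture_stds_ev"] = np.sqrt(
                gm.covariances_.ravel()[np.argsort(gm.means_.ravel())]
            )
        except Exception as err:  # pragma: no cover - defensive fallback
            warnings.warn(f"mixture fit failed ({err}); unimodal summary", stacklevel=2)
            result["mixture_means_ev"] = np.array([energies.mean()])
            result["mixture_weights"] = np.array([1.0])
            result["mixture_stds_ev"] = np.array([energies.std(ddof=1)])
    return result


def contribution_by_energy(
    solutions: Sequence[ExcitonSolution],
    group_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-frame summed first-exciton weight per named group vs exciton energy."""
    if not solutions:
        raise DomainError("contribution_by_energy requires at least one solution")
    basis = solutions[0].basis_ids
    unmapped = [b for b in basis if b not in group_map]
    if unmapped:
        raise ConfigurationError(f"basis ids without a group: {unmapped}")
    groups = sorted(set(group_map[b] for b in basis))
    members = {g: [i for i, b in enumerate(basis) if group_map[b] == g] for g in groups}
    rows = []
    for s in solutions:
        w = s.contributions[:, 0]
        row = {"frame": s.frame_index, "energy_ev": s.exciton_energies_ev[0]}
        for g in groups:
            row[g] = float(w[members[g]].sum())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Absorption line shape
# ---------------------------------------------------------------------------


@dataclass
class LineshapeResult:
    wavelength_nm: np.ndarray
    intensity: np.ndarray
    peak_nm: float
    splitting_nm: float  # NaN when no secondary feature is detected
    fwhm_nm: float


def _fwhm(grid: np.ndarray, y: np.ndarray) -> float:
    half = y.max() / 2.0
    above = y >= half
    idx = np.flatnonzero(above)
    if len(idx) == 0:
        return float("nan")

    def crossing(i0, i1):
        # linear interpolation between samples straddling the half maximum
        x0, x1, y0, y1 = grid[i0], grid[i1], y[i0], y[i1]
        if y1 == y0:
            return x0
        return x0 + (half - y0) * (x1 - x0) / (y1 - y0)

    left = grid[idx[0]] if idx[0] == 0 else crossing(idx[0] - 1, idx[0])
    right = grid[idx[-1]] if idx[-1] == len(grid) - 1 else crossing(idx[-1], idx[-1] + 1)
    return float(abs(right - left))


def _secondary_feature(grid: np.ndarray, y: np.ndarray) -> float:
    """Wavelength distance from the global peak to the most prominent secondary
    peak, or to the strongest shoulder (second-derivative minimum) if no
    distinct secondary peak exists.  NaN when nothing is found."""
    peak_pos = grid[int(np.argmax(y))]
    peaks, props = scipy.signal.find_peaks(y, prominence=1e-3 * y.max())
    if len(peaks) >= 2:
        order = np.argsort(props["prominences"])[::-1]
        main = peaks[order[0]]
        second = peaks[order[1]]
        return float(abs(grid[main] - grid[second]))
    # shoulder: local minima of the second derivative away from the main peak
    d2 = np.gradient(np.gradient(y, grid), grid)
    cand, _ = scipy.signal.find_peaks(-d2)
    w = _fwhm(grid, y)
    scale = w if np.isfinite(w) and w > 0 else np.ptp(grid) / 10
    cand = [c for c in cand
            if d2[c] < 0 and abs(grid[c] - peak_pos) > 0.25 * scale
            and y[c] > 0.05 * y.max()]
    if not cand:
        return float("nan")
    best = min(cand, key=lambda c: d2[c])
    return float(abs(grid[best] - peak_pos))


def lineshape_from_sticks(
    centers_nm: Sequence[float],
    weights: Sequence[float],
    width_nm: float,
    grid_nm: np.ndarray | None = None,
) -> LineshapeResult:
    """Unit-area sum of Gaussian kernels on a wavelength axis, with metrics."""
    centers = np.asarray(centers_nm, dtype=float)
    w = np.asarray(weights, dtype=float)
    if width_nm <= 0:
        raise DomainError("kernel width must be positive")
    if grid_nm is None:
        lo = centers.min() - 6 * width_nm
        hi = centers.max() + 6 * width_nm
        grid_nm = np.linspace(lo, hi, 4001)
    grid_nm = np.asarray(grid_nm, dtype=float)
    if grid_nm.size < 2:
        raise DomainError("wavelength grid must contain at least 2 points")
    kern = np.exp(-0.5 * ((grid_nm[None, :] - centers[:, None]) / width_nm) ** 2)
    intensity = (w[:, None] * kern).sum(axis=0)
    area = np.trapezoid(intensity, grid_nm)
    if area <= 0:
        raise DomainError("spectrum has zero area (all weights zero?)")
    intensity = intensity / area
    return LineshapeResult(
        wavelength_nm=grid_nm,
        intensity=intensity,
        peak_nm=float(grid_nm[int(np.argmax(intensity))]),
        splitting_nm=_secondary_feature(grid_nm, intensity),
        fwhm_nm=_fwhm(grid_nm, intensity),
    )


def absorption_lineshape(
    solutions: Sequence[ExcitonSolution],
    width_nm: float,
    grid_nm: np.ndarray | None = None,
) -> LineshapeResult:
    """Ensemble spectrum: Gaussian kernel per exciton per frame, weighted by
    the exciton dipole strength ``|sum_i c_ia mu'_i|^2`` and normalized to
    unit area on the wavelength axis."""
    if not solutions:
        raise DomainError("absorption_lineshape requires at least one solution")
    centers: List[float] = []
    weights: List[float] = []
    for s in solutions:
        if s.transition_dipoles is None:
            raise DomainError(
                "solutions lack per-basis transition dipoles; rerun the exciton "
                "stage to populate them"
            )
        for a in range(s.n_basis):
            e = s.exciton_energies_ev[a]
            if e <= 0:
                continue
            mu_exc = s.eigenvectors[:, a] @ s.transition_dipoles
            centers.append(HC_EV_NM / e)
            weights.append(float(mu_exc @ mu_exc))
    return lineshape_from_sticks(centers, weights, width_nm, grid_nm)


def summarize_tables(
    site_table: pd.DataFrame,
    coupling_table: pd.DataFrame,
) -> dict:
    """Report shifts, site-energy ranges and the extreme coupling of the tables."""
    shifts = electrochromic_shift(site_table)
    report = {"shifts_mev": shifts.to_dict(orient="index")}
    for col, name in (("gas_energy_ev", "gas"),
                      ("isolated_energy_ev", "isolated"),
                      ("full_energy_ev", "full")):
        (lo_l, lo), (hi_l, hi) = range_summary(dict(site_table[col]))
        report[f"{name}_range_ev"] = {
            "min": {"site": lo_l, "energy_ev": lo},
            "max": {"site": hi_l, "energy_ev": hi},
        }
    m = coupling_table.to_numpy()
    off = ~np.eye(len(m), dtype=bool)
    k = np.argmax(np.abs(m)[off].reshape(-1))
    ii, jj = np.transpose(np.nonzero(off))[k]
    report["max_abs_coupling_cm"] = {
        "pair": [coupling_table.index[ii], coupling_table.columns[jj]],
        "value_cm": float(m[ii, jj]),
        "abs_value_cm": float(abs(m[ii, jj])),
    }
    return report
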