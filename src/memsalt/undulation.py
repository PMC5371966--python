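"""Membrane undulation spectrum and the Helfrich bending-stiffness fit.

The out-of-plane displacement field of the bilayer midplane is sampled on a
coarse periodic grid (default 12×12 cells) from the z-coordinates of the
glycerol–tail junction carbons, each leaflet's mean subtracted.  Its 2D
Fourier spectrum, radially binned in |q|, follows the Helfrich form for a
tensionless-to-weakly-tense fluid sheet:

    ⟨u²(q)⟩ = k_B T / (⟨L_x⟩²·(k_c q⁴ + γ̃ q²)),

from which a nonlinear least-squares fit in the low-wavenumber regime
(default q ≤ 2.0 nm⁻¹) yields the bending stiffness k_c (J) and the
microscopic surface-tension coefficient γ̃ (mN·m⁻¹).

FFT convention: with Ũ = FFT2(z̄)/N², a pure mode z̄ = A·cos(q₀x) carries
⟨u²(q₀)⟩ = A²/4 in each of the two conjugate modes, and Parseval reads
Σ_q |Ũ_q|² = spatial mean of z̄².  The synthetic Helfrich sampler
(synthetic_data) shares this convention, making closure tests
convention-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from memsalt.core_model import Constants, Frame, Topology

#: 1 J·nm⁻² in mN·m⁻¹ (1 J/nm² = 1e18 J/m² = 1e21 mN/m)
J_NM2_TO_MN_M = 1e21


class FitError(RuntimeError):
    """Helfrich fit failed (too few points or unphysical optimum)."""


@dataclass(frozen=True)
class UndulationGrid:
    """Cell-averaged displacement field z̄(x_i, y_j) on an L-periodic grid."""

    values: np.ndarray  # (n, n) nm
    box_xy: tuple  # (L_x, L_y) nm
    fill_mask: np.ndarray  # True where the cell was neighbor-filled


@dataclass(frozen=True)
class Spectrum:
    """Radially binned undulation intensity ⟨u²(q)⟩."""

    q: np.ndarray  # nm⁻¹
    u2: np.ndarray  # nm²
    n_modes: np.ndarray


@dataclass(frozen=True)
class HelfrichFit:
    k_c: float  # J
    k_c_err: float
    gamma_tilde: float  # mN·m⁻¹
    gamma_tilde_err: float
    q_max: float
    r_squared: float


def undulation_field(frame: Frame, topology: Topology,
                     n_cells: int = 12,
                     reference_tag: str = "junction_carbon") -> UndulationGrid:
    """Grid the leaflet-mean-subtracted z of the reference atoms.

    Atoms of both leaflets are pooled into one n×n grid by their x,y cell;
    empty cells are filled with the periodic 8-neighbor average, iterated
    until no empty cells remain.
    """
    mask = topology.select(reference_tag)
    if not mask.any():
        raise ValueError(f"no atoms tagged {reference_tag!r}")
    z = frame.coords[mask, 2].astype(float).copy()
    xy = frame.coords[mask, :2]
    leaf = topology.leaflet[mask]
    for side in ("upper", "lower"):
        sel = leaf == side
        if sel.any():
            z[sel] -= z[sel].mean()
    lx, ly = float(frame.box[0]), float(frame.box[1])
    ix = np.floor(np.mod(xy[:, 0], lx) / lx * n_cells).astype(int) % n_cells
    iy = np.floor(np.mod(xy[:, 1], ly) / ly * n_cells).astype(int) % n_cells
    grid = np.zeros((n_cells, n_cells))
    count = np.zeros((n_cells, n_cells))
    np.add.at(grid, (ix, iy), z)
    np.add.at(count, (ix, iy), 1.0)
    empty = count == 0
    if empty.all():
        raise ValueError("all grid cells empty")
    with np.errstate(invalid="ignore"):
        grid = np.where(empty, np.nan, grid / np.where(empty, 1.0, count))
    fill_mask = empty.copy()
    while np.isnan(grid).any():
        nan = np.isnan(grid)
        acc = np.zeros_like(grid)
        num = np.zeros_like(grid)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                sh = np.roll(np.roll(grid, dx, axis=0), dy, axis=1)
                ok = ~np.isnan(sh)
                acc[ok] += sh[ok]
                num[ok] += 1.0
        fillable = nan & (num > 0)
        if not fillable.any():  # isolated region; fill with zero
            grid[nan] = 0.0
            break
        grid[fillable] = acc[fillable] / num[fillable]
    return UndulationGrid(values=grid, box_xy=(lx, ly), fill_mask=fill_mask)


def _mode_q(n: int, L: float) -> np.ndarray:
    """|q| per FFT mode: q_mn = 2π(m, n)/L with signed frequencies."""
    f = 2.0 * np.pi * np.fft.fftfreq(n, d=L / n)
    qx, qy = np.meshgrid(f, f, indexing="ij")
    return np.sqrt(qx**2 + qy**2)


def spectrum(grids: Sequence[UndulationGrid | np.ndarray],
             box_size: float | None = None) -> Spectrum:
    """Frame-averaged 2D FFT intensity of the displacement grids, radially
    binned with one bin per distinct |q| on the lattice; zero mode excluded.
    """
    if len(grids) == 0:
        raise ValueError("need at least one grid")
    first = grids[0]
    if isinstance(first, UndulationGrid):
        n = first.values.shape[0]
        L = first.box_xy[0] if box_size is None else box_size
    else:
        n = np.asarray(first).shape[0]
        if box_size is None:
            raise ValueError("box_size required for bare-array grids")
        L = box_size
    qmag = _mode_q(n, L)
    acc = np.zeros((n, n))
    for g in grids:
        arr = g.values if isinstance(g, UndulationGrid) else np.asarray(g)
        u = np.fft.fft2(arr) / n**2
        acc += np.abs(u) ** 2
    acc /= len(grids)
    qr = np.round(qmag, 9).ravel()
    ir = acc.ravel()
    keep = qr > 0
    qs = np.unique(qr[keep])
    u2 = np.array([ir[qr == q].mean() for q in qs])
    n_modes = np.array([(qr == q).sum() for q in qs])
    return Spectrum(q=qs, u2=u2, n_modes=n_modes)


def helfrich_model(q: np.ndarray, k_c: float, gamma_j_nm2: float,
                   L: float, T: float = 300.0) -> np.ndarray:
    """⟨u²(q)⟩ in nm² for k_c in J, γ̃ in J·nm⁻², box edge L in nm."""
    kT = Constants(T=T).kT_joule
    return kT / (L**2 * (k_c * q**4 + gamma_j_nm2 * q**2))


def fit_helfrich(spec: Spectrum, mean_Lx: float, T: float = 300.0,
                 q_max: float = 2.0) -> HelfrichFit:
    """Fit the Helfrich spectrum to ⟨u²(q)⟩ for q ≤ q_max.

    Unweighted nonlinear least squares on u² (not log u²); parameters are
    internally scaled (k_c in 10⁻²⁰ J, γ̃ in mN·m⁻¹) for conditioning.
    Returns k_c in J, γ̃ in mN·m⁻¹, 1σ errors from the covariance, and the
    r² of fitted vs observed intensities.
    """
    sel = spec.q <= q_max
    q, u2 = spec.q[sel], spec.u2[sel]
    if q.size < 3:
        raise FitError(f"only {q.size} spectrum points with q ≤ {q_max}")
    kT = Constants(T=T).kT_joule

    def model(qq, k20, g_mn):
        k_c = k20 * 1e-20
        gamma = g_mn / J_NM2_TO_MN_M
        return kT / (mean_Lx**2 * (k_c * qq**4 + gamma * qq**2))

    p0 = (2.0, 10.0)
    try:
        popt, pcov = curve_fit(model, q, u2, p0=p0,
                               bounds=([1e-6, -1e3], [1e6, 1e6]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Helfrich fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    fitted = model(q, *popt)
    ss_res = float(np.sum((u2 - fitted) ** 2))
    ss_tot = float(np.sum((u2 - u2.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    k_c = popt[0] * 1e-20
    if k_c <= 0:
        raise FitError("fit converged to non-positive bending stiffness")
    return HelfrichFit(k_c=k_c, k_c_err=perr[0] * 1e-20,
                       gamma_tilde=popt[1], gamma_tilde_err=perr[1],
                       q_max=q_max, r_squared=max(0.0, min(1.0, r2)))
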