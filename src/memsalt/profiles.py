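"""Number-density profiles along the bilayer normal and derived landmarks.

The common intermediate of the binding, electrostatics and thickness stages
is a 1D binned density along z (the membrane normal), accumulated over
frames with per-frame box volumes.  From the phosphorus and water-oxygen
profiles this module extracts the head-to-head bilayer thickness D_HH, the
water-layer thickness d_w = ⟨L_z⟩ − D_HH, the shear planes z_s (half-bulk
water density), the water-layer midpoint z_m, and the bulk salt
concentration c̄_blk (geometric mean of the ion densities at z_m).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from memsalt.core_model import Constants, Frame, Topology


class SelectionError(ValueError):
    """The atom selection for a profile is empty."""


class LandmarkError(ValueError):
    """A structural landmark (peak, crossing) cannot be located."""


@dataclass(frozen=True)
class Profile1D:
    """A binned scalar field along z, frame-averaged.

    ``values`` are densities per nm³ (number or charge); bins are uniform
    and span [−L_z/2, L_z/2) of the (mean) box.
    """

    bin_edges: np.ndarray
    values: np.ndarray
    species: str = ""
    n_frames: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if len(vals) != len(edges) - 1:
            raise ValueError("len(values) must equal len(bin_edges) - 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "values", vals)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def dz(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def at(self, z: float) -> float:
        """Density linearly interpolated between bin centers at position z."""
        return float(np.interp(z, self.centers, self.values))


@dataclass(frozen=True)
class MembraneLandmarks:
    """Scalar landmarks of a centered bilayer–water system."""

    D_HH: float  # nm, head-to-head bilayer thickness
    d_w: float  # nm, water layer thickness
    z_s_lower: float  # nm, shear plane below the membrane (< 0)
    z_s_upper: float  # nm, shear plane above the membrane (> 0)
    z_m: float  # nm, center of the water layer (may be wrapped)
    c_blk: float  # mol/L, bulk salt concentration


def density_profile(frames: Sequence[Frame], topology: Topology, species: str,
                    n_bins: int = 500) -> Profile1D:
    """Time-averaged number density of atoms tagged ``species`` along z.

    Each frame's histogram is normalized by its own bin volume
    L_x·L_y·Δz (the box fluctuates under semi-isotropic barostatting); the
    fixed bin grid spans [−⟨L_z⟩/2, ⟨L_z⟩/2).  Frames must be centered.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be ≥ 10")
    mask = topology.select(species)
    if not mask.any():
        raise SelectionError(f"no atoms tagged {species!r}")
    mean_lz = float(np.mean([fr.box[2] for fr in frames]))
    edges = np.linspace(-mean_lz / 2.0, mean_lz / 2.0, n_bins + 1)
    dz = edges[1] - edges[0]
    acc = np.zeros(n_bins)
    for fr in frames:
        counts, _ = np.histogram(fr.coords[mask, 2], bins=edges)
        acc += counts / (fr.box[0] * fr.box[1] * dz)
    return Profile1D(bin_edges=edges, values=acc / len(frames),
                     species=species, n_frames=len(frames))


def bilayer_thickness(phosphorus_profile: Profile1D) -> float:
    """Head-to-head thickness D_HH: distance between the density maxima of
    the phosphorus profile on the two sides of z = 0.

    Raw bin maxima are used; ties are broken toward larger |z|.
    """
    c = phosphorus_profile.centers
    v = phosphorus_profile.values
    peaks = []
    for side in (c < 0, c > 0):
        vs, cs = v[side], c[side]
        if vs.size == 0 or vs.max() <= 0:
            raise LandmarkError("no density maximum on one side of z=0")
        best = np.flatnonzero(vs == vs.max())
        idx = best[np.argmax(np.abs(cs[best]))]
        # require an interior local maximum, not a monotone edge ramp
        peaks.append(cs[idx])
    lo, hi = peaks
    if not (lo < 0 < hi):
        raise LandmarkError("phosphorus peaks do not bracket z=0")
    # a single central peak straddling z=0 is not a bilayer: demand a dip
    # between the two putative headgroup peaks
    between = (c > lo) & (c < hi)
    peak_height = min(v[np.argmin(np.abs(c - lo))], v[np.argmin(np.abs(c - hi))])
    if between.any() and v[between].min() > 0.9 * peak_height:
        raise LandmarkError("no density dip between peaks: single central peak")
    return float(hi - lo)


def water_layer_thickness(mean_L_z: float, D_HH: float) -> float:
    """Water layer thickness d_w = ⟨L_z⟩ − D_HH."""
    if mean_L_z <= D_HH:
        raise ValueError(f"⟨L_z⟩ = {mean_L_z} must exceed D_HH = {D_HH}")
    return mean_L_z - D_HH


def shear_plane(water_profile: Profile1D,
                bulk_fraction: float = 0.2) -> tuple[float, float]:
    """Locate the shear planes: the z on each side of the membrane where the
    water density first reaches half its bulk value moving outward from z=0.

    The bulk value is the mean density over the outermost ``bulk_fraction``
    of |z| on both sides.  Crossings are linearly interpolated between bin
    centers.  Returns (z_s_lower, z_s_upper) with z_s_lower < 0 < z_s_upper.
    """
    c = water_profile.centers
    v = water_profile.values
    half_l = np.abs(c) >= (1.0 - bulk_fraction) * np.abs(c).max()
    bulk = v[half_l].mean()
    if bulk <= 0:
        raise LandmarkError("no positive bulk water plateau")
    half = bulk / 2.0
    out = []
    for sign in (-1, 1):
        side = np.flatnonzero(sign * c > 0)
        order = side[np.argsort(np.abs(c[side]))]  # innermost → outermost
        vv, cc = v[order], c[order]
        cross = np.flatnonzero((vv[:-1] < half) & (vv[1:] >= half))
        if cross.size == 0:
            raise LandmarkError("water density never crosses half-bulk")
        i = cross[0]
        frac = (half - vv[i]) / (vv[i + 1] - vv[i])
        out.append(float(cc[i] + frac * (cc[i + 1] - cc[i])))
    z_lo, z_hi = out
    return z_lo, z_hi


def water_midplane(z_s_lower: float, z_s_upper: float, mean_L_z: float) -> float:
    """Midpoint z_m of the water slab through the periodic z boundary.

    After centering, the water layer runs from z_s_upper up across ±L_z/2 and
    back to z_s_lower; its midpoint is wrapped into [−L_z/2, L_z/2).
    """
    zm = 0.5 * (z_s_upper + (z_s_lower + mean_L_z))
    return float(np.mod(zm + mean_L_z / 2.0, mean_L_z) - mean_L_z / 2.0)


def bulk_concentration(rho_na_profile: Profile1D, rho_cl_profile: Profile1D,
                       z_m: float,
                       constants: Constants = Constants()) -> float:
    """Bulk salt concentration in mol/L from the geometric mean of the Na⁺ and
    Cl⁻ number densities (nm⁻³) at the water-layer midpoint z_m:
    c̄_blk = 10²⁴ · N_A⁻¹ · √(ρ_Na(z_m)·ρ_Cl(z_m)).
    """
    rho_na = rho_na_profile.at(z_m)
    rho_cl = rho_cl_profile.at(z_m)
    if rho_na < 0 or rho_cl < 0:
        raise ValueError("ion densities must be non-negative")
    return 1e24 / constants.N_A * float(np.sqrt(rho_na * rho_cl))


def landmarks(water_profile: Profile1D, phosphorus_profile: Profile1D,
              rho_na: Profile1D | None, rho_cl: Profile1D | None,
              mean_L_z: float,
              constants: Constants = Constants()) -> MembraneLandmarks:
    """Convenience: derive all scalar landmarks from the three profiles."""
    d_hh = bilayer_thickness(phosphorus_profile)
    d_w = water_layer_thickness(mean_L_z, d_hh)
    z_lo, z_hi = shear_plane(water_profile)
    z_m = water_midplane(z_lo, z_hi, mean_L_z)
    c_blk = 0.0
    if rho_na is not None and rho_cl is not None:
        c_blk = bulk_concentration(rho_na, rho_cl, z_m, constants)
    return MembraneLandmarks(D_HH=d_hh, d_w=d_w, z_s_lower=z_lo,
                             z_s_upper=z_hi, z_m=z_m, c_blk=c_blk)


def write_profile_tsv(path, profile: Profile1D, stderr=None,
                      units: str = "nm^-3") -> None:
    """Write a profile as 3-column TSV (z_center, value, stderr)."""
    import pandas as pd

    err = stderr if stderr is not None else np.zeros_like(profile.values)
    pd.DataFrame({
        f"z_nm[{profile.species}]": profile.centers,
        f"density_{units}": profile.values,
        "stderr": err,
    }).to_csv(path, sep="\t", index=False)
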