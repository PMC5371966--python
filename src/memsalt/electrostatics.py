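"""Intramembrane electrostatic potential from binned charge density.

The potential along the bilayer normal follows from the 1D Poisson equation,
φ″(z) = −ρ_a(z)/ε₀, integrated twice over the binned atom-based charge
density with zero field in the bulk water:

    φ(z) = C − ε₀⁻¹ ∫_z^{L_z/2} dz′ ∫_{z′}^{L_z/2} dz″ ρ_a(z″).

The summation is atom-based (each point charge binned individually), the
common convention for membrane simulations even though a molecule-based
grouping would be the more rigorous multipole bookkeeping; see the methods
note.  Component profiles (all atoms / ions / lipids / water) are anchored
to zero in the bulk except the water component, which is anchored at the
bilayer center.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from memsalt.core_model import Constants, Frame, Topology
from memsalt.profiles import Profile1D, SelectionError


@dataclass(frozen=True)
class PotentialProfile:
    """Electrostatic potential φ(z) in volts along the bilayer normal."""

    z: np.ndarray  # nm, bin centers
    phi: np.ndarray  # V
    component: str = "all"  # all | ions | lipids | water
    anchoring: str = "bulk_zero"  # bulk_zero | center_zero
    symmetrized: bool = False


def charge_density(frames: Sequence[Frame], topology: Topology,
                   subset: str = "all",
                   bin_width: float = 0.093) -> Profile1D:
    """Frame-averaged atom-based charge density (e·nm⁻³) along z.

    ``subset`` is 'all' or a topology tag ('na_ion', 'lipid', 'water', ...);
    the per-bin sum of atomic charges is divided by the per-frame bin
    volume.  The bin count is ⌈⟨L_z⟩/bin_width⌉ on a fixed grid spanning
    [−⟨L_z⟩/2, ⟨L_z⟩/2).
    """
    if subset == "all":
        mask = np.ones(topology.n_atoms, dtype=bool)
    else:
        mask = topology.select(subset)
        # 'ions' convenience: union of the two ion tags
        if subset == "ions":
            mask = topology.select("na_ion") | topology.select("cl_ion")
        if not mask.any():
            raise SelectionError(f"no atoms in subset {subset!r}")
    mean_lz = float(np.mean([fr.box[2] for fr in frames]))
    n_bins = max(10, int(round(mean_lz / bin_width)))
    edges = np.linspace(-mean_lz / 2.0, mean_lz / 2.0, n_bins + 1)
    dz = edges[1] - edges[0]
    q = topology.charge[mask]
    acc = np.zeros(n_bins)
    for fr in frames:
        h, _ = np.histogram(fr.coords[mask, 2], bins=edges, weights=q)
        acc += h / (fr.box[0] * fr.box[1] * dz)
    return Profile1D(bin_edges=edges, values=acc / len(frames),
                     species=f"charge[{subset}]", n_frames=len(frames))


def potential(charge_profile: Profile1D, anchoring: str = "bulk_zero",
              component: str = "all",
              constants: Constants = Constants(),
              bulk_fraction: float = 0.1) -> PotentialProfile:
    """Double-integrate a charge-density profile into a potential profile.

    Trapezoidal cumulative integration with the field anchored to zero at
    the box edge (the bulk); the integration constant is then fixed by
    ``anchoring``: 'bulk_zero' subtracts the mean φ over the outermost
    ``bulk_fraction`` of |z|, 'center_zero' subtracts φ at the bin nearest
    z = 0.  Charge density in e·nm⁻³ yields φ in V via e/(ε₀·nm) ≈ 18.095.
    """
    z = charge_profile.centers
    dz = np.diff(z)
    if not np.allclose(dz, dz[0], rtol=1e-8):
        raise ValueError("potential integration requires uniform bins")
    rho = charge_profile.values
    # The binned ρ is piecewise constant, so the field I(z) = ∫_z^{top} ρ dz″
    # is exactly linear within each bin: evaluate it at the bin edges by a
    # suffix bin-sum (exact, and exactly zero at the bottom for a neutral
    # system), then integrate the piecewise-linear field analytically down
    # to each bin center.  φ(top edge) = 0 before re-anchoring.
    h = float(dz[0])
    n = rho.size
    inner_e = np.zeros(n + 1)  # I at edges, I[top] = 0
    inner_e[:-1] = h * np.cumsum(rho[::-1])[::-1]
    seg = h * (inner_e[:-1] + inner_e[1:]) / 2.0  # ∫ I over each bin (exact)
    outer_e = np.zeros(n + 1)  # G(z) = ∫_z^{top} I dz′ at edges
    outer_e[:-1] = np.cumsum(seg[::-1])[::-1]
    inner_c = (inner_e[:-1] + inner_e[1:]) / 2.0  # I at centers
    outer_c = outer_e[1:] + (h / 2.0) * (inner_c + inner_e[1:]) / 2.0
    phi = -constants.e_over_eps0_nm * outer_c
    if anchoring == "bulk_zero":
        sel = np.abs(z) >= (1.0 - bulk_fraction) * np.abs(z).max()
        phi = phi - phi[sel].mean()
    elif anchoring == "center_zero":
        phi = phi - phi[np.argmin(np.abs(z))]
    else:
        raise ValueError(f"unknown anchoring {anchoring!r}")
    return PotentialProfile(z=z, phi=phi, component=component,
                            anchoring=anchoring)


def symmetrize(profile: PotentialProfile) -> PotentialProfile:
    """Mirror-average about the bilayer center: φ_sym(z) = (φ(z)+φ(−z))/2.

    Idempotent linear projection; requires a z grid symmetric about 0."""
    if not np.allclose(profile.z, -profile.z[::-1], atol=1e-9):
        raise ValueError("grid is not centered; cannot symmetrize")
    phi_sym = 0.5 * (profile.phi + profile.phi[::-1])
    return replace(profile, phi=phi_sym, symmetrized=True)
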