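"""Bilayer mechanics: area per lipid, compressibility, disjoining pressures,
finite-size extrapolation and the leaflet-interdigitation coefficient.

Under periodic boundary conditions the bilayer interacts with its own images
across the water layer; the resulting disjoining pressure is estimated two
ways.  P_MD infers it from membrane elasticity and the salt-induced area
change, P_MD = (κ_A/d_w)·(1 − a_L/a_L,o); P_TH is the theoretical osmotic
repulsion from unequal counterion densities at the water-layer midplane,
P_TH = kT·(√ρ_Na − √ρ_Cl)².  The interdigitation coefficient
B = k_c/(κ_A·D_HH²) compares bending stiffness with stretching stiffness:
B ≈ 1/48 for freely sliding leaflets, ≈ 1/12 for strongly coupled ones.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from memsalt.core_model import Constants, Frame, ScalarWithError, block_average_error

#: J·nm⁻² per kJ·mol⁻¹·nm⁻²
KJMOL_NM2_TO_J_NM2 = 1e3 / Constants().N_A


def area_per_lipid_series(frames: Sequence[Frame], N_L: int) -> np.ndarray:
    """Per-frame area per lipid a_L = L_x·L_y/(N_L/2) in nm²."""
    if N_L <= 0 or N_L % 2:
        raise ValueError("N_L must be positive and even")
    return np.array([fr.box[0] * fr.box[1] for fr in frames]) / (N_L / 2.0)


def area_per_lipid(frames: Sequence[Frame], N_L: int) -> ScalarWithError:
    """Mean area per lipid with a block-averaging error estimate."""
    series = area_per_lipid_series(frames, N_L)
    if series.size < 10:
        return ScalarWithError(value=float(series.mean()), error=0.0, method="none")
    return block_average_error(series)


def area_compressibility(aL_series, N_L: int, T: float = 300.0) -> float:
    """Area compressibility κ_A = k_B T·ā_L / ((N_L/2)·Var(a_L)) in
    kJ·mol⁻¹·nm⁻², from equilibrium area fluctuations.

    The population variance of the per-frame a_L is used.  Fluctuation-based
    κ_A is only meaningful for barostats with correct volume statistics
    (e.g. Parrinello–Rahman).
    """
    x = np.asarray(aL_series, dtype=float)
    if x.size < 100:
        raise ValueError("need ≥ 100 area samples for a fluctuation estimate")
    var = float(x.var())  # population variance
    if var < 1e-20 * float(x.mean()) ** 2:
        raise ValueError("zero area variance: degenerate input")
    const = Constants(T=T)
    return const.kT * float(x.mean()) / ((N_L / 2.0) * var)


def p_md(kappa_A: float, d_w: float, a_L_o: float, a_L: float) -> float:
    """Disjoining pressure inferred from the simulated area change:
    P_MD = (κ_A/d_w)·(1 − a_L/a_L,o), in kJ·mol⁻¹·nm⁻³.

    ``a_L_o`` is the salt-free reference area per lipid.  Sign is free:
    positive means image bilayers repel.
    """
    if d_w <= 0 or a_L_o <= 0:
        raise ValueError("d_w and a_L_o must be positive")
    return kappa_A / d_w * (1.0 - a_L / a_L_o)


def p_th(rho_na_zm: float, rho_cl_zm: float, T: float = 300.0) -> float:
    """Theoretical disjoining pressure from ion densities (nm⁻³) at the
    water-layer midplane: P_TH = kT·(√ρ_Na − √ρ_Cl)², in kJ·mol⁻¹·nm⁻³.

    Always ≥ 0; zero iff the two densities are equal.
    """
    if rho_na_zm < 0 or rho_cl_zm < 0:
        raise ValueError("densities must be non-negative")
    const = Constants(T=T)
    return const.kT * (np.sqrt(rho_na_zm) - np.sqrt(rho_cl_zm)) ** 2


def a_L_infinity(P: float, kappa_A: float, d_w: float, a_L_o: float) -> float:
    """Area per lipid at infinite bilayer separation implied by a disjoining
    pressure P: a_L,o,∞ = a_L,o·(1 − P·d_w/κ_A).

    Feeding back P = p_md(...) returns a_L identically (the relation is the
    algebraic inverse); the physically-motivated extrapolation uses P = P_TH.
    """
    if kappa_A <= 0:
        raise ValueError("kappa_A must be positive")
    return a_L_o * (1.0 - P * d_w / kappa_A)


def finite_size_free_energy(kappa_A: float, a_L_o: float,
                            a_L_o_inf: float) -> float:
    """Free energy of relaxing the area per lipid from a_L,o to a_L,o,∞:
    ΔG_FS = κ_A·(a_L,o,∞ − a_L,o)²/(2·a_L,o), in kJ·mol⁻¹ (per lipid ·nm²
    bookkeeping cancels).  Always ≥ 0.
    """
    if a_L_o <= 0:
        raise ValueError("a_L_o must be positive")
    return kappa_A * (a_L_o_inf - a_L_o) ** 2 / (2.0 * a_L_o)


def interdigitation_B(k_c_joule: float, kappa_A_kjmolnm2: float,
                      D_HH_nm: float) -> float:
    """Interdigitation coefficient B = k_c/(κ_A·D_HH²), dimensionless.

    ``k_c`` in J; ``κ_A`` in kJ·mol⁻¹·nm⁻² (converted internally to J·nm⁻²
    via Avogadro's constant); ``D_HH`` in nm.
    """
    if k_c_joule <= 0 or kappa_A_kjmolnm2 <= 0 or D_HH_nm <= 0:
        raise ValueError("all inputs must be positive")
    kappa_j = kappa_A_kjmolnm2 * KJMOL_NM2_TO_J_NM2
    return k_c_joule / (kappa_j * D_HH_nm**2)
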