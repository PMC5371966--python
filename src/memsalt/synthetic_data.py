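"""Synthetic-trajectory generators with analytic ground truth.

Raw MD data for a solvated bilayer is bulky and rarely deposited; every
analysis stage in this package is therefore validated against generators
that emulate the *statistical structure* the stage consumes — not the
chemistry producing it:

* a bilayer slab with Gaussian phosphorus peaks, a logistic water interface
  and ions drawn from prescribed ρ(z) profiles (density/binding stages);
* equilibrium Helfrich surfaces with exponentially distributed mode
  intensities (undulation stage);
* 2D random walks with prescribed normal or anomalous diffusion (dynamics);
* static charged slabs with closed-form potentials (electrostatics);
* rigid all-trans chains at fixed tilt (order parameters).

Each generator is seeded and returns a manifest dict recording every
ground-truth parameter.  Defaults mirror the study conditions of a 128-POPC
patch in ~0.5 M NaCl at 300 K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from memsalt.core_model import Constants, Frame, Topology
from memsalt.order_dynamics import ChainGeometry
from memsalt.undulation import helfrich_model, J_NM2_TO_MN_M


# --------------------------------------------------------------------------
# Bilayer slab with ions
# --------------------------------------------------------------------------

@dataclass
class BilayerSpec:
    """Study-condition defaults: 128 lipids, ~0.5 M NaCl, box from the
    original-force-field run (a_L = 0.542 nm², ⟨L_z⟩ = 9.02 nm)."""

    seed: int = 0
    n_frames: int = 50
    box: tuple = (5.8898, 5.8898, 9.02)
    n_lipids: int = 128
    D_HH: float = 4.31
    peak_width: float = 0.25
    n_water: int = 5020
    water_z0: float | None = None  # default: D_HH/2
    water_width: float = 0.15
    n_na: int = 50
    n_cl: int = 50
    rho_na: Callable | None = None  # unnormalized ρ(z) shape, nm⁻³
    rho_cl: Callable | None = None
    center_offset: float = 0.0  # shift applied to all z (tests centering)
    box_area_sigma: float = 0.0  # relative std of L_x·L_y (barostat mimic)


def _inverse_cdf_sample(rng: np.random.Generator, shape: Callable,
                        lz: float, n: int) -> np.ndarray:
    zg = np.linspace(-lz / 2.0, lz / 2.0, 4001)
    pdf = np.clip(np.asarray(shape(zg), dtype=float), 0.0, None)
    if pdf.sum() <= 0:
        raise ValueError("density shape is identically zero")
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0
                                           * np.diff(zg))])
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.interp(u, cdf, zg)


def make_bilayer_slab(spec: BilayerSpec):
    """Generate (frames, topology, manifest) for a bilayer–water–ion slab.

    Phosphorus atoms (one per lipid) sit Gaussian about ±D_HH/2; water
    oxygens follow a logistic interface ρ_w ∝ 1/(1+exp(−(|z|−z0)/w)); ions
    are inverse-CDF sampled from the supplied ρ(z) shapes (default: same
    logistic shape).  Frames are independent equilibrium resamples.
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    z0 = spec.water_z0 if spec.water_z0 is not None else spec.D_HH / 2.0
    half = spec.n_lipids // 2

    def water_shape(z):
        return 1.0 / (1.0 + np.exp(-(np.abs(z) - z0) / spec.water_width))

    rho_na = spec.rho_na or water_shape
    rho_cl = spec.rho_cl or water_shape

    n_atoms = spec.n_lipids + spec.n_water + spec.n_na + spec.n_cl
    names, types, tags, mols = [], [], [], []
    for i in range(spec.n_lipids):
        names.append("P")
        types.append("P")
        tags.append({"lipid", "phosphorus"})
        mols.append(i)
    for i in range(spec.n_water):
        names.append("OW")
        types.append("OW")
        tags.append({"water", "water_oxygen"})
        mols.append(spec.n_lipids + i)
    for i in range(spec.n_na):
        names.append("NA")
        types.append("NA+")
        tags.append({"na_ion"})
        mols.append(spec.n_lipids + spec.n_water + i)
    for i in range(spec.n_cl):
        names.append("CL")
        types.append("CL-")
        tags.append({"cl_ion"})
        mols.append(spec.n_lipids + spec.n_water + spec.n_na + i)
    top = Topology(atom_name=np.array(names, dtype=object),
                   atom_type=np.array(types, dtype=object),
                   charge=np.zeros(n_atoms),
                   mol_id=np.array(mols),
                   tags=tags)

    frames = []
    for t in range(spec.n_frames):
        scale = 1.0
        if spec.box_area_sigma > 0:
            scale = np.sqrt(max(0.1, 1.0 + spec.box_area_sigma
                                * rng.standard_normal()))
        coords = np.empty((n_atoms, 3))
        coords[:, 0] = rng.random(n_atoms) * lx * scale
        coords[:, 1] = rng.random(n_atoms) * ly * scale
        zp_upper = rng.normal(+spec.D_HH / 2.0, spec.peak_width, half)
        zp_lower = rng.normal(-spec.D_HH / 2.0, spec.peak_width, half)
        z = np.empty(n_atoms)
        z[: spec.n_lipids] = np.concatenate([zp_upper, zp_lower])
        sl = slice(spec.n_lipids, spec.n_lipids + spec.n_water)
        z[sl] = _inverse_cdf_sample(rng, water_shape, lz, spec.n_water)
        sl = slice(spec.n_lipids + spec.n_water,
                   spec.n_lipids + spec.n_water + spec.n_na)
        z[sl] = _inverse_cdf_sample(rng, rho_na, lz, spec.n_na)
        sl = slice(n_atoms - spec.n_cl, n_atoms)
        z[sl] = _inverse_cdf_sample(rng, rho_cl, lz, spec.n_cl)
        z = np.mod(z + spec.center_offset + lz / 2.0, lz) - lz / 2.0
        coords[:, 2] = z
        frames.append(Frame(time=float(t), coords=coords,
                            box=np.array([lx * scale, ly * scale, lz])))
    manifest = {
        "generator": "make_bilayer_slab",
        "seed": spec.seed,
        "box": list(spec.box),
        "n_frames": spec.n_frames,
        "n_lipids": spec.n_lipids,
        "D_HH": spec.D_HH,
        "peak_width": spec.peak_width,
        "water_z0": z0,
        "water_width": spec.water_width,
        "n_water": spec.n_water,
        "n_na": spec.n_na,
        "n_cl": spec.n_cl,
        "center_offset": spec.center_offset,
        "box_area_sigma": spec.box_area_sigma,
    }
    return frames, top, manifest


# --------------------------------------------------------------------------
# Helfrich surfaces
# --------------------------------------------------------------------------

@dataclass
class HelfrichSpec:
    """Defaults follow the large pure-water patch: L = 12.47 nm, 12×12 grid,
    k_c = 2.8e-20 J, γ̃ = 17.3 mN/m, 300 K."""

    seed: int = 0
    n_frames: int = 2000
    n_cells: int = 12
    L: float = 12.47
    k_c: float = 2.8e-20  # J
    gamma_mN_m: float = 17.3
    T: float = 300.0


def make_helfrich_frames(spec: HelfrichSpec):
    """Sample equilibrium displacement grids of a Helfrich sheet.

    Mode amplitudes are complex Gaussian with Hermitian symmetry (hence
    exponential intensities, the equilibrium distribution of a harmonic
    mode) with per-mode expectation ⟨|ũ_q|²⟩ = kT/(L²(k_c q⁴+γ̃q²)) under
    the package FFT convention Ũ = FFT2(z̄)/N².  Returns (grids, manifest).
    """
    if spec.k_c <= 0 or spec.gamma_mN_m < 0:
        raise ValueError("k_c must be > 0 and γ̃ ≥ 0")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    f = 2.0 * np.pi * np.fft.fftfreq(n, d=spec.L / n)
    qx, qy = np.meshgrid(f, f, indexing="ij")
    q = np.sqrt(qx**2 + qy**2)
    gamma = spec.gamma_mN_m / J_NM2_TO_MN_M
    target = np.zeros_like(q)
    nz = q > 0
    target[nz] = helfrich_model(q[nz], spec.k_c, gamma, spec.L, spec.T)
    grids = []
    for _ in range(spec.n_frames):
        w = rng.standard_normal((n, n))
        a = np.fft.fft2(w)  # Hermitian, E|A_q|² = n²
        c = a * np.sqrt(target) / n  # E|C_q|² = target, exponential intensity
        grids.append(np.real(np.fft.ifft2(c * n**2)))
    manifest = {
        "generator": "make_helfrich_frames",
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "n_cells": n,
        "L": spec.L,
        "k_c_J": spec.k_c,
        "gamma_mN_m": spec.gamma_mN_m,
        "T": spec.T,
    }
    return grids, manifest


# --------------------------------------------------------------------------
# Lateral random walks
# --------------------------------------------------------------------------

@dataclass
class WalkSpec:
    """Defaults: 128 walkers sampled every 2 ps for 6 ns at the pure-water
    medium-window diffusivity 45e-8 cm²/s."""

    seed: int = 0
    n_walkers: int = 128
    n_frames: int = 3001
    dt: float = 2.0  # ps
    D: float = 45.0  # 10⁻⁸ cm²·s⁻¹
    alpha: float = 1.0  # anomalous exponent; MSD(t) = 4·D_gen·t^alpha from t=0
    # two-regime (caged) variant: Ornstein–Uhlenbeck "rattling" components
    # superimposed on the slow Brownian drift.  Stationary, with analytic
    # MSD(τ) = 4·D·τ + Σ_i 4·σ_i²·(1 − exp(−τ/τ_c,i)); the effective
    # window-fitted D then decreases from short to long lag windows, the
    # timescale dependence lipid trajectories show.
    cage_sigmas: tuple = ()  # nm, per component
    cage_taus: tuple = ()  # ps, per component
    box_xy: float = 1000.0  # nm; large so trajectories stay unwrapped


def make_random_walks(spec: WalkSpec):
    """Generate (frames, topology, manifest) of 2D Gaussian walks.

    For alpha = 1 increments have variance 2·D·Δt per dimension; for
    anomalous walks the increment variance over [t_{k−1}, t_k] is
    2·D·(t_k^α − t_{k−1}^α), giving exactly MSD(t) = 4·D·t^α from the
    origin.  Walkers carry lipid tags and are split across two leaflets.
    """
    if spec.D < 0:
        raise ValueError("D must be ≥ 0")
    rng = np.random.default_rng(spec.seed)
    d_int = spec.D * 1e-6  # nm²/ps^alpha
    t = np.arange(spec.n_frames) * spec.dt
    dvar = 2.0 * d_int * np.diff(t**spec.alpha)  # per-dimension step variance
    steps = rng.standard_normal((spec.n_frames - 1, spec.n_walkers, 2)) \
        * np.sqrt(dvar)[:, None, None]
    xy = np.empty((spec.n_frames, spec.n_walkers, 2))
    xy[0] = spec.box_xy / 2.0 + rng.random((spec.n_walkers, 2)) * 10.0
    xy[1:] = xy[0] + np.cumsum(steps, axis=0)
    for sigma, tau in zip(spec.cage_sigmas, spec.cage_taus):
        # exact stationary OU discretization per dimension
        decay = np.exp(-spec.dt / tau)
        innov = sigma * np.sqrt(1.0 - decay**2)
        ou = np.empty_like(xy)
        ou[0] = sigma * rng.standard_normal((spec.n_walkers, 2))
        for k in range(1, spec.n_frames):
            ou[k] = decay * ou[k - 1] \
                + innov * rng.standard_normal((spec.n_walkers, 2))
        xy += ou
    half = spec.n_walkers // 2
    leaflet = np.array(["upper"] * half + ["lower"] * (spec.n_walkers - half),
                       dtype=object)
    top = Topology(
        atom_name=np.array(["C"] * spec.n_walkers, dtype=object),
        atom_type=np.array(["C"] * spec.n_walkers, dtype=object),
        charge=np.zeros(spec.n_walkers),
        mol_id=np.arange(spec.n_walkers),
        tags=[{"lipid"} for _ in range(spec.n_walkers)],
        leaflet=leaflet,
    )
    box = np.array([spec.box_xy, spec.box_xy, 10.0])
    z = np.where(np.arange(spec.n_walkers) < half, 1.0, -1.0)
    frames = []
    for k in range(spec.n_frames):
        coords = np.column_stack([xy[k], z])
        frames.append(Frame(time=t[k], coords=coords, box=box))
    manifest = {
        "generator": "make_random_walks",
        "seed": spec.seed,
        "n_walkers": spec.n_walkers,
        "n_frames": spec.n_frames,
        "dt_ps": spec.dt,
        "D_1e-8_cm2_s": spec.D,
        "alpha": spec.alpha,
        "cage_sigmas_nm": list(spec.cage_sigmas),
        "cage_taus_ps": list(spec.cage_taus),
    }
    return frames, top, manifest


# --------------------------------------------------------------------------
# Charged slab
# --------------------------------------------------------------------------

@dataclass
class SlabSpec:
    seed: int = 0
    box: tuple = (6.0, 6.0, 12.0)
    slab_half_width: float = 1.5  # nm
    rho0: float = 0.05  # e·nm⁻³ inside the slab
    comp_z: float = 4.0  # compensating layer positions ±comp_z
    n_slab: int = 40000
    n_comp: int = 20000
    n_frames: int = 1
    compensate: bool = True


def make_charged_slab(spec: SlabSpec):
    """Generate (frames, topology, manifest) of a static uniform charged slab
    with optional neutralizing surface layers at ±comp_z.

    Inside the slab the analytic potential is parabolic with curvature
    φ″ = −ρ₀/ε₀; the manifest records ρ₀ and the layer geometry.
    """
    rng = np.random.default_rng(spec.seed)
    lx, ly, lz = spec.box
    a = spec.slab_half_width
    q_total = spec.rho0 * lx * ly * 2.0 * a
    q_slab = q_total / spec.n_slab
    n_atoms = spec.n_slab + (spec.n_comp if spec.compensate else 0)
    coords0 = np.empty((n_atoms, 3))
    coords0[:, 0] = rng.random(n_atoms) * lx
    coords0[:, 1] = rng.random(n_atoms) * ly
    coords0[: spec.n_slab, 2] = rng.uniform(-a, a, spec.n_slab)
    charge = np.full(n_atoms, q_slab)
    tags: list = [{"slab"} for _ in range(spec.n_slab)]
    if spec.compensate:
        halfc = spec.n_comp // 2
        zc = np.concatenate([np.full(halfc, spec.comp_z),
                             np.full(spec.n_comp - halfc, -spec.comp_z)])
        coords0[spec.n_slab:, 2] = zc
        charge[spec.n_slab:] = -q_total / spec.n_comp
        tags += [{"comp"} for _ in range(spec.n_comp)]
    top = Topology(
        atom_name=np.array(["Q"] * n_atoms, dtype=object),
        atom_type=np.array(["Q"] * n_atoms, dtype=object),
        charge=charge,
        mol_id=np.arange(n_atoms),
        tags=tags,
    )
    frames = [Frame(time=float(k), coords=coords0.copy(),
                    box=np.array([lx, ly, lz])) for k in range(spec.n_frames)]
    manifest = {
        "generator": "make_charged_slab",
        "seed": spec.seed,
        "box": list(spec.box),
        "rho0_e_nm3": spec.rho0,
        "slab_half_width": a,
        "comp_z": spec.comp_z if spec.compensate else None,
        "total_charge_e": 0.0 if spec.compensate else q_total,
    }
    return frames, top, manifest


# --------------------------------------------------------------------------
# Tilted all-trans chains
# --------------------------------------------------------------------------

@dataclass
class ChainSpec:
    seed: int = 0
    n_chains: int = 200
    n_carbons: int = 10
    tilt_deg: float = 0.0
    isotropic: bool = False  # random axis orientation instead of fixed tilt
    n_frames: int = 20
    box: tuple = (20.0, 20.0, 20.0)


def _rotation(axis_theta: float, azimuth: float) -> np.ndarray:
    ct, st = np.cos(axis_theta), np.sin(axis_theta)
    ca, sa = np.cos(azimuth), np.sin(azimuth)
    ry = np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]])
    rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    return rz @ ry


def make_tilted_chains(spec: ChainSpec):
    """Generate (frames, topology, geometry, manifest) of rigid all-trans
    chains tilted by ψ from z (random azimuth per chain per frame).

    For a rigid zigzag every reconstructed C–D vector is perpendicular to
    the chain axis, so the azimuth-averaged order parameter is the
    closed form S = −P₂(cos ψ)/2 (−0.5 at ψ = 0, 0 under isotropic
    orientations).  The plane of the zigzag is also randomized.
    """
    rng = np.random.default_rng(spec.seed)
    n_at = spec.n_chains * spec.n_carbons
    # ideal zigzag in the x–z plane: axis along z
    k = np.arange(spec.n_carbons)
    base = np.column_stack([0.0445 * (-1.0) ** k, np.zeros_like(k, dtype=float),
                            0.127 * k])
    base -= base.mean(axis=0)
    psi = np.deg2rad(spec.tilt_deg)
    frames = []
    for fidx in range(spec.n_frames):
        coords = np.empty((n_at, 3))
        for ci in range(spec.n_chains):
            if spec.isotropic:
                theta = np.arccos(rng.uniform(-1.0, 1.0))
            else:
                theta = psi
            rot = _rotation(theta, rng.uniform(0.0, 2.0 * np.pi))
            spin = _rotation(0.0, rng.uniform(0.0, 2.0 * np.pi))  # about axis
            pts = (rot @ (spin @ base.T)).T
            offset = rng.random(3) * np.array(spec.box) * 0.5 \
                + np.array(spec.box) * 0.25
            coords[ci * spec.n_carbons:(ci + 1) * spec.n_carbons] = pts + offset
        frames.append(Frame(time=float(fidx), coords=coords,
                            box=np.array(spec.box, dtype=float)))
    top = Topology(
        atom_name=np.array(["C"] * n_at, dtype=object),
        atom_type=np.array(["CH2"] * n_at, dtype=object),
        charge=np.zeros(n_at),
        mol_id=np.repeat(np.arange(spec.n_chains), spec.n_carbons),
        tags=[{"lipid", "tail_carbon"} for _ in range(n_at)],
    )
    geometry = ChainGeometry(chains=tuple(
        tuple(range(c * spec.n_carbons, (c + 1) * spec.n_carbons))
        for c in range(spec.n_chains)))
    s_analytic = (0.0 if spec.isotropic
                  else -0.25 * (3.0 * np.cos(psi) ** 2 - 1.0))
    manifest = {
        "generator": "make_tilted_chains",
        "seed": spec.seed,
        "n_chains": spec.n_chains,
        "n_carbons": spec.n_carbons,
        "tilt_deg": spec.tilt_deg,
        "isotropic": spec.isotropic,
        "S_analytic": s_analytic,
    }
    return frames, top, geometry, manifest


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
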