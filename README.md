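# memsalt

Analysis toolkit for molecular-dynamics studies of lipid bilayers in
electrolyte solutions — how dissolved salt (e.g. ~0.5 M NaCl around a POPC
membrane) reshapes membrane structure, mechanics, order, dynamics and
electrostatics. It is written for simulators who have trajectories of a
solvated bilayer (or want ground-truth synthetic ones) and need the standard
battery of membrane observables with honest error estimates.

## What it computes

Given frames (coordinates + orthorhombic box) and a topology table
(charges, molecule ids, atom-group tags, leaflets), the package derives:

* **Density profiles and landmarks** — number densities ρ(z) along the
  bilayer normal; head-to-head thickness D_HH (distance between phosphorus
  density peaks); water-layer thickness d_w = ⟨L_z⟩ − D_HH; the shear
  planes z_s where the water density falls to half its bulk value; the bulk
  salt concentration c̄_blk = 10²⁴ N_A⁻¹ √(ρ_Na(z_m) ρ_Cl(z_m)).
* **Ion–membrane binding** — per-leaflet bound counts
  Ñ_b = a_L (N_L/2) ∫₀^{z_s} ρ_ion(z) dz and the mass-action constants
  K_app = α̃/((1−α̃) c̄_blk) with α̃ = Ñ_b/(N_L/2), plus the intrinsic
  constant K_int = K_app·exp(β q_I Δζ) correcting for the zeta potential.
* **Mechanics** — area per lipid a_L = ⟨L_x L_y⟩/(N_L/2); area
  compressibility κ_A = k_BT ā_L/((N_L/2) Var a_L); disjoining pressures
  between periodic bilayer images, both elastic
  (P_MD = (κ_A/d_w)(1 − a_L/a_L,o)) and osmotic
  (P_TH = k_BT (√ρ_Na − √ρ_Cl)² at the water midplane); finite-size
  extrapolation a_L,o,∞ and ΔG_FS; the interdigitation coefficient
  B = k_c/(κ_A D_HH²).
* **Order and dynamics** — deuterium order parameters
  S = ⟨3cos²θ − 1⟩/2 with united-atom hydrogen reconstruction; radial
  distribution functions and first/second-shell coordination numbers
  (with a shoulder fallback); timescale-resolved lateral diffusion from
  windowed MSD fits (2–6 ns, 100–500 ps, 2–10 ps).
* **Electrostatics** — the intramembrane potential φ(z) from double
  integration of the binned atom-based charge density (Poisson equation
  with zero bulk field), by component (all/ions/lipids/water), symmetrized.
* **Undulations** — 12×12-gridded displacement field of the glycerol–tail
  junction carbons, its 2D spectrum, and the Helfrich fit
  ⟨u²(q)⟩ = k_BT/(⟨L_x⟩²(k_c q⁴ + γ̃ q²)) for the bending stiffness k_c.
* **Force-field pair tables** — Lennard-Jones C12 scaling schemes for
  ion–ion and ion–lipid pairs (s_NaCl = 1.33, s_Cl = 0.057,
  s_Na = 3.2/3.0) on top of geometric-mean combination rules.

A `synthetic_data` module generates seeded fixtures with analytic ground
truth for every stage (bilayer slabs, Helfrich surfaces, random walks,
charged slabs, tilted chains), and `pipeline_cli` orchestrates multi-run
analyses from a YAML config, including the cross-run wiring mechanics needs
(κ_A from a fluctuation-faithful barostat twin, a_L,o from a salt-free run).

## Worked example

```python
from memsalt import synthetic_data as sd
from memsalt.core_model import center_membrane, assign_leaflets
from memsalt import profiles as pf, binding as bd

# a 128-lipid bilayer slab in ~0.5 M salt, 50 frames, known ground truth
frames, top, manifest = sd.make_bilayer_slab(sd.BilayerSpec(seed=5))
frames = center_membrane(frames, top)
top = assign_leaflets(frames[0], top)

water = pf.density_profile(frames, top, "water_oxygen", 500)
phosph = pf.density_profile(frames, top, "phosphorus", 500)
na = pf.density_profile(frames, top, "na_ion", 500)
cl = pf.density_profile(frames, top, "cl_ion", 500)
lm = pf.landmarks(water, phosph, na, cl, mean_L_z=9.02)
print(f"D_HH = {lm.D_HH:.2f} nm, d_w = {lm.d_w:.2f} nm, "
      f"z_s = ({lm.z_s_lower:.2f}, {lm.z_s_upper:.2f}) nm, "
      f"c_blk = {lm.c_blk:.2f} M")

res = bd.binding_result("Na+", na, (lm.z_s_lower, lm.z_s_upper),
                        a_L=0.542, N_L=128, c_blk=lm.c_blk)
print(f"K_app(Na+) = {res.K_app_mean:.2f} ± {res.K_app_sd:.2f} 1/M")
```

prints (seed 5):

```
D_HH = 4.44 nm, d_w = 4.58 nm, z_s = (-2.13, 2.13) nm, c_blk = 0.47 M
K_app(Na+) = 0.06 ± 0.01 1/M
```

D_HH lands within two histogram bins of the generator's 4.31 nm ground
truth, the shear planes sit at the half-bulk crossing of the logistic water
interface, and the small K_app reflects that this generator draws ions from
the same water-like profile (no surface enrichment) — an enriched ρ_Na(z)
passed via `BilayerSpec.rho_na` raises it accordingly.

The same stages are available from the shell:

```bash
memsalt synth --stage bilayer --seed 5 --out demo/
memsalt profile demo/trajectory.gro demo/topology.tsv --species phosphorus
memsalt run pipeline.yml
```

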