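# silksim

Crystal-model construction and water-mobility analysis for the crystalline domain of
*Bombyx mori* silk fibroin, represented by the alternating alanine–glycine
copolypeptide (Ala–Gly)<sub>n</sub> in its silk-I form.

Silk fibroin materials (sutures, scaffolds, films, biodegradable devices) change their
mechanical and degradation behaviour with water content, so a recurring modelling task
is: build the (Ala–Gly)<sub>n</sub> crystal, hydrate it, and quantify where water sits
and how it moves. `silksim` packages that workflow as a tested library and CLI:

* **Model building** — the four-chain orthorhombic silk-I unit cell
  (a = 17.8 Å, b = 15.7558 Å, c = 11.4904 Å) grown from backbone torsion templates by
  internal-coordinate (NeRF) placement, with explicit hydrogens, periodic terminal
  closure (each chain's C-terminus bonds to the N-terminus of its own periodic image)
  and supercell replication.
* **Hydration** — rigid three-site waters (O–H 0.9572 Å, H–O–H 104.52°) inserted by
  rejection sampling with a minimum silk–water distance of 1.7 Å under the
  minimum-image convention.
* **Synthetic dynamics** — Brownian water tracers with Arrhenius temperature
  dependence D(T) = D₀·exp(−Eₐ/RT) and optional per-axis anisotropy, plus backbone
  (φ, ψ) ensembles drawn from a stated secondary-structure composition. These carry
  exact ground truth (image counts, region labels), so every analysis stage is
  verifiable without an external MD or DFT engine.
* **Analysis** — Ramachandran classification into silk-relevant regions
  (3₁₀-helix, β-sheet, antiparallel β-sheet, left-handed α-helix, coil) with
  per-region fractions and density histograms; multi-origin mean-square displacement
  MSD(τ) = ⟨|x(t₀+τ) − x(t₀)|²⟩ (total and per axis); diffusion coefficients
  D = slope/(2·dim); Arrhenius regression of ln D on 1/T giving Eₐ = −slope·R and
  D₀ = exp(intercept); water occupancy grids; incorporation-energy bookkeeping
  E<sup>inc</sup> = E(SF+H₂O) − E(SF) − E(H₂O) with site ranking.

## Worked example

```python
from dataclasses import replace
import silksim as ss
from silksim.dynamics import REFERENCE_ARRHENIUS_CONFIG, ARRHENIUS_TEMPERATURES_K

unit = ss.build_unit_cell()                     # 272 atoms: 4 chains x 4 (Ala-Gly) x 17
super4 = ss.replicate(unit, 4, 4, 4)            # 17408 atoms
wet = ss.insert_waters(super4, 538, min_dist=1.7, seed=1)
print(wet.n_atoms, round(ss.water_mass_fraction(wet), 3))
# 19022 0.069

points = []
for i, T in enumerate(ARRHENIUS_TEMPERATURES_K):        # (273, 285, 298, 310) K
    cfg = replace(REFERENCE_ARRHENIUS_CONFIG, temperature_k=T, n_steps=1000, seed=100 + i)
    traj = ss.water_trajectory(cfg, 500, super4.cell)   # 500 tracers, 1 ns
    points.append((T, ss.fit_diffusion(ss.msd(traj))))
fit = ss.arrhenius_fit(points)
print(round(fit.ea_kj_mol, 2), f"{fit.d0_cm2_s:.2e}", round(fit.r_squared, 3))
# 12.32 1.95e-04 0.981
```

The first block builds and hydrates the 4×4×4 supercell: 19,022 atoms at ≈6.9 wt %
water. The second generates tracer trajectories whose ground-truth diffusivity follows
the Arrhenius law with Eₐ = 12.07 kJ mol⁻¹ and D₀ = 1.78 × 10⁻⁴ cm² s⁻¹, then recovers
those parameters through the MSD → D → Arrhenius pipeline: the printed 12.32 kJ mol⁻¹
and 1.95 × 10⁻⁴ cm² s⁻¹ are within the statistical spread of a 500-tracer, 1 ns run.

The same stages are available from the shell:

```sh
silksim build --supercell 2 2 2 --out super2.pdb
silksim hydrate super2.pdb super2_wet.pdb --n-waters 67 --seed 1
silksim simulate-water --temps 273,285,298,310 --n 500 --steps 1000 --seed 1 --out-prefix w
silksim msd --traj w_298K.xyz --out msd_298K.csv
silksim arrhenius --msd-dir . --temps 273,285,298,310 --out arrhenius.json
silksim run-all --seed 1 --out-dir out/
```

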