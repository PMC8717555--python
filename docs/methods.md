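# Methods

This note documents the models and procedures implemented in `silksim`, the parameter
choices that matter, what the synthetic-data generators do and do not emulate, and the
numerical conventions.

## The crystal model

The crystalline domain of *B. mori* silk fibroin is represented by the alternating
(Ala–Gly)<sub>n</sub> copolypeptide in an orthorhombic cell with the silk-I initial
lattice parameters a = 17.8 Å, b = 15.7558 Å, c = 11.4904 Å (all angles 90°). The unit
cell holds four chains of four Ala–Gly repeats each; with explicit hydrogens an Ala
residue carries 10 atoms (N, H, CA, HA, CB, HB1–3, C, O) and a Gly residue 7
(N, H, CA, HA1, HA2, C, O), so one repeat is 17 atoms and the default cell 272 atoms.
Supercells replicate the cell on an integer grid; the 2×2×2 and 4×4×4 systems contain
2176 and 17,408 atoms respectively (2377 and 19,022 when hydrated with 67 and 538
waters).

### Chain construction

Chains are grown atom-by-atom by NeRF internal-coordinate placement: each atom is
positioned from three predecessors by a bond length, a bond angle and a dihedral.
Bond lengths and angles use standard peptide geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å, sp²/tetrahedral angles); the full table lives in
`silksim.geometry.DEFAULT_GEOMETRY` and any entry can be overridden from a YAML file.
Backbone torsions come from a per-residue-type template; the default is the
3₁₀-helix-like silk-I assignment from NMR-constrained electronic-structure work on
this system, ⟨φ, ψ⟩ = (−59°, 119°) for Ala and (−78°, 149°) for Gly, with ω = 180°.
A virtual residue-0 frame bootstraps the first residue so that residue 1 honours its
φ; dihedrals recomputed from the built coordinates reproduce the template to well
below 10⁻⁴° for interior residues (a property the suite tests for random templates).
Dihedral signs follow the IUPAC convention and are cross-checked against MDAnalysis.

### Periodic closure

Chains propagate along the crystal c axis, and each chain's C-terminal carbonyl bonds
to the N-terminus of its own periodic image ("connected to mirror images of
themselves" in the construction it follows). A torsion template does not generally
produce a repeat period equal to c — the default template's natural period for four
repeats is 23.5 Å — so the chain is closed by a homogeneous axial strain: after
rotating the propagation vector onto +z, every atom is displaced along z in proportion
to its sequence position so that the virtual next nitrogen lands exactly on the image
of the first. The last carbonyl group is pinned to the closure end so the periodic
peptide bond keeps its ideal 1.329 Å length. A mismatch larger than 0.2 Å per atom
step raises a construction error naming the chain. The resulting cell is a
*topologically correct starting structure* (right stoichiometry, connectivity and
periodicity), not an energy-minimised one; relaxation belongs to external engines and
is out of scope.

The four chains sit at fractional (a, b) offsets (0,0), (½,0), (0,½), (½,½). These
offsets, and parallel chain orientation, are a documented assumption — the source
construction gives no numerical offsets or hydrogen-bond register. Replication along
c concatenates the periodic images into single longer chains so closure is
re-established across the enlarged cell; x/y images become new chains.

## Hydration

Rigid three-site waters (O–H 0.9572 Å, H–O–H 104.52°) are inserted with uniformly
random oxygen positions and orientations, accepted only if every water atom is at
least `min_dist` (default 1.7 Å) from every silk atom under the minimum-image
convention. The same exclusion is applied water–water — the source rule names only
silk, but without it the sampler can create steric clashes that only a relaxation
engine would remove. Silk lookups use a periodic KD-tree; the test suite checks the
result against a brute-force all-images oracle. Insertion is deterministic per seed;
an exhausted attempt budget (default 10,000 per water) raises an error reporting how
many waters were placed.

The reference water counts are fixed by the printed hydrated atom totals: 67 waters
for 2×2×2 ((2377 − 2176)/3) and 538 for 4×4×4 ((19,022 − 17,408)/3). These imply
≈6.9 wt % water, slightly below the nominal "ca. 7.5 wt %" that accompanies them; the
atom counts are taken as authoritative and the discrepancy is left as such.

## Synthetic dynamics

The generators replace external MD/AIMD engines with processes whose ground truth is
known exactly, which is what makes every analysis stage testable at desk scale.

**Water tracers.** Non-interacting Brownian particles in the periodic cell. The
diffusivity is either direct or Arrhenius, D(T) = D₀·exp(−Eₐ/RT) with
R = 8.314 J mol⁻¹ K⁻¹. Anisotropy is imposed through axis fractions (f_x, f_y, f_z)
summing to 1, with per-axis diffusivity D_axis = 3·f_axis·D, so the isotropic case
(⅓, ⅓, ⅓) gives MSD = 6Dt and the axis diffusivities always sum to 3D. Each step adds
a Gaussian increment of variance 2·D_axis·dt per axis; positions are wrapped with
integer image counts recorded, so unwrapped displacements are exact by construction.
Defaults mirror the study conditions: dt = 1 ps, 1000 steps (1 ns), 500 tracers, and
two emulation configs — Arrhenius mode with D₀ = 1.78 × 10⁻⁴ cm² s⁻¹ and
Eₐ = 12.07 kJ mol⁻¹ run at T ∈ {273, 285, 298, 310} K (the 273–310 K range with two
interior points, which are not printed and are therefore configurable), and a direct
room-temperature config with D = 1.60 × 10⁻⁶ cm² s⁻¹ at 298 K. The two configs are
kept independent because the two printed values are mutually inconsistent: the
Arrhenius pair evaluated at 298 K gives ≈1.36 × 10⁻⁶ cm² s⁻¹, not 1.60 × 10⁻⁶, an
~18% gap that the source leaves unexplained. Neither value is derived from the other
here.

The tracers do **not** model silk–water interactions, caging, sub-diffusive onset, or
any force-field physics; anisotropy is imposed, not emergent. Passing recovery tests
therefore demonstrates that the *analysis* chain (unwrapping, multi-origin MSD, OLS
slope, Arrhenius inversion) is unbiased and correctly scaled — it says nothing about
whether a real silk crystal channels water, only that if trajectories have a given
D(T) and anisotropy, the pipeline will report them.

**Torsion ensembles.** Each residue-frame draws a region label from a stated
composition over named Ramachandran regions plus "coil", then (φ, ψ) = region centre
+ independent Gaussian jitter (σ default 10°), wrapped to (−180°, 180°]. Coil samples
are uniform over the torus excluding every region rectangle, so the drawn label is
the classification ground truth. The default composition emulates the reported
populations: 37% 3₁₀-helix, 26% β-sheet, 37% coil, sampled for 2048 residues × 500
frames. With σ = 10° and ±30° half-widths, ~0.5% of region samples jitter outside
their rectangle, a bias well inside the ±2-point recovery tolerance.

## Ramachandran analysis

φ_i = dihedral(C_{i−1}, N_i, CA_i, C_i) and ψ_i = dihedral(N_i, CA_i, C_i, N_{i+1});
for periodically closed chains the missing neighbours come from the minimum-image
copy, so every residue has both angles. Classification uses rectangular regions with
±30° half-widths about the characteristic centres — left-handed α-helix (70°, 10°),
3₁₀-helix (−40°, −30°), β-sheet (−60°, 130°), antiparallel β-sheet (−143°, 142°) —
with priority order antiparallel β > β > 3₁₀ > left-handed α where rectangles
overlap; everything else is coil. Centres are as quoted for this system; half-widths,
priorities and the region list are configurable (YAML). Note that the silk-I torsion
template (−59°, 119°)/(−78°, 149°) lies inside the β-sheet rectangle as defined —
the region naming for that part of the map is ambiguous in the source and is
preserved as configured rather than resolved. Fractions are reported per region,
total and split Ala/Gly, with equal frame weights and waters excluded; the histogram
uses a 10° default bin width (the contour resolution is not specified anywhere, so
this is a package choice).

## Diffusion analysis

MSD is averaged over particles and over time origins spaced `origin_stride` frames
(default 10; the origin scheme is unspecified in the source) on unwrapped
coordinates. Trajectories must carry image counts (or no cell at all): MSD on wrapped
coordinates without image data raises an error, and no heuristic unwrapping is ever
attempted. The total MSD is defined as the sum of the per-axis components, so the
decomposition identity is exact at every lag. D = slope/(2·dim) over a fit window
defaulting to lags in [10%, 50%] of the maximum lag (avoiding the zero-lag end and
the poor-statistics tail; the source states no window), with 1 cm² s⁻¹ = 10⁴ Å² ps⁻¹.
The Arrhenius fit is ordinary least squares of ln D on 1/T, Eₐ = −slope·R,
D₀ = exp(intercept), with r² and residuals surfaced. Occupancy grids histogram
wrapped positions on a voxel lattice.

Expected statistical precision at the default problem size (500 tracers, 1 ns,
multi-origin): per-temperature D to ~2–3%, hence Eₐ over the 273–310 K ladder to
~5% and D₀ (an extrapolation of the intercept to 1/T = 0, which amplifies slope
noise ~3.4×) to within a factor of ~1.3 — consistent with the recovery tolerances
the acceptance suite asserts (10% on Eₐ, factor 1.5 on D₀, 5% on room-T D).

## Energetics

E<sup>inc</sup> = E(SF+H₂O) − E(SF) − E(H₂O) on a common reference; negative values
mean a thermodynamic driving force for uptake. Sites are ranked ascending with ties
broken lexicographically by label; E<sup>inc</sup> = 0 is classified unfavorable (no
driving force). The literature electronic-structure value for the most favorable
inter-chain site, −83.92 kJ mol⁻¹, ships as a documented reference constant
(`silksim.constants`) for comparison with user-supplied triples; reproducing it would
require an electronic-structure engine and is explicitly out of scope.

## Numerical choices and degenerate inputs

* Angles wrap to (−180°, 180]; classification is invariant under ±360° shifts.
* Dihedrals of colinear atom quadruples raise an error (undefined torsion).
* Wrapping is idempotent; fractional coordinates live in [0, 1).
* All randomness flows from one global seed through named, CRC-derived child seeds
  (< 2³¹), so any stage reproduces in isolation; identical seeds give bit-identical
  output.
* OLS fits use `scipy.stats.linregress`; two points fit exactly with r² = 1.
* File formats are plain text only: PDB (CRYST1/ATOM fixed columns, 3-decimal
  coordinates), extended multi-frame XYZ with per-atom image-count columns, CSV,
  JSON sidecars, YAML configs. Outputs embed a short hash of the producing
  configuration.

## Problem sizes

The default study sizes — 500 tracers × 1000 steps per temperature, 2048 residues ×
500 frames for the torsion ensemble, 67/538 inserted waters — match the emulated
study conditions and keep a full pipeline run (build, hydrate both supercells, four
Arrhenius temperatures, room-T run, ensemble analysis) around ten seconds on one CPU.

## Known limitations

* The built crystal is a schematic silk-I starting structure: the axial closure
  strain (the default template compresses ~2× along c) and the assumed chain offsets
  mean its geometry is not an equilibrium structure, and its static Ramachandran
  angles differ from the template. Equilibrated lattice parameters are engine
  territory and deliberately not predicted.
* Only Ala/Gly sequences are supported; Ser/Tyr/Val-containing fibroin sequences are
  out of scope.
* The tracer generator cannot validate claims about *why* diffusion in silk is
  anisotropic — only that imposed anisotropy is correctly measured.
* No force-field energies, thermostats or barostats anywhere; the energetics module
  is bookkeeping over externally supplied energies.
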