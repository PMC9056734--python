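# spinbarrier

Torsion-barrier landscapes, van Vleck NMR second moments and BPP
relaxometry for hindered molecular rotors in amorphous solids.

## The problem

Amorphous pharmaceutical solids have no crystal structure to diffract, so
their molecular dynamics — which methyl groups spin, which fragments
librate, how high the barriers are — must be read out of solid-state ¹H NMR
observables. The case this package is built around is amorphous
rosuvastatin calcium, where the dynamics even encode *chemistry*: the
rotatable isopropyl group of the E isomer has one unusually low-barrier
methyl, so the amplitude of the low-temperature relaxation process counts
the E-isomer population in an E/Z mixture.

`spinbarrier` implements the three computational stages of that analysis as
a reusable, tested pipeline:

1. **Steric torsion landscapes** (`structures`, `steric`). A molecule is an
   atom list plus a bond graph; a fragment is rotated rigidly about a
   single bond in 1° steps and the conformational energy is evaluated with
   the atom–atom (Buckingham exp-6) potential

   E(r_ij) = −A_ij·r_ij⁻⁶ + B_ij·exp(−C_ij·r_ij),

   summed over non-excluded pairs (A, B combined geometrically, C
   arithmetically). Barrier height = max − min of the landscape; minima
   structure and thermally accessible angular windows are extracted from
   the periodic grid.

2. **Second moments** (`spin_m2`). The rigid-lattice like-spin van Vleck
   powder second moment

   M₂ = (3/5)(μ₀/4π)² γ⁴ ħ² I(I+1) (1/N) Σ_{i≠j} r_ij⁻⁶  (reported in G²)

   and its motional averaging: each pair factor B_ij = (3cos²Θ_ij−1)/r_ij³
   is averaged over the jump sites of a motional model (C3 methyl hopping,
   restricted arcs, isotropic tumbling) *before* squaring — the fast-motion
   limit — with the powder average taken by seeded Monte-Carlo sampling of
   crystallite orientations. Proton-count composites and the
   intra/intermolecular split are included, as is second-moment read-back
   from CW derivative line shapes via M₂ = (1/3)∫x³g′dx / ∫x·g′dx.

3. **Relaxometry** (`relaxation`). Multi-process BPP spin–lattice
   relaxation,

   1/T₁ = Σ_k C_k [τ/(1+ω₀²τ²) + 4τ/(1+4ω₀²τ²)],  τ = τ₀·exp(E_A/RT),

   with the rotating-frame analogue (weights 3/2, 5/2, 1 at 2ω₁, ω₀, 2ω₀),
   deterministic multi-start least-squares fitting on ln T₁,
   T₁-minimum location, Arrhenius flank slopes, and the isomer-count
   inference: with ρ = C_low/C_med and E anions contributing 1 low-barrier
   + 3 medium-barrier methyls (Z anions: 4 medium), f_E = 4ρ/(1+ρ).

A `synthdata` module generates every input deterministically — ideal
tetrahedral methyl rotors, an isopropyl-on-scaffold toy with tunable
asymmetry, the 1.5 Å water proton pair, noisy T₁(T) datasets and Gaussian
CW line shapes — so the full pipeline runs and is tested with no external
data.

## Worked example

```python
from spinbarrier import *
from spinbarrier.synthdata import *

# 1. torsion barriers of the two methyls in the asymmetric isopropyl toy
mol = build_isopropyl_toy(asymmetry=DEFAULT_ISOPROPYL_ASYMMETRY)
for bond in ISOPROPYL_METHYL_BONDS:
    rb = partition_by_bond(mol, bond)
    ls = torsion_scan(mol, rb, step=1.0)
    print(bond, barrier_height(ls), len(find_minima(ls)))

# 2. methyl second moment, rigid vs fast C3 hopping
_, spins, motion = build_methyl()
print(rigid_m2_powder(spins).value)
print(mc_m2(spins, motion, n_orientations=100_000, seed=0).value)

# 3. fit a noisy synthetic T1(T) curve and infer the isomer ratio
ds = simulate_t1_dataset(noise_cv=0.05, seed=1)
fit = fit_bpp(ds, n_processes=2)
low, med = fit.processes
print(isomer_fraction(low.C, med.C))
```

prints (formatted):

```
bond (0, 3): barrier = 34.21 kJ/mol, 3 minima
bond (0, 4): barrier = 135.65 kJ/mol, 3 minima
rigid M2 = 22.524 G^2 ; fast C3 hopping -> 5.645 +- 0.019 G^2
low:    C = 2.31e+08 s^-2, tau0 = 5.93e-10 s, EA = 1.23 +- 0.02 kJ/mol
medium: C = 9.68e+08 s^-2, tau0 = 1.65e-11 s, EA = 6.87 +- 0.12 kJ/mol
T1 minimum: 0.097 s at 150.3 K
C_low/C_med = 0.239 -> f_E = 0.772 (75% E)
```

Reading: each methyl landscape shows the three-fold minima of a C3 rotor,
and the scaffold asymmetry makes one barrier ~4× the other — the E-isomer
signature. Fast C3 hopping reduces the intra-methyl second moment by the
closed-form factor 4. The two-process fit of the 5%-noise synthetic curve
recovers the generating parameters (C in s⁻², τ₀ in s, E_A in kJ/mol)
within their uncertainties; the C-constant ratio ≈ 0.24 translates through
the methyl-count model into ≈ 75% E isomer.

The same stages are scriptable from a shell:

```sh
spinbarrier synth t1 --noise-cv 0 --out t1.csv
spinbarrier relax fit --data t1.csv
spinbarrier relax isomers --c-low 2.29e8 --c-med 9.64e8
```

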