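# Methods

This note records the models implemented, the conventions and defaults
chosen where the underlying methods admit more than one, and what the
synthetic-data generators do and do not emulate.

## Geometry and torsion scans

A molecule is an ordered atom list (element, Å coordinates, potential
class) plus an undirected bond graph. Bonds come either from an explicit
sidecar list (preferred for toy fragments, since it is exactly
reproducible) or from the covalent-radius criterion d ≤ 1.2·(r_i + r_j)
with Cordero-style radii shipped in `data/covalent_radii.yaml`.

A bond is rotatable iff deleting it disconnects the graph in two; ring
bonds raise an explicit error. The rotation axis passes through the two
bond atoms, which are therefore invariant; the "rotating side" is the
component containing the partner atom. Angles are degrees throughout, with
the right-hand rule looking from pivot to partner; the sign convention is
arbitrary but consistent, and scans default to the grid −180…180° in 1°
steps (endpoint-inclusive, so periodic closure |E(−180)−E(180)| < 1e−9 is
an invariant the tests assert).

## Atom–atom potential

The non-bonded energy is the Buckingham exp-6 form E(r) = −A r⁻⁶ + B e^(−Cr),
with the attractive term first; tables written in the repulsive-first
dialect are rejected explicitly (a `convention` key in the parameter file)
rather than silently reinterpreted. Mixed-pair constants use the geometric
rule for A and B and the arithmetic rule for C.

The shipped parameter table (`data/exp6_params.yaml`, classes H C N O F S)
is a **representative Williams-type set, explicitly labelled a stand-in**:
the torsion analysis here is qualitative (three-fold minima, barrier
asymmetry ratios, accessible windows), and those conclusions are robust to
the exact historical parameterisation. Every operation accepts a user
table for quantitative work.

Pairs separated by one or two bonds are excluded from the sum (the standard
atom–atom-method convention; configurable via `ExclusionPolicy`). Landscape
energies are shifted so min = 0; barriers (max − min) are unaffected.
`find_minima` works on the periodic grid with a prominence filter (default
0.1 kJ/mol); plateau minima report the plateau's central grid point.
`accessible_range` returns maximal periodic intervals below a threshold,
merging across the ±180° seam.

## Second moments

The rigid like-spin powder value uses the van Vleck expression with the
3/5 powder prefactor and pinned CODATA constants (γ = 2.6752218744e8
rad s⁻¹ T⁻¹, ħ = 1.054571817e−34 J s, μ₀ = 1.25663706212e−6 N A⁻²), computed
in SI and reported in G² (1 T = 10⁴ G). Results are therefore bit-stable.

Motional averaging is implemented in the fast-motion limit only: the pair
factor B_ij = (3cos²Θ_ij − 1)/r_ij³ is averaged over the motional sites
*before* squaring. This reproduces plateau (fully averaged) second-moment
values; intermediate-rate line-shape theory is out of scope. Jump sites are
equally weighted (equal-well assumption). Protons in the same group jump
coherently (their site lists zip); protons in different groups are
independent (Cartesian product of sites). The powder average is Monte
Carlo: field directions uniform on the sphere from normalised 3-D normal
deviates of a seeded generator (default n = 100 000, standard error
reported, bit-reproducible given the seed). A static model agrees with the
analytic powder value within sampling error — asserted at 3σ in the tests.

Motion kinds: `static`, `c3_jump` (0/120/240°), `arc_jump` (explicit angle
list within an arc) and `isotropic`. The isotropic kind models fast
molecular tumbling (mobile water): its site set is the 60 rotations of the
icosahedral group, which average any rank-2 tensor exactly to zero, so an
intra-group pair contributes nothing — a quadrature, not a sampling,
choice, and the minimal mechanism that realises full tumbling with discrete
sites (a single-axis arc cannot: it always leaves the axial
(3cos²β−1)/2 factor).

Line-shape read-back uses the CW identity M₂ = (1/3)∫x³g′dx / ∫x g′dx for
first-derivative spectra: baseline is the mean of the outer 5% of points,
the line centre is the derivative zero-crossing nearest the grid midpoint,
and visibly truncated or asymmetric supports trigger warnings with the
offending magnitudes.

## BPP relaxometry

Laboratory frame: 1/T₁ = C[τ/(1+ω₀²τ²) + 4τ/(1+4ω₀²τ²)] with
τ = τ₀ exp(E_A/RT); independent processes add rates. Rotating frame:
weights (3/2, 5/2, 1) at frequencies (2ω₁, ω₀, 2ω₀) — the standard
like-spin dipolar form; alternative weight conventions rescale C only.
C is stored in s⁻² (dimensional analysis of the rate expression; some
published tables print the unit as 1/s). The rate expressions are written
in reciprocal form (1/(1/τ + ω²τ)) so that an overflowing τ at extreme
E_A/T combinations yields a zero rate rather than NaN — needed because the
fitter explores such corners.

Useful closed forms kept as named constants: the single-process rate
maximum sits at ω₀τ = 0.6157951…, where 1/T₁ = 1.4251757…·C/ω₀. In extreme
narrowing both frames give 5Cτ.

Fitting minimises equal-weight residuals on ln T₁, with log₁₀ C and
log₁₀ τ₀ as free parameters (natural scale for the optimiser) and E_A in
kJ/mol. Initialisation `"auto"` is deterministic: minima of the lightly
smoothed data seed one process each (C from the minimum depth via the
closed form, E_A from the cold-flank slope, τ₀ from ω₀τ = 0.6158 at the
minimum), plus, for two-process fits, a fixed family of fallback starts
that sweep plausible positions of the shallower process — the best final
residual wins. No random restarts. Parameters ending on bounds flag the fit
as unconverged. Reported processes are ordered by ascending E_A.

T₁-minimum location: coarse 1 K scan then bounded scalar minimisation to
0.01 K; a minimum on the range boundary raises "no interior minimum".
Arrhenius slopes: OLS of ln T₁ on 1000/T, E_A = |slope|·R; the declared
flank ("high" = extreme-narrowing side, negative slope) is checked and
sign/monotonicity violations warn rather than fail.

Isomer inference: ρ = C_low/C_med with E anions contributing 1 low-barrier
and 3 medium-barrier methyls and Z anions 4 medium ones gives
f_E = 4ρ/(1+ρ) (so ρ = 1/3 ⇔ pure E); values outside the model clip to
[0, 1] with a warning. A formatter rounds to the nearest 5% for reporting.
With the reported constants ρ = 2.29/9.64 = 0.238, f_E = 0.768, i.e. 75%
after rounding; note that published statements of "75/25" and "around 80%"
bracket this model's raw 77% — the counting model is stated here explicitly
rather than reverse-engineered.

A caveat the acceptance machinery makes visible: evaluating the two-process
model with the published rounded parameter set at 25 MHz puts the T₁
minimum at 150.3 K / 0.098 s. The depth matches the published ≈0.1 s within
5%, but the location sits ≈3.7 K below the published 154 K (the
experimentally observed minimum). The corresponding test asserts the
published location and is expected to fail by that margin; it is kept
failing deliberately rather than loosened, as the discrepancy is a genuine
property of the rounded parameter set under this (standard) BPP convention.

## Synthetic data

The generators define the study conditions; all are pure given
(parameters, seed).

* `build_methyl`: exact tetrahedral C3 rotor, r_CH default 1.09 Å
  (validated to the chemically sane 1.0–1.2 Å), H–H = r·√(8/3) = 1.780 Å.
* `build_isopropyl_toy`: isopropyl on a small scaffold (two O probes + H on
  the scaffold carbon). `asymmetry` (degrees of probe tilt-and-swing
  towards one methyl) = 0 gives exactly mirror-equivalent methyls ("Z-like");
  the shipped default 26.0 was fixed once, at fixture creation, to make the
  crowded methyl's barrier ≈4× the other ("E-like"), and the resulting
  ratio (3.9652 on the 1° grid) is frozen as fixture truth so tests detect
  regressions. Likewise the 13 kJ/mol window threshold at which the
  symmetric toy's central-bond landscape opens a single >80° window through
  0°. These fixtures reproduce the *qualitative* signatures; absolute
  barriers of the real anion depend on undeposited geometries and are not
  claimed.
* `build_water_pair`: two protons at exactly 1.5 Å; optional isotropic
  tumbling model.
* `simulate_t1_dataset`: T₁(T) from the two reference methyl processes
  (C = 9.64e8 s⁻², τ₀ = 1.69e−11 s, E_A = 6.84 kJ/mol medium;
  C = 2.29e8, τ₀ = 58.70e−11, E_A = 1.23 low) at 25 MHz on a 30–300 K, 2 K
  grid, with multiplicative log-normal noise of coefficient of variation
  0.05 (zero mean in log space, σ = √ln(1+cv²)).
* `simulate_flank_dataset`: single-flank ln T₁ linear in 1000/T with the
  slope set by a chosen E_A (default 15.8 kJ/mol over 260–344 K, 20 points).
* `simulate_lineshape`: analytic first derivative of a Gaussian absorption
  mixture; exact mixture M₂ = Σwσ²/Σw.

What passing tests therefore show: the machinery (geometry, potential sums,
averaging algebra, fitting) is correct on inputs whose ground truth is
known exactly. What they do not show: agreement with any particular
experimental curve, barrier heights of the real anion, or behaviour under
correlation-time distributions / stretched-exponential relaxation typical
of amorphous solids, none of which are modelled.

## Problem sizes and numerical settings

Defaults used by the test suite and the acceptance script: torsion grids of
1–10° on ≤14-atom toys; Monte-Carlo orientation counts of 10³–10⁵ (standard
error scales as 1/√n and is always reported); 100 replicate fits for the
parameter-recovery medians. Golden tolerances are stated per test; generic
numerical assertions use 1e−9 (rigid-body contracts), 3σ (Monte-Carlo
agreement) and 1% (quadrature-based line-shape moments).
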