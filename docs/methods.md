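# Methods

## The charge-fluctuation lattice model

The model asks a single question: can divalent counterions confined
between two like-charged DNA duplexes turn their interaction attractive?
It keeps only the electrostatics of the interfacial region. Each duplex
contributes one row of N interface phosphate sites (N ≈ L/b; with
L = 6.8 nm and b = 1.75 nm, N = round(3.89) = 4). A site is either
occupied by a divalent ion (charge αe − e = +1e for α = 2) or bare
(−1e). Configurations interact through screened Coulomb pair energies,
and the free energy at interhelical spacing x is the exact
grand-canonical sum over all 2^(2N) = 256 occupancy states. Everything
else about the real system — helical charge geometry, lipid dynamics,
hydration, dispersion — is deliberately absent, so only the *contrast*
between parameter sets is meaningful, not absolute depths.

Assumptions worth stating explicitly:

- **1-D interface lattice.** Only the phosphates facing the gap matter;
  the remaining backbone charge is absorbed into the rods' effective
  charge ν_eff.
- **Pairwise screened Coulomb.** Site–site energy
  c_i c_j ℓ_B e^(−κ_m r)/r with r = √(x² + b²Δ²) for inter-strand pairs
  and r = bΔ within a strand. Intra-strand pairs are included by
  default: they carry the in-row repulsion that makes the alternating
  (checkerboard) occupancy the ground state; without them the minimizer
  is one fully occupied and one empty strand, which is not what the
  confined-ion system does.
- **Coupling scale.** ℓ_B is the Bjerrum length of the *fluctuating
  divalent ion*, ℓ_B(αe) = α²ℓ_B(e) — the same scale the Γ = ℓ_B/d
  coupling analysis uses for confined Mg²⁺ pairs. With the monovalent
  scale the N = 4 lattice at these geometries never leaves the
  weak-coupling regime and the bilayer free energy sits several k_BT
  above its ground state, contradicting the ordered, ground-state-like
  behavior the membrane system exhibits. `coupling_valence=1` recovers
  the bare site-charge convention exactly (the unit tests use it).
- **Mean-field rod term.** U_rod = 2ℓ_B(e)λ²LK₀(κx), the standard
  Debye–Hückel result for parallel line charges of density
  λ = ν_eff(x)/L. It is configuration independent, non-negative, and
  factors out of the partition sum exactly.
- **Grand-canonical weighting** with chemical potential μ per bound ion;
  μ = 0 (equal a priori occupancy) by default, exposed as a parameter.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| b (site spacing) | 1.75 | nm | interface phosphate spacing of the simulated duplexes |
| L (duplex length) | 6.8 | nm | 20 bp × 0.34 nm |
| N (sites/strand) | 4 | — | round(L/b) |
| α (counterion valence) | 2 | — | Mg²⁺ |
| ε_r | 40.1 / 92.2 | — | computed permittivities of the membrane-confined and in-solution systems, consumed as constants |
| T | 300 | K | standard bilayer-simulation temperature; exposed |
| κ_model (lipid) | 0.1 | nm⁻¹ | the lamellar interstitial gap is salt depleted (very little Cl⁻ between the strands), so the confined-ion couplings are nearly unscreened |
| κ_model (solution) | bulk κ ≈ 1.17 | nm⁻¹ | in solution the gap holds bulk electrolyte; correlations are screened like everything else |
| κ (rod term) | bulk κ from 50 mM MgCl₂ at the preset ε_r | nm⁻¹ | Debye screening of the mean-field repulsion |
| ν_eff (lipid) | −1e at 4.0 nm, +0.17e at 3.0 nm, linear | e | free-state effective charge and half the near-neutral condensed-state shell charge per duplex; linear in x between/beyond anchors |
| ν_eff (solution) | −3.5e constant | e | free-state value; no condensed anchor exists, so it is held constant |
| μ | 0 | k_BT | no independent constraint on the binding chemical potential |
| depth threshold | 0.5 | k_BT | an attraction shallower than thermal noise is not a condensate |
| spacing grid | 2.0–6.0, 41 pts | nm | from duplex contact (~2 nm diameter) to the far field |

With these defaults the lipid preset yields an attractive profile
(−1.23 k_BT at the contact edge of the grid, E_ground − F ≈ 0.88 k_BT at
the minimum, alternating ground state) and the solution preset a
monotonically repulsive one — the qualitative contrast between the two
environments.

**Classification.** A profile is *attractive* when its minimum over the
grid (excluding the large-x gauge point) lies more than the depth
threshold below the gauge. The lattice model has no hard-core or
hydration term, so nothing stops the correlation attraction from growing
down to duplex contact; the minimum of an attractive profile therefore
sits at the short-spacing edge of the physical domain rather than
strictly inside it, and the classification is by depth, not by interior
curvature.

## Electrolyte quantities

SI forms throughout: ℓ_B(q) = q²e²/(4πε₀ε_r k_BT) (the Gaussian-units
q²/ε_r k_BT of the electrolyte literature), κ⁻¹ = (8πℓ_B(e)N_A I)^(−1/2)
with I = ½Σc_i z_i² converted to a number density, Γ = ℓ_B(q₁q₂)/d with
|q₁q₂| so unlike pairs report a positive coupling strength. For 50 mM
MgCl₂ in water at 298 K, I = 0.15 M and κ⁻¹ = 0.79 nm ≈ 8 Å. The Γ
values for confined Mg–Mg pairs use d equal to the condensed-state
interhelical separations (2.97 nm simulated, 2.89 nm measured); the
sources do not state which "average ion separation" produced the printed
couplings, and these are the separations that reproduce them — a
reconstruction, recorded as such.

## Synthetic configurations

The generator emulates the *structure* of the simulated system, not its
physics: two idealized B-DNA phosphate helices (rise 0.34 nm, twist 36°,
track radius 0.94 nm, 5′ termini unphosphorylated so two 20-bp duplexes
carry exactly −76e), two planar head-group surfaces (φ_DOPC = 0.6;
DOPC → paired PC_N⁺/PC_OP⁻ sites, DOTAP → TAP_N⁺), hexahydrated Mg²⁺ as
single +2e particles with a 0.45 nm contact distance, and Cl⁻ counts
fixed by exact electroneutrality. Ion placement modes: `uniform`,
`metropolis` (single-particle moves in the screened field of the fixed
charges; mobile–mobile interactions neglected, so it is an enrichment
device, not an equilibrium sampler), and `lattice_sampler` (one
occupancy configuration drawn from the exact Boltzmann distribution of
the lattice model, Mg placed on the occupied interface sites). The
lamellar stack is a 1-D repeat of two head-group planes (42 Å apart) and
one DNA plane midway through the remaining 25 Å, giving the 67 Å repeat
by construction; the 42/25 split is arbitrary within the fixed sum and
configurable.

What passing tests on these frames do **not** show: convergence of any
ensemble average, realistic ion–ion structure, lipid disorder, or the
MD-derived census numbers (shell charges of −1.78e/−6.60e, 0.46 Mg/bp,
21–24 direct contacts). The frames contain few, deliberately simple
particles; the tests demonstrate that the observables are computed
correctly (closure identities, brute-force recounts), not that the
synthetic ensemble resembles the simulated one.

## Numerical choices

- Enumeration is vectorized over all per-strand occupancy vectors and
  capped at 24 total sites (2²⁴ states); beyond that the banded transfer
  matrix over column states (σ₁ᵢ, σ₂ᵢ) must be used. Under a shared
  site-offset cutoff the two routes agree to < 10⁻¹⁰ k_BT.
- Partition sums use `logsumexp`; no exponential overflow at any tested
  coupling.
- Ground-state ties break lexicographically on the concatenated
  occupancy vector (the enumeration order), and the global spin-flip
  degeneracy means the reported pattern is one of a symmetric pair.
- Minimum-image distances on orthorhombic boxes only, via periodic
  k-d trees; an O(N²) loop oracle backs every census in the tests.
- Scattering peaks: local maxima must have prominence ≥ 10% of the
  profile maximum — a finite stack of N repeats carries interference
  side lobes of ≈ 5% of the Bragg peak (first sinc² lobe), which must
  not be read as first-order peaks — followed by parabolic refinement
  over the three bracketing samples.
- Slab concentration profiles fold the final partial slab into the last
  bin so the count-closure identity Σc·V·N_A = N holds exactly;
  `accessible` mode subtracts spherical-cap solute volumes per slab.
- Degenerate inputs raise rather than return sentinels: zero ionic
  strength (infinite screening length), zero charge Bjerrum length,
  empty shells/cores, grids shorter than three points, r_max beyond
  minimum-image validity.

## Problem sizes

Everything is desk scale by design: 256-state enumerations on 41-point
grids, frames of ~500 particles, 10⁵-draw sampler checks, 864-particle
scattering stacks on 300-point q grids. The full test suite runs in
well under a minute; `scripts/acceptance.py` in seconds.

## Known limitations

- Absolute free-energy depths are not comparable to the simulated
  landscape (the model is electrostatics-only; the sources report only
  modest quantitative agreement themselves).
- ν_eff(x) is linear through two printed anchors; its slope for the
  solution system is unknown and taken as zero.
- The correlation-term screening κ_model inside the lamellar gap is a
  physical judgement (salt-depleted ⇒ weak), not a fitted constant.
- The Metropolis mode ignores mobile–mobile interactions and is not a
  converged sampler.
- PDB round trips lose precision to the format's fixed decimal places;
  extended-XYZ is the lossless interchange format.
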