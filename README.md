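# lipodna

Statistical-thermodynamics modelling and synthetic-configuration analysis of
**DNA–DNA attraction inside cationic lipid bilayers**.

Genomic DNA duplexes are strongly anionic and repel each other in solution,
yet when confined between DOPC/DOTAP bilayers in ~50 mM MgCl₂ they condense
into ordered lamellar lipoplex phases. `lipodna` implements the core model
that explains this like-charge attraction — divalent counterions hopping
("ping-ponging") between the phosphate groups of two apposed duplexes create
correlated charge fluctuations whose electrostatic energy wins over the
screened mean-field repulsion — together with the supporting electrolyte,
trajectory-observable and scattering analyses, exercised entirely on
synthetic point-charge configurations. It is aimed at people studying
polyelectrolyte condensation, lipoplex assembly, or counterion-correlation
physics who want a small, fully testable desk-scale implementation.

## The model

Two parallel duplexes of length *L* are reduced to two rows of
*N* ≈ *L*/*b* interface phosphate sites at spacing *b*, a distance *x*
apart. Each site carries an occupancy σ ∈ {0, 1}; with counterion valence
α = 2 the site charge is σα − 1 ∈ {−1, +1} (in units of *e*). The
correlation energy of a configuration is the screened Coulomb sum

$$U_{\mathrm{corr}}(\sigma, x) = \sum_{\text{site pairs}} c_i c_j\,
\ell_B \frac{e^{-\kappa_m r_{ij}}}{r_{ij}},\qquad
r_{ij} = \sqrt{x^2 + b^2 (i-j)^2},$$

with the coupling scale ℓ_B the Bjerrum length of the fluctuating divalent
ion, ℓ_B(αe) = α²e²/(4πε₀ε_r k_BT). The configuration-independent
mean-field repulsion of the two partially neutralized rods is the
Debye–Hückel parallel-line-charge result

$$U_{\mathrm{rod}}(x) = 2 \ell_B(e)\, \lambda^2 L\, K_0(\kappa x),
\qquad \lambda = \nu_{\mathrm{eff}}(x)/L,$$

and the grand-canonical free energy over all 2^(2N) occupancy
configurations,

$$F(x) = U_{\mathrm{rod}}(x) - \ln \sum_{\sigma}
e^{-U_{\mathrm{corr}}(\sigma,x) + \mu n_\sigma},$$

is evaluated **exactly** (enumeration, or an equivalent banded transfer
matrix for larger N). Two presets encode the two environments studied:
`lipid` (ε_r = 40.1, salt-depleted interstitial gap, ν_eff interpolating
−1e → +0.17e between the free and condensed states) and `solution`
(ε_r = 92.2, bulk 50 mM MgCl₂ screening, ν_eff = −3.5e).

Supporting modules: `electrolyte` (ionic strength, Bjerrum/Debye lengths,
coupling parameter Γ = ℓ_B/d), `traj_analysis` (concentration profiles,
solvation-shell charge decomposition, coordination/contact/bridge censuses,
RDFs on labeled point-charge frames), `scattering` (axis-scan and Debye
powder intensities, Bragg-peak periodicity), `synthetic` (idealized B-DNA
phosphate lattices, DOPC/DOTAP head-group planes, electroneutral ion
placement, lamellar density stacks) and `io`/`cli` (extended-XYZ and PDB
frames, CSV/JSON writers, a `lipodna` command-line tool).

## Worked example

```python
import lipodna.fluctuation_model as fm

for name in ("lipid", "solution"):
    lattice, rods = fm.preset(name)
    prof = fm.free_energy_profile(fm.default_spacing_grid(), lattice, rods)
    print(name, prof.classification, round(prof.minimum_depth, 2), "kT")
```

prints

```
lipid attractive -1.23 kT
solution repulsive 0.0 kT
```

i.e. between bilayers the fluctuation attraction pulls the profile
1.23 k_BT below its large-separation value (and within ~0.9 k_BT of the
lattice ground state, whose occupancies alternate across the two strands in
a checkerboard), while in solution the profile only rises as the duplexes
approach — the experimentally observed contrast. The numbered scripts under
`analysis/` run the full story (electrolyte context, free-energy profiles,
frame censuses, scattering periodicity) and write their tables under
`results/`:

```sh
python analysis/01_electrolyte_conditions.py
python analysis/02_free_energy_profiles.py
python analysis/03_synthetic_frame_observables.py
python analysis/04_scattering_periodicity.py
```

For instance, `04_scattering_periodicity.py` reports the first Bragg peak
of the default synthetic bilayer/DNA stack at q = 0.0946 Å⁻¹, a real-space
repeat of 66.4 Å against the constructed 67 Å.

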