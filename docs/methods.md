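# Methods

This package implements a desk-scale empirical valence bond (EVB) study of
the hydride-transfer (dehydrogenase) step of MTHFD2 together with the
supporting procedures around it: construction and coordination analysis of
the two-Mg²⁺ active-site model, grand-canonical water flooding of the
active-site cavity, simplified linear-response (LRA) binding electrostatics,
protonation-state Monte Carlo, and closed-form transition-state-theory and
pH energetics. Everything runs on a reduced synthetic model of the active
site so that the full pipeline executes in minutes on one CPU with no
external downloads.

## The EVB model

The reacting system is described by diabatic (valence-bond) states. For the
dehydrogenase step three resonance structures are carried: reactant
(5,10-CH₂-THF + NAD⁺), the hydride-transferred intermediate (5,10-CH⁺-THF +
NADH, charge freshly moved), and a relaxed product state. Each state `i` has
a classical energy

ε_i = Σ bonds (Morse for the reacting C–H, harmonic for framework)
    + angles + torsions + LJ + Coulomb(state-i charges) + α_i

with the gas-phase shift α_i the only adjustable asymptotic offset. The
Morse convention is E(r₀) = −D_e, E(∞) = 0, so bond cleavage appears
explicitly in the diabatic gap. The ground surface is the lowest eigenvalue
of the state Hamiltonian with constant off-diagonal coupling A (a
distance-dependent A·e^(−μr) form is parsed but off by default: the paper
trail for this system constrains only the calibration targets, so the
fewest-parameter form is used). The reaction coordinate is the energy gap
Δε = ε_reactant − ε_product; the diabatic crossing Δε = 0 is the transition
seam.

Units everywhere: kcal/mol, Å, fs, amu, K, elementary charges; the Coulomb
constant is 332.0636 kcal·Å/mol/e². Direct pairwise Coulomb with no cutoff
(droplets are small). Exclusions: 1-2 and 1-3 excluded, 1-4 scaled by 0.5;
the exclusion graph is the union of all states' bonding patterns so the
pair list is state-independent.

## Sampling and the free-energy protocol

Dynamics are BAOAB-discretized Langevin at 300 K with a 1 fs step on the
mapping potential ε_λ = Σλᵢεᵢ. Free energies come from the standard
FEP/umbrella-sampling combination: 55 uniformly spaced mapping windows drag
the system from reactant to product; window free energies are exponential
averages between adjacent mapping potentials (forward and reverse both
computed, their mean used); the ground-surface profile Δg(Δε) is assembled
by reweighting each window onto gap bins with exp(−β(E_g − ε_λ)). ΔG‡ is
the profile maximum between the basins, ΔG_rxn the product-minimum offset.
Each gap bin takes its value from the window holding the most frames in
that bin (the standard curve-joining construction): averaging across
windows lets rare excursions from distant windows, whose reweighting
factors are enormous, poison individual bins. Bins whose best window holds
only a handful of frames are dropped.

Desk-scale protocol choices (one CPU, minutes): 3,000 steps per window with
the first half discarded as window equilibration, samples every 5 steps,
thermostat friction 10 ps⁻¹. The friction is deliberately strong: the ionic
cluster carries stiff local modes whose integration error at 1 fs
accumulates as kinetic heating under weak coupling; at 10 ps⁻¹ the measured
kinetic temperature of every variant is within ~1% of the target
(equipartition is asserted in the tests). Hydrogen masses are repartitioned
to 3 amu for the same stability reason; equilibrium (configurational)
averages, and therefore all free energies, are mass-independent. Window
seeds derive from the master seed and window index through a counter-based
(Philox) generator, so results are independent of execution order and
bitwise reproducible.

The droplet boundary is deliberately simple: mobile atoms inside an 8.5 Å
sphere, a harmonic radial wall (k = 10 kcal/mol/Å²) pulling strays back,
atoms beyond a far radius frozen. This replaces the surface-constrained
solvent, Langevin-dipole layer and bulk continuum of full-scale EVB
packages; it is a physics simplification, not an approximation of them, and
is the main reason absolute energies of the reduced model are meaningful
only after calibration.

## Calibration

A two-state leg has two free parameters: Δα (moves ΔG_rxn one-for-one) and
A (depresses the barrier below the diabatic crossing). `calibrate` runs the
full mapping protocol on the *reference* system — the same reacting
fragments in a pure water droplet — and iterates a damped Newton step with
the parabolic-limit Jacobian (∂ΔG_rxn/∂Δα = 1, ∂ΔG‡/∂Δα = ½, ∂ΔG‡/∂A = −1)
until the reference reproduces its targets, by default within 0.15
kcal/mol. Window seeds are held fixed across iterations so the
parameter→observable map is deterministic. The calibrated (Δα, A) are then
frozen for every protein-model run; only the environment differs between
variants. The packaged reference targets play the role of the
quantum-chemical reference-reaction values; they are constants of the
shipped model, chosen once so that the calibrated site-B droplet reproduces
the published activation free energy of the single-metal enzyme model
through the full calibrate→freeze→sample→extract chain. That chain — not
the original full-protein physics — is what the acceptance run validates.

## The reduced active-site model

`make_active_site_fixture` builds a ~100-atom droplet: an inorganic
phosphate (P +1.0, 4×O −1.0) flanked along the ion axis by two Mg²⁺ sites;
each Mg is an exact octahedron at construction (two phosphate oxygens, a
carboxylate-analog oxygen, and shell waters; site A swaps one water for the
Arg-analog NH₂ nitrogen), with Mg–ligand distances near 2.05 Å. The solute
is a 13-atom two-fragment model of the reacting pair: an
imidazoline/pterin stub of the folate substrate and a pyridinium stub of
the nicotinamide cofactor, donor and acceptor carbons 3.1 Å apart and the
transferring hydride 1.1/2.1 Å from donor/acceptor — the optimized-reactant
geometry of the full system. State charges move one net charge from the
cofactor fragment (NAD⁺, reactant) to the substrate fragment (iminium
cation, product). Framework bonds/angles take their equilibrium values from
the as-built geometry, so the construction is its own minimum.

Environment heavy atoms and the metal-shell waters (including their
hydrogens) are positionally restrained at the standard pair-constraint
strength of 10 kcal/mol/Å², mirroring the constrained optimized-ion
configuration of the full-scale protocol; the donor–acceptor distance is
restrained to 3.1 Å with the same constant. Free waters (seeded, clash-free
placement; default 24 total) are unrestrained. The restrained shell is
load-bearing: if the shell waters may reorient freely, a single interposed
water screens a metal's field almost completely and variant differences
drown in hydrogen-bond-network multistability; with the structural shell
held, the ion differentials transmit and seed-to-seed scatter of the
barrier drops well below 1 kcal/mol.

Ion variants (`two_mg`, `mg_a`, `mg_b`, `no_mg`) differ only in which ions
are present; `reference` is the bare solute in water. The model reproduces
trends — barrier ordering across ion variants, phosphate-binding ordering,
the sign structure of the Arg↔Mg decomposition, phosphate drift — not the
absolute full-protein numbers, and the documentation and reports say so.

The fixture's `pocket_structure` adds an uncharged Lennard-Jones wall shell
(a complete Fibonacci sphere of 600 carbon-like sites, radius 6.7 Å around
the reactive midpoint) standing in for the protein matrix that encloses the
real active site. The shell deliberately overlaps the solute where the ion
cluster pokes through — wall sites interact only with flooding waters, and
any gap would let water leak between the shell and the hard MC boundary.
It is used only by cavity hydration: without walls the reduced model is an
open droplet and a 6 Å cavity would simply hold bulk water.

## Analytic oracle systems

Two toy systems with closed-form answers exercise the full machinery:

- the Marcus system — two displaced equal-curvature harmonic diabats
  (λ = ½k·d²) with constant coupling; diabatic barrier (λ+ΔG⁰)²/4λ,
  adiabatic barrier from a dense scan of the closed-form ground surface
  (λ/4 − H₁₂ for the symmetric case, up to the small coupling-induced well
  depression);
- the harmonic-pair system — two wells of different stiffness sharing a
  minimum, ΔA = (k_BT/2)·ln(k₂/k₁), cross-checked by quadrature.

Both are one mobile particle tethered to frozen anchors with off-axis
degrees of freedom frozen, so the 1-D closed forms are exact for the
sampled system. The FEP/US estimate must land within 0.3 kcal/mol of the
Marcus barrier and 0.02 kcal/mol of the harmonic ΔA. The toy protocols use
near-critically damped friction (γ ≈ 2ω, i.e. 12–20 ps⁻¹ here) rather than
the droplet default: a single harmonic degree of freedom is underdamped at
10 ps⁻¹ (coherent oscillation for ~1/γ) and overdamped far above 2ω
(diffusive slowdown, τ ≈ γ/ω²); either regime starves the windows of
independent samples.

## Water flooding

The cavity is over-saturated by random insertion (30% above the
probe-estimated accessible volume at bulk density) and then pruned and
equilibrated by grand-canonical Metropolis moves — insertion, deletion,
rigid translation, and small rotation — against a hard spherical wall (6.0
Å) that forbids exchange across the cavity boundary. Waters are 3-site
(−0.834/+0.417 charges), one LJ site on oxygen plus a small repulsive wall
on the hydrogens (as in the CHARMM water variant) that prevents bare-proton
collapse onto anionic oxygens. Water–water electrostatics are screened by
an effective dielectric of 2 (water–solute interactions are not): with bare
charges every retained water binds its neighbours by 5–12 kcal/mol, the
grand-canonical exchange acceptance collapses to ~e^(−10β), and the water
count freezes at the over-saturation value instead of responding to the
activity. The screened model keeps insertion/deletion ergodic, which is
what makes the activity a real control. z is the method's one free
parameter; it is calibrated once so a solute-free 6 Å cavity holds
bulk-density water (0.0334 Å⁻³ → ⟨N⟩ ≈ 30) and shipped as
`BULK_ACTIVITY = 0.0386 Å⁻³` (reproducible via `calibrate_activity`). The
headline observable is the mean occupancy of the 6 Å cavity centered midway
between the reactive carbons of the enclosed two-metal model.

## Simplified-LRA binding and the group decomposition

Binding electrostatics use the linear-response half-sum
ΔG ≈ ½(⟨ΔU⟩_charged + ⟨ΔU⟩_uncharged) over seeded configurations generated
with the ligand charges on and off (4 configurations × 2 ps by default).
Screening uses two dielectrics: ε_eff = 60 between formally charged groups
(|net| ≥ 0.5 e per residue) and ε_p = 4 otherwise. Explicit waters are
excluded from the environment sum — they are the continuum the dielectrics
represent, and counting them at ε_p would double-count solvent screening.
The Langevin-dipole grid of the full semi-macroscopic method is not
reproduced; every output is labeled "simplified-LRA" and compared only as
orderings and signs. The group decomposition is a screened-Coulomb
interaction at fixed coordinates with ε_eff throughout (it is defined for
charged-group pairs), exactly additive over partitions.

## Protonation Monte Carlo

Microstate energy Σᵢ 2.303·k_BT·sᵢ·(pH − pKaᵢ) + ½ΣΣ qᵢqⱼWᵢⱼ with single-site
Metropolis flips; intrinsic pKa defaults (Asp 3.9, Glu 4.2, His 6.5, Lys
10.5, Arg 12.5, Cys 8.3, Tyr 10.1) ship with the package. Exhaustive
enumeration (≤ 20 sites) is the oracle in the tests.

## Closed forms

Eyring: k = (k_B T/h)·e^(−ΔG‡/RT), exact inverse round trip. Hydroxide
formation: ΔG = k_B T·ln 10·(15.7 − pH), "room temperature" taken as
298.15 K (the kinetics scans 298–300 K because the dynamic protocol is
defined at 300 K).

## Numerical choices and edge cases

- Degenerate eigenvector weights at exactly zero coupling fall back to the
  argmin state; couplings below ~1e-9 are numerically degenerate too.
- The gap profile uses 1–2 kcal/mol bins; smoothing is never applied before
  barrier extraction. Reactant/product basins are split at Δε = 0 (the
  crossing seam); a profile without samples on both sides raises rather
  than extrapolates.
- Exponential averages are computed with max-shifted logs; overlap is
  diagnosed by effective sample size and attached as a warning, not an
  error.
- Bootstrap errors use block resampling (block ≈ n/10) to respect
  autocorrelation.
- The divergence guard aborts integration when |E| exceeds 10⁶ kcal/mol and
  reports the step.

## Known limitations

- The reduced model's absolute electrostatics depend on the restrained
  geometry; only the calibrated site-B barrier is quantitative, and only by
  construction. Variant differences are qualitative orderings.
- Water screening in a ~24-water droplet is neither bulk-like nor
  protein-like; the two-dielectric LRA numbers are order-of-magnitude.
- The flexible 3-site water with hydrogen-mass repartitioning reproduces
  neither the dielectric constant nor the diffusion of real water; it is a
  minimal polar solvent.
- The proton-relay chemistry of the second (cyclohydrolase) activity is
  described only by the closed-form hydroxide energetics; no reactive
  topology for ring hydration is shipped.
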