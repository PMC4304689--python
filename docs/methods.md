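# Methods

## The model

A detergent-solubilised membrane protein carries a self-assembled belt
("corona") of detergent around its hydrophobic transmembrane surface.
`coronafit` models the protein–detergent complex as

* the all-atom protein structure, oriented with its transmembrane axis
  along z and the membrane mid-plane at z = 0;
* a hydrophobic **tail region**: an elliptical hollow torus of height
  `a` — a circular tube of radius a/2 swept along an in-plane ellipse of
  mean radius `b` with semi-axes `b·e` and `b/e`, optionally rotated by
  `phi` in the membrane plane;
* a hydrophilic **head region**: a shell of constant thickness `t`
  wrapped around the tail tube.

The tube cross-section is circular with radius a/2 and centred on the
elliptical path at radius b.  This is the minimal shape that gives the
torus a height of `a` and a mean outer radius R = b + a/2.  Points are
classified with the elliptical radial coordinate
u = b·sqrt((x′/(b·e))² + (y′/(b/e))²) (x′, y′ = coordinates rotated by
−phi): tail if (u − b)² + z² ≤ (a/2)², head if additionally within
(a/2 + t)².  `u` is exact at e = 1 and deviates from true Euclidean
distance to the ellipse only at O((e−1)²), adequate for the
near-circular coronas of interest (e ≈ 1.1).

### Two-density pseudo-atom lattices

Each region is filled with one pseudo-atom type on a simple cubic
lattice.  Given a pseudo-atom with n_e electrons and excluded volume
V_vdW, a buffer density ρ₀, and a target region density ρ, the
elementary cell volume

    V_cell = (n_e − ρ₀·V_vdW) / (ρ − ρ₀),     spacing s = V_cell^{1/3}

makes one bead per cell reproduce the region's contrast exactly in the
continuum limit.  Defaults: CH₃ beads (n_e = 9, V_vdW = 32.0 ų) for
the tails at ρ_tails = 0.28 e⁻ Å⁻³ (s ≈ 3.15 Å) and NH₃ beads (n_e =
10, V_vdW = 18.2 ų) for the heads at ρ_heads = 0.52 e⁻ Å⁻³ (s ≈ 2.76
Å), against ρ₀ = 0.334 e⁻ Å⁻³ (pure water).  Both lattices are
axis-aligned with a node at the origin; the ellipse is rotated by phi
rather than the lattice, so bead sets stay nested across phi scans and
the corona is exactly mirror-symmetric in z.

A bead is removed when any protein heavy-atom centre lies within
1.8 Å + s/2 of it.  This prevents double-counting of electron density
at the protein surface; the cutoff scales with the lattice spacing so
that roughly one cell of clearance is kept per region.

Bead counts convert to detergent-molecule numbers through molecular
volumes: N_region = n_beads · V_cell / V_mol.  Defaults for DDM:
V_mol(tail) = 350.2 ų for the C₁₂ chain (Tanford's 27.4 + 26.9·n
relation) and V_mol(head) = 359 ų for the maltoside head (DDM partial
specific volume minus the tail).

## Scattering engine

The orientationally averaged intensity is the Debye double sum

    I(q) = Σ_i Σ_j f_i(q) f_j(q) sin(q r_ij)/(q r_ij).

Effective amplitudes include the displaced solvent.  With the
Gaussian-sphere damping g_V(q) = exp(−q² V^{2/3} / 4π):

* protein atomic groups: f(q) = f_grp(q) − α·ρ₀·V_vdW·g_V(q), where
  f_grp is the tabulated (Cromer–Mann) heavy-atom form factor with the
  bonded hydrogens folded in;
* corona pseudo-atoms: f(q) = (n_e − α·ρ₀·V_vdW)·g_V(q).  A pseudo-atom
  stands for a uniform-density cell, so its *net* contrast is damped;
  leaving a constant point term n_e would make each bead's contrast
  cross zero and recover full atomic scattering at high q, which has no
  physical counterpart in a coarse-grained region;
* hydration dummy waters: f(q) = δρ_hyd·30·g₃₀(q).

α is a global excluded-volume factor close to 1; through the cell
relation it also shifts the effective region densities,
ρ′ = ρ₀ + (n_e − α·ρ₀·V_vdW)/V_cell, which are reported with every fit.

The double sum is evaluated through pair-distance histograms (default
bin 0.1 Å, distances snapped to bin centres) resolved per species pair,
so the q-dependent amplitudes factor out of the O(N²) distance work:
I(q) = Σ_a N_a f_a² + Σ_{ab} f_a f_b Σ_r H_ab(r)·sinc(qr).  Changing α
or δρ_hyd therefore costs O(n_species²·n_q), which makes the inner
contrast search essentially free, and the protein–protein histogram is
computed once per grid scan and reused at every grid point.

### Hydration layer

Dummy waters (volume 30 ų) are laid on a 3 Å grid over the solvent
region within 3 Å (default) of the complex envelope.  The envelope is
found by voxelising the particles at half the bead grid, closing
single-voxel pores, filling interior voids, and taking the Euclidean
distance transform of the solvent region — so beads cover only
solvent-exposed surface and internal cavities stay empty.  δρ_hyd = 0
leaves the curve exactly unchanged.

### Scoring

Model curves are evaluated directly on the experimental Q grid (no
resampling).  The agreement factor is the reduced, error-weighted
root-mean-square discrepancy after optimal scaling:

    c = argmin Σ((I_exp − c·I_calc)/σ)²  (closed form),
    χ = sqrt( Σ((I_exp − c·I_calc)/σ)² / (N − 1) ).

The denominator is N − 1, with no additional deduction for the fitted
c, α, δρ_hyd; users comparing against other engines should account for
this convention.  For optional cross-checks with spherical-harmonics
engines, the recommended order is L = ceil(5 + Q_max·D_max/2), capped
at 99.

## Grid fitting

The corona parameter space (a, b, t, e, phi) is scanned exhaustively on
a user grid.  At every grid point the corona is built, the curve
computed, and χ minimised over small inner grids of the two contrast
parameters (defaults α ∈ [0.95, 1.05] step 0.01, δρ_hyd ∈ [0, 0.05]
step 0.01 e⁻ Å⁻³).  Results are ranked by χ with ties broken by
smaller bead count and then parameter order, making ranked tables
byte-reproducible.  Coarse-to-fine refinement is available as a
convenience but plain exhaustive scanning is the default, since cost is
linear in the number of grid points.

`density_scan` repeats the scan over a list of (ρ_heads, ρ_tails)
pairs and summarises, for each pair, all models with χ within +5%
(configurable) of that pair's minimum: means and standard deviations of
the geometry, α, ρ′ and the detergent counts, plus a self-consistency
flag marking head/tail count agreement within 10% — a quantitative
stand-in for the qualitative "counts from the hydrophilic and
hydrophobic volumes agree" criterion.

## Synthetic data

`make_toy_protein` builds a lattice-filled cylinder of carbon-like
beads (defaults: radius 15 Å, height 30 Å, spacing 3 Å, n_e = 7,
V_vdW = 20 ų), sized so the best-fit corona scales (a ≈ 30, b ≈ 25 Å)
resemble a real protein–detergent complex while keeping particle counts
below 10⁴.  `make_tetramer_standin` is a larger, explicitly synthetic
surrogate of an aquaporin-like tetramer (rounded-square transmembrane
prism ~54 Å wide and 34 Å tall with narrower extramembrane caps, bead
spacing 2.5 Å ≈ protein heavy-atom packing); it reproduces the regime
in which the protein fills the torus hole, which controls the a–b
count degeneracy and the detergent counts of real complexes.

`simulate_experiment` adds independent Gaussian noise per point,
σ_i = max(relative_sd·I_i, floor), with a recorded seed — the standard
SEC–SAXS error-propagation assumption.  It does **not** simulate free-
micelle background, inter-particle structure factors, beam smearing or
frame-to-frame drift; passing recovery tests on these fixtures
therefore demonstrates correctness of the engine and search, not
robustness to the systematic errors of real measurements.

### Problem sizes used in the validation suite

The shipped studies use the toy cylinder with a 5⁴-point grid
(a: 26–34 step 2, b: 23–27 step 1, t: 3–7 step 1, e: 1.0–1.2 step
0.05) at 1% noise, and a fine (a, b) slice (a: 29–31 step 1, b:
33.5–36.5 step 0.5) around the optimum at tetramer scale for the
correlation study.  These sizes keep a full validation run in the
minutes range on one CPU; larger grids scale linearly.

## Numerical choices and edge cases

* Histogram bin 0.1 Å keeps the histogram path within 0.5% of the
  exact double sum for typical systems; q = 0 uses the sinc limit 1.
* Auto-alignment uses the covariance (inertia) eigenvector whose
  eigenvalue is most separated from the other two; if the separation is
  below 5% of the spread the orientation is ambiguous and the two-point
  axis mode is required.  The transmembrane mid-plane defaults to the
  centroid of all atoms projected on the axis, with an optional residue
  selection and a z-offset for manual fine-tuning.
* Alternate locations resolve to the highest-occupancy conformer.
* Corona models fully swallowed by the clash region yield an empty,
  warning-carrying model rather than an error; grid scans skip such
  points and fail only if every point is empty.
* PDB output uses hybrid-36 serials beyond 99,999 records, so large
  bead models round-trip without truncation.
* An empty head shell (t = 0) and protein-free coronas are valid.

## Known limitations

* The corona cross-section is circular and single-curvature; nanodiscs,
  bicelles, amphipols and per-leaflet asymmetry are out of scope.
* The elliptical coordinate u is approximate for strongly elliptical
  coronas (e far from 1).
* Electron densities are uniform per region; no curvature-dependent
  head packing.
* The hydration layer is a uniform-contrast dummy-bead shell; engines
  with angularly-resolved hydration models will differ quantitatively.
* D_max and the transmembrane orientation are user responsibilities;
  the package refines neither.
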