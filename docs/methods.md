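# Methods

This note documents the models, parameter choices and numerical conventions
behind `confspec`, and what the synthetic validation does and does not
demonstrate.

## Synthetic conformer ensembles

The generator emulates the three data sources of an ensemble IR study —
an equilibrium trajectory with per-frame energies, per-conformer harmonic
stick spectra, and a reference spectrum — with fully known ground truth.

**Geometry.** A fixed 18-atom internal-coordinate template (a
glycyl-glycine-like fragment: an NH₃⁺-type terminal amine, one amide N–H,
a carbonyl and a carboxyl group) with four free backbone torsions.  Frames
are drawn by (i) sampling a basin with probability equal to its population,
(ii) sampling torsions from von Mises distributions about the basin means
(default concentration κ = 80, circular sd ≈ 6.4°), and (iii) rebuilding
Cartesian coordinates by standard internal-to-Cartesian (NeRF) placement.
Hydrogen-bond geometry is imposed explicitly: "probe" acceptor oxygens are
placed along the N–H axes of the terminal amine at distances drawn from
N(d_basin, 0.05 Å); probes beyond the basin's engaged-acceptor count are
parked at 8 Å so that every frame shares one chemical composition.  Frames
with any interatomic distance below 0.5 Å are resampled (bounded retries).

**Energies.** E = basin offset + ½k Σ Δφ² + |N(0, σ_E)| with k = 5
kcal/mol/rad² and σ_E = 0.5 kcal/mol.  The noise is half-normal rather than
normal: one exact basin-mean frame (energy = offset, zero penalty and
noise) is appended per basin, and non-negative noise makes it almost surely
the *strict* minimum of its basin, so representative-conformer recovery is
exactly checkable.

**Spectra.** Each basin has stick lines (position, intensity, shift slope);
line positions shift by slope × (d − 2.9 Å) with the H-bond distance,
mimicking the red shift of X–H stretches under stronger hydrogen bonding.
The reference spectrum is the population-weighted sum of the broadened
basin spectra, optionally with additive Gaussian noise, clipped at zero.
Per-frame spectra use the frame's actual mean engaged-probe distance, so
spectra vary within a basin.

**Default study conditions** (`default_basins`): three basins with
populations 0.6/0.3/0.1, torsion means separated by ≥ 90° in several
torsions, H-bond distances 2.85/2.95/3.05 Å, engaged acceptor counts
1/2/1, and four stick peaks each (amide-fingerprint and stretch regions).
The standard sample size is 3000 frames — large enough for stable kernel
density estimation in the 2-D conformer map, small enough for desk-scale
runs.

**What this does not emulate:** real force-field energetics, anharmonic
couplings and Fermi resonances, conformational kinetics, solvent, and
IRMPD multiple-photon effects.  Passing tests demonstrate that the
analysis machinery recovers known populations, geometries and spectra from
data with realistic statistical structure — not that any particular force
field or spectroscopy model is accurate.

## Descriptors

The SOAP power spectrum is computed natively.  For each atomic environment
the Gaussian-smeared neighbour density (σ = 0.4 Å) is expanded in an
orthonormalised polynomial radial basis (rcut − r)^(n+2), n ≤ n_max = 6,
times spherical harmonics up to l_max = 4, within rcut = 5 Å.  The angular
part of each coefficient is analytic (exponentially scaled modified
spherical Bessel functions); the radial integral is evaluated by 100-point
Gauss–Legendre quadrature, by default through a 4096-point interpolation
table in neighbour distance (exact per-pair quadrature is available and is
what the test-suite oracle checks against; table error < 1e-7).  The
central atom is excluded from its own neighbour density.  Per-frame
("average") descriptors are arithmetic means over all atomic environments,
L2-normalised by default.  Clustering operates on the first two principal
components of the descriptor matrix; on the synthetic conditions these
carry ≈ 90% of the variance and separate the basins with AUC ≈ 1.

## Clustering

PAMM-style density-based clustering:

- **Grid:** farthest point sampling of min(1000, n) landmarks; each frame
  belongs to its nearest landmark (Voronoi weight = occupancy fraction).
- **Density:** a balloon kernel estimate over all frames evaluated at each
  landmark, with a per-landmark bandwidth from Silverman's rule applied to
  the covariance of the nearest fraction `f_points` of samples (floored at
  d+1).  The probability-mass view (`grid_prob_`, Voronoi-weighted and
  normalised to 1) is kept alongside the continuous density.
- **Bandwidth fraction:** the probe fraction must scale with sample size.
  At the synthetic scale (n ≈ 3·10³ in 2-D) the pipeline default is
  `f_points = 1.0` (global Silverman); small fractions such as 0.008 are
  refinement probes appropriate for trajectories orders of magnitude
  larger, and remain the estimator-class default for that use.
- **Quick-shift:** each landmark links to its nearest landmark of strictly
  higher density within α·λ (α = 0.9, λ = local bandwidth); unlinked
  landmarks are modes, ties break to the lowest index.
- **Shallow-mode postmerge:** finite-sample KDE mode-seeking inevitably
  produces spurious shallow modes.  Adjacent clusters (sharing a Voronoi
  boundary or lying within each other's bandwidth) are fused when the
  saddle density between them exceeds `dip_threshold = 0.5` of the lower
  mode density — a deterministic stand-in for statistical mode-significance
  merging.  Clusters below `min_cluster_weight` of the frames (pipeline
  default 5%; estimator default 0 = off) are outlier islands and are
  dissolved into the nearest surviving cluster.
- **Weights and representatives:** w_c = n_c/n; the representative is the
  lowest-energy member frame (ties to the lowest index).
- **Hierarchy:** agglomerative Ward merging of cluster centroids in the
  projection space, restricted to grid-adjacent cluster pairs (with an
  unrestricted fallback if the adjacency graph disconnects).  Ward
  distance d(A,B) = sqrt(2 n_A n_B/(n_A+n_B)) ‖c_A − c_B‖; heights are
  clamped non-decreasing (dendrogram convention).  A merged node's
  representative is the lower-energy child representative.

## Hydrogen-bond statistics

Triplets are N–H⋯O with a covalent D–H cutoff of 1.3 Å and a d_DA
enumeration cutoff of 4.5 Å.  Acceptors fewer than 3 bonds from the donor
(bond graph inferred from distances: < 1.3 Å with H, < 1.8 Å heavy-heavy)
are excluded — 1-2/1-3 contacts are not hydrogen bonds.  O–H⋯O bonds are
excluded by default (donor species is configurable).

Membership is the posterior of the bonded component in a two-component
mixture: a diagonal Gaussian at (ν, μ, d_DA) = (−0.9, 2.9, 2.9) Å with sds
0.25 Å and prior 0.5, against a uniform background over
[−4,4]×[0,8]×[0,8] Å.  This replaces training a mixture on reference
trajectory data while preserving the 0–1 contract: ≈ 1 at the reference
geometry, → 0 as the acceptor leaves, monotone in d_DA beyond the minimum.

Counts: s_D(N) sums memberships of triplets donating from N; s_A(O) and
s_H(H) analogously.  Atoms with counts below a participation threshold
(default 0.1) are ignored in averages.  Per-frame s values are means over
participating atoms; per-cluster ⟨s⟩ ± sd are population statistics over
frames (frame-then-atom averaging; the alternative atom-pooling convention
would weight frames by their participating-atom count).

Surfaces: histograms with 0.05-wide bins on [0, 3], smoothed by convolving
with a triangular kernel of half-width 0.025 via exact bin-overlap
integrals (mass-conserving; note that at the default width the kernel is
narrower than a bin, so smoothing only matters for wider settings), then
normalised.  F = −k_B T ln P with k_B = 0.0019872 kcal/mol/K, masked where
P = 0; a min-shifted copy is provided for plotting.  Integer-cell
integration sums P over [i−½, i+½) cells and reports the argmax cell and
its percentage.

## Spectra and the Pendry factor

- Broadening: unit-area Gaussians, σ = FWHM/2.3548, default FWHM 10 cm⁻¹;
  the stick `scale_factor` (default 1.0 for synthetic data; required
  explicitly when ingesting real harmonic frequencies) multiplies line
  positions.
- Averaging: pointwise convex combination on a shared grid (no implicit
  resampling; mismatched grids are an error).  Averaging commutes with
  broadening by linearity.
- Hierarchical series: the level-L spectrum averages the merged clusters'
  representative spectra with their merged weights, from L = K down to the
  single root.
- Smoothing of noisy references: moving average (window in cm⁻¹, rounded
  to an odd point count) with reflective boundaries, rescaled to conserve
  total intensity.
- Pendry: Y = L/(1+v_oi²L²) with L = I′/I by central differences; where
  I < 1e-8 × max I, Y := 0.  v_oi defaults to 5 cm⁻¹ — half the broadening
  FWHM, i.e. the approximate half-width of the peaks.  R_P is evaluated on
  the common grid of the region (linear interpolation of the second
  spectrum; extrapolation refused), reported for 600–1800 cm⁻¹ and
  2700–3600 cm⁻¹.  Identities: R_P(S,S) = 0; disjoint Y-support gives
  exactly 1; R_P is symmetric and invariant to rescaling either spectrum;
  values up to 2 are possible for anti-correlated Y-functions.

## Pipeline

`run(config)` executes generate/load → descriptors → PCA → clustering →
weights/representatives → H-bond statistics → broadening → ensemble
average → hierarchical series → Pendry report → within-cluster
consistency, writing CSV/JSON/Newick/two-column-text artifacts.  The
configuration is a strictly validated YAML schema (unknown keys rejected);
all randomness flows from the single integer seed through one
`SeedSequence`, and repeated runs are byte-identical.  The clustering
stage is cached on disk keyed by a hash of the stages that affect it, so
spectra-only parameter changes reuse the clustering unchanged.  Plots are
not produced by the pipeline; every figure-ready quantity is emitted as
text.

## Problem sizes used in validation

Recovery checks run ten seeded ensembles of n = 3000 frames (three basins,
populations 0.6/0.3/0.1); spectrum-reconstruction checks use n = 1000; the
remaining unit and property tests use tens-to-hundreds of frames or small
constructed inputs with exhaustive oracles (≤ 50 landmarks/atoms).

## Known limitations

- The membership mixture is fixed, not trained; systems with materially
  different H-bond geometry need adjusted component parameters.
- The dip-threshold postmerge is a heuristic surrogate for statistical
  mode-significance testing; very unequal cluster densities near a common
  boundary can over- or under-merge.
- Ward heights after adjacency restriction are clamped monotone, so
  heights above an inversion are conventional rather than exact Ward
  costs.
- The descriptor implementation targets small molecules (dozens of atoms);
  no neighbour lists or sparsity are used.
- ⟨s⟩ averaging and histogram bin settings follow the conventions stated
  above; alternative conventions change third-decimal details of summary
  tables.
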