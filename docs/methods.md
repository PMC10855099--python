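# Methods

## The model

The desorption of atrazine from a hydrated Ca²⁺-montmorillonite surface is
reduced to one collective variable, ξ: the Cartesian-z distance between the
adsorbate's center of mass and the mean z of the basal oxygen atoms (Ob)
tagged as the adsorbing sheet. The free energy along ξ is the potential of
mean force W(ξ) = −k_BT ln g(ξ), with g the equilibrium distribution of ξ.
Because the system cannot cross the ~11.5 kcal/mol barrier spontaneously on
simulation time scales, sampling is done under harmonic umbrella biases
V(ξ) = ½kᵢ(ξ−ξᵢ)², one window per restraint center, and the unbiased
profile is recovered with the weighted histogram analysis method (WHAM).

All energies are kcal/mol, lengths Å, temperatures K;
k_B = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹, and the working temperature is 350 K
(k_BT = 0.6955 kcal/mol).

## The synthetic study conditions

The published trajectories are first-principles molecular dynamics and are
not reproducible at desk scale. The `synthetic` module therefore generates
data with the same statistical structure:

**Reference surface.** An analytic C¹ profile interpolates the five
printed singularities — P1 (3.41 Å, 0), M1 (3.88 Å, 1.5), P2 (4.24 Å, 0),
M2 (5.35 Å, 11.5), P3 (5.56 Å, 11.0 kcal/mol; set 0.5 below M2 from the
reported M2−P3 gap) — with cubic Hermite segments forced to zero slope at
every anchor. Zero anchor slopes make each segment monotone, so the surface
has no extrema other than the five prescribed ones. Below P1 the profile
rises as a repulsive wall (quadratic blending into a 20 kcal·mol⁻¹·Å⁻¹
line); above P3 it rises first quadratically with the curvature of the
M2→P3 segment (6·|ΔF|/h² ≈ 68 kcal·mol⁻¹·Å⁻²), then relaxes over 0.35 Å to
a straight line whose slope is solved so that F(8.920 Å) = 15 kcal/mol —
the free energy beyond the last minimum is not a measured quantity, and
this normalization is a model choice. Matching the initial tail curvature
to the adjacent anchor-determined well is deliberate: a much shallower
right side would let kernel smoothing displace the last minimum by
~0.06 Å, i.e. the generator would no longer carry its prescribed
singularity positions through the analysis chain.

**Window protocol.** The 19 umbrella windows (centers 3.583–8.920 Å,
k ∈ {14.3, 28.6, 57.1} kcal·mol⁻¹·Å⁻², durations summing to 209 ps) are
reproduced verbatim, including the three center-duplicated pairs, which are
treated as independent windows throughout.

**Sampler.** Per window, a Metropolis chain on ξ with stationary density
∝ exp(−[F_ref(ξ)+V(ξ)]/k_BT): symmetric uniform proposals of half-width
0.3 Å (of the order of the widest restraint's thermal width, a compromise
between acceptance and decorrelation), started at the window center, first
5 % of the run discarded as burn-in (mirroring the discarded equilibration
segments of the original protocol), 2×10⁵ retained samples per window, and
per-window seed = base seed + window index. F_ref is evaluated from a dense
table (1 mÅ spacing, linear interpolation; error ≲10⁻⁵ kcal/mol, far below
thermal noise). An overdamped-Langevin mode (Euler–Maruyama on the same
biased surface) is available for experiments needing strongly
autocorrelated series.

Consecutive Metropolis samples are correlated (integrated autocorrelation
≈1.5 steps at these settings). Distribution checks therefore thin the
chain 10× before applying the iid Kolmogorov–Smirnov calibration; on the
full chain D√n does not follow the Kolmogorov law and the iid critical
value would reject a perfectly correct sampler.

**Toy snapshots.** For descriptor tests, `toy_snapshot` builds a flat Ob
sheet at z = 0, a rigid planar adsorbate proxy carrying the named atoms
(N1, N3, Cl, Ce, Ci) tilted so the ghost-atom angle equals the prescribed
θ and translated so the center of mass sits at the prescribed ξ, a Ca1
bound at the monodentate contact distance (2.411 Å from N1), a remote Ca2,
and water oxygens placed inside/outside the 3.0/3.5 Å cutoffs so the
hydration-sphere sizes and the Atra∩Ca1 overlap match the prescription
exactly (Ca2's waters are disjoint by construction). Infeasible
prescriptions raise instead of silently degrading.

What the generator does **not** emulate: real water structure and dynamics,
hydrogen bonding, surface flexibility, correlated multidimensional motion,
finite-temperature fluctuations of the descriptors along a trajectory, and
any coupling between ξ and the other descriptors. Passing recovery tests
shows the reconstruction and analysis chain is correct, not that the
physical conclusions of a first-principles study would be reproduced.

## WHAM

Standard self-consistent equations, windows weighted by their actual
sample counts Nᵢ. Numerical choices:

- the recursion runs in log space (scipy `logsumexp`); the plain
  exponential form overflows over a ~15 kcal/mol range;
- the additive gauge is fixed by f₁ := 0 after every update — the
  equations determine the offsets only up to a common constant, and
  without an anchor the iteration drifts uniformly and the bin-energy
  residual never converges;
- initialization fᵢ = 0; by gauge invariance the converged profile is
  independent of it;
- convergence is declared when no defined bin's W changes by more than the
  tolerance (10⁻⁶ kcal/mol default) between consecutive iterations, the
  criterion quoted for the original analysis; the iteration count and
  final residual are logged and carried on the result;
- bins with zero aggregate counts are masked out, never an error; under
  the default conditions convergence takes ≈1300 iterations.

The pipeline (`run_pipeline`) additionally drops bins with fewer than 100
aggregate counts (configurable) before smoothing and detection: the free
energy of an essentially unvisited bin is sampling noise and can fake an
extremum in the sparse outer tail of the last window.

## Profile analysis

- **Smoothing**: Gaussian-kernel weighted average over defined bins,
  bandwidth σ = 0.05 Å (≈8 bins), renormalized over the defined mask so
  gaps do not bleed. Gaussian smoothing of an extremum with unequal
  flanking curvatures biases its position by ~σ²×(curvature asymmetry);
  with these anchors the largest such shift (M1) is ≈0.011 Å — below the
  ±0.05 Å recovery tolerance but up to two bin widths, which is why
  bit-level extremum positions should not be read off a smoothed curve.
- **Singularity detection**: interior sign-change extrema, plateaus
  resolved to the lowest-ξ bin, same-kind neighbours merged (keeping the
  stronger), then iterative pruning of any extremum whose free-energy
  contrast against both flanking opposite extrema (grid-end values serve
  as virtual flanks) is below the prominence threshold, 0.2 kcal/mol by
  default — 7× smaller than the smallest real barrier while safely above
  residual post-smoothing noise. Raising the prominence can only shrink
  the set. Labels P1/M1/P2/M2/P3 are assigned when exactly five
  alternating singularities are found.
- **Barriers**: smoothed barrier = F(max) − F(preceding min) on the
  smoothed curve; point-to-point barrier = max raw F within ±0.1 Å of the
  maximum minus min raw F within ±0.1 Å of the preceding minimum, on the
  unsmoothed WHAM curve. The point-to-point values exceed the smoothed
  ones by construction; how far depends on the scatter of the underlying
  data, so only the smoothed barriers are compared against reference
  values.
- **Zones and bands**: ξ zones are |ξ−c| ≤ 0.2 Å around c = 6.0, 7.0,
  8.0 Å. A singularity's membership band is the maximal contiguous
  interval where |F − F(singularity)| ≤ δF (default 0.5 kcal/mol, not
  derivable from the source material and therefore configurable). Note
  that bands of adjacent singularities can only be disjoint when δF is
  below half their free-energy gap; with the M2−P3 gap ≈0.4 the default
  bands necessarily overlap there.

## Descriptors

- θ = sign(z_N3 − z_Cl) × angle at the Cl vertex between Cl→X and Cl→N3,
  X = (x_N3, y_N3, z_Cl). If N3 is vertically aligned with Cl the angle is
  ±90° by the sign convention; coincident atoms are an error. θ is exactly
  antisymmetric under reflecting z_N3 about z_Cl.
- Hydration spheres: water oxygens within 3.0 Å of a cation, or within
  3.5 Å of any adsorbate heavy atom. The cation cutoff is the reported
  criterion; the adsorbate cutoff is not stated anywhere and 3.5 Å (a
  typical first-shell O…heavy-atom distance) is a configurable default
  flagged in reports. Hydrogens never enter distance criteria.
- Named distances: Ca1–N1, Ca1–Cl, Ca1–Ca2 are 3-D minimum-image
  distances (27-image search, exact below half the shortest cell height);
  the –surf quantities are signed z offsets from the instantaneous surface
  plane, recomputed per snapshot.
- "Normalized" distributions are unit-area densities (Σ density·Δ = 1),
  which keeps overlap coefficients well defined.
- Summary tables aggregate whatever record groups the caller supplies
  (zone or band membership); no reweighting of biased records is applied,
  and empty groups produce a warning row, not an error.

## Problem sizes and determinism

Default runs use 2×10⁵ retained samples per window (3.8×10⁶ total), 1000
bins, and converge end to end in a few seconds on one core; the test suite
runs one such full recovery and reuses it across checks. Every random
stream derives from an explicit seed, outputs are written with
full-precision decimal repr, and a fixed (config, seed) pair reproduces
every artifact byte-identically.

## Known limitations

- One-dimensional treatment only; no 2-D surfaces, error bars, MBAR or
  umbrella integration.
- The profile beyond P3 (tail slope, curvature relaxation) is a modelling
  choice normalized at F(8.920 Å) = 15 kcal/mol, not a measured shape;
  quantities that depend on it (e.g. zone free energies) are synthetic.
- The interlayer spacing δ ≈ 18 Å is reported-only; it cannot be derived
  from d001 without the layer thickness and is never computed.
- Adjacent-window overlap under the reference surface is genuinely small
  (≈0.3 %) for the pair straddling the steep rise below M2; the overlap
  diagnostic flags it, and WHAM still stitches the profile through the
  shared bins. With substantially fewer samples per window that pair is
  the first place reconstruction quality degrades.
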