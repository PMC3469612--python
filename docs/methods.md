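# Methods

## The inverse model

All reconstructions are posterior means of the Gaussian linear model
`v = G s + n`, `n ~ N(0, λC)`, `s ~ N(0, R)`:

    W = R Gᵀ (G R Gᵀ + λ C)⁻¹ .

`R` is kept at unit mean diagonal (for diagonal priors) and the
regularization strength is carried explicitly by λ multiplying `C`; this is
mathematically identical to folding the scale into `R` but keeps the
cross-validation axis well defined.  Reduced-basis solutions substitute
`G̃ = G Tᵀ` and map back with `Tᵀ`; the equivalence with the dipole-space
prior `Tᵀ R_b T` is exact and is asserted to 1e-10 in the tests.

### Bases

*Spherical harmonics.* Real orthonormal convention without the
Condon–Shortley phase, colatitude measured from each sphere map's +z pole.
Any fixed unitary variant spans the same subspace, so this choice affects
coefficient values, never reconstructions.  Default cutoff degree
`L_max = 10` → 121 functions per hemisphere, 242 coefficients per
orientation-constrained time sample.  The spatial-Nyquist helper returns
the smallest degree L with L² ≥ n_sensors (128 sensors → L = 12, 169
harmonics): the harmonic count (L+1)² then strictly exceeds the sensor
count, and a coarser cutoff would already be expressible by the net.

*Abel–Poisson splines.* `K_h(cos γ) = (1/4π)(1−h²)/(1+h²−2h cos γ)^{3/2}`,
the closed form of `Σ (2l+1) h^l P_l /4π`.  Centres are level-2 icosphere
nodes snapped to the nearest mesh vertices (162 per hemisphere), so basis
columns align with actual dipoles.  Default scale `h = 0.8`; smaller `h`
widens the splines the way smaller `L_max` smooths the harmonics.

*Spectral prior.* Harmonic rows of degree l receive prior variance
`(1+l)^(−2γ)`; `1+l` rather than `l` keeps the DC term usable.  γ defaults
to 0.75, the midpoint of the useful 0.5–1 range; larger values suppress
high spatial frequencies harder and are appropriate for noisier data.  For
splines the smoothing is carried by `h` and the basis prior is identity.

### Comparison algorithms

Depth weighting uses `w_j = (Σ_i g_ij²)^(−1)` (exponent configurable),
giving weaker — deeper — dipoles larger prior variance.  LORETA's prior is
`D^½ (LᵀL + ε)⁻¹ D^½` with `L` the cotangent-weight surface Laplacian of
the folded meshes and `D` the depth weights; the cotangent discretization
(not inverse-edge-length graph weights) is used because it is the standard
consistent Laplace–Beltrami operator — with barycentric mass normalization
it reproduces the degree-1 eigenvalue l(l+1)/r² on a sphere to 0.03%.  The
ε ridge (1e-8 × mean diagonal) absorbs the constant null space; the prior
is applied through a sparse factorization, never a dense inverse.  IBF
spans each hemisphere by the leading 512 eigenvectors of a Gaussian
coherence matrix `exp(−d²/2σ²)` over graph-geodesic distances (σ = 10 mm
default), eigenvalue-weighted and depth-weighted.  dSPM divides each row of
`W` by the noise SD propagated through it (`σ_j² = (W C Wᵀ)_jj`); sLORETA
divides by the square root of the resolution diagonal `(W G)_jj` (free
orientation: the 3×3 block trace — full block whitening adds complexity
with no effect on the magnitude maps used here).

### Significance

`q_j = s_j²/σ_j²` is compared against the χ² quantile at `1 − α/n_sensors`
with 1 (constrained) or 3 (free) degrees of freedom — the exact
large-denominator limit of the F statistic, Bonferroni-corrected over
sensors (α = 0.05 default).

## Regularization by OCV

The leave-one-sensor-out cost has the closed form
`Σ_i ((v_i − (Av)_i)/(1 − A_ii))²` with `A = G W`.  That identity holds for
independent observations, so the cost is evaluated on whitened data: the
whitened hat matrix `C^{-1/2} A C^{1/2}` is symmetric with eigenvalues in
[0, 1), which keeps the denominators positive and the cost curve unimodal.
With the package's spatially correlated noise covariance the literal
unwhitened form can reach `A_ii ≥ 1` and develops spurious local minima;
with `C ∝ I` the two forms coincide exactly (the brute-force refit oracle
in the tests verifies this case to 1e-8).  One eigendecomposition serves
the whole λ grid.  Default grid: 25 log-spaced points over `[1e-4, 1e2] ×
trace(G R Gᵀ)/trace(C)/n`, a scale-free anchor; multi-sample data pools
per-sample costs; a boundary minimum raises a warning.  In the benchmark λ
is selected once per algorithm from the pooled noisy draws of the first
configuration, mirroring per-recording selection in practice.

## Synthetic study conditions

The generator emulates an evoked-potential simulation study:

| quantity | default | rationale |
|---|---|---|
| cortex mesh | level-4 icosphere per hemisphere (2,562 dipoles) | level 5 (10,242) supported; level 4 keeps the bench desk-scale |
| hemisphere radius / offset | 58 mm, ±14 mm | fits strictly inside the 80 mm inner shell; 3-ring patches then span ~24 mm ≈ the 2.5 cm physiological patch size |
| folds | ±4 mm band-limited radial perturbation | creates gyral crowns and facing sulcal walls that exercise surface bias and sign reversal |
| head model | shells 80/85/92 mm, conductivities 1 : 1/30 : 1 | standard scalp/skull/brain contrast; truncated Legendre series (80 terms) |
| sensors | 128, Fibonacci lattice on the scalp shell, upper 3/4 | high-density EEG net geometry, average reference |
| sources | two 37-dipole patches (1+6+12+18) or single dipoles, outward moments, strong:weak = 2:1 | several-cm² activations; the ratio probes amplitude recovery |
| scalp amplitude | 10 μV peak | typical evoked-response magnitude |
| noise | Gaussian, squared-exponential covariance, 30 mm length scale, 1 μV RMS, 100 draws (25 in desk-scale runs) | residual noise of an averaged recording is smooth and ≤ 1 μV |
| patch locations | 66 per hemisphere, greedy farthest-point on an icosphere grid | near-uniform spread with nearest-neighbour spacing ≈ patch diameter |

Solutions are averaged over noise draws; by linearity of `W` this equals
the solution of the draw-averaged data, which the driver exploits (the
equality is asserted exactly in a test).  A location counts as
significantly localizable when the signal+noise solution beats the
noise-only solution's localization error in ≥ 95% of draws.

What the generator does **not** emulate: real folding geometry and
cortical thickness, skull inhomogeneity, BEM-accurate lead fields,
non-Gaussian or nonstationary recording noise, and inter-subject anatomy.
Passing benchmarks therefore demonstrate algorithmic correctness and
relative behaviour (orderings of bias/coherence across algorithms), not
absolute localization accuracy on real recordings.

## Numerical choices

- Icosphere subdivision uses a lexicographic edge-key midpoint cache:
  meshes are bit-reproducible across runs.
- The layered-sphere transfer per degree is solved as a 5×5 interface
  system in radially scaled variables (all entries bounded by ~n), stable
  to degree ≥ 300; sensors are projected radially onto the outer shell
  (error if > 2% off), dipoles must lie strictly inside the inner shell.
- Arc-to-mm conversion multiplies the great-arc angle by the effective
  radius `sqrt(A_folded/4π)`; exact for spherical fixtures, deterministic
  and cheap otherwise.
- Localization error subtracts the source's own extent and clamps at zero
  (a negative error is meaningless); coherence is capped at 1 so over-focal
  solutions cannot out-score a perfect one; AUC uses average ranks for
  ties, making it exactly the pairwise win probability.
- The synthetic noise covariance is expressed in the average-reference
  convention (the common-mode direction is an exact eigenvector carrying
  the removed mean variance), so average-referenced operators null the
  all-ones sensor vector and the matrix stays invertible.
- The sensor-space solve ridge-loads by `1e-10 × trace` only if the plain
  symmetric solve fails.
- Same-hemisphere configurations omit coincident *and overlapping* patch
  pairs; localization error, amplitude ratio, widths and coherence are
  undefined there (no per-source dipole assignment) and reported as NaN,
  while surface bias and AUC remain defined.

## Problem sizes in the shipped runs

Unit tests run on level-2/3 fixtures; the directional benchmark and the
acceptance script use the level-4 fixture with 20 seeded configurations ×
25 noise draws and all eight algorithms, and a level-2 grid (162 locations)
for the significance map — sizes chosen so a full from-scratch
reproduction stays within a coffee break on a single core while leaving
every pipeline stage (mesh → gain → basis → OCV → inversion →
normalization → metrics) genuinely exercised.

## Known limitations

- Basis algorithms (harmonics, splines, IBF, LORETA) are implemented for
  orientation-constrained sources; free orientation is supported for the
  dipole-basis algorithms and normalizations.
- The spherical mapping must be supplied (or generated); no inflation
  algorithm is included.
- Gain import supports delimited text and HDF5; no BEM/FEM solver, no MEG
  coil integration.
- OCV is the only λ-selection rule (no GCV, which is more prone to local
  minima).
- Congruency needs ≥ 3 configurations with variance in both widths and
  errors; it is a population-level quantity and is reported per algorithm,
  not per configuration.
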