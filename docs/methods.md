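# Methods

## Model

A voxel is described by a fibre orientation distribution (FOD) `F` on the unit
sphere and an axially symmetric tensor fibre response function (FRF) with
diffusivities `d_axial >= d_radial >= 0` in μm²/ms. The measured
diffusion-weighted attenuation along unit gradient direction `g` at b-value
`b` (s/mm², internally converted to ms/μm² so exponents are dimensionless) is
modelled as the spherical convolution

    S(g) = ∫_{S²} F(v) · exp(−b (d_radial + (d_axial − d_radial) (g·v)²)) dΩ(v).

`F` is expanded on a real, orthonormal, even-order spherical-harmonic (SH)
basis of order 6 (28 coefficients; odd orders vanish because diffusion and
microscopy FODs are antipodally symmetric). By the Funk–Hecke theorem the
convolution is a per-degree scaling of the SH coefficients by
`f_l = 2π ∫_{−1}^{1} kernel(t) P_l(t) dt`, evaluated with 64-node
Gauss–Legendre quadrature (exact far beyond order 6; validated against a
10⁴-point direct double integral to < 10⁻⁴ relative error, and to machine
precision in practice).

The microscopy side observes only the in-plane angles of fibres in a 2D
section. Its data object is a normalised histogram over the folded in-plane
angle θ ∈ [−π/2, π/2). The model counterpart is the azimuthal marginal of the
(clipped) FOD: the integral of `F` over each wedge of in-plane angle. For a
band-limited FOD this marginal is linear in the SH coefficients and is applied
as a precomputed `n_bins × 28` operator, assembled once per
(plane, binning) with Gauss–Legendre quadrature in both the out-of-plane sine
and the within-bin angle. An earlier implementation that binned dense-sphere
samples instead aliases badly at 1° bins (2562 grid points into 180 bins
leaves near-empty bins) and was replaced; the exact marginal matches the
histogram of projected fibre samples drawn from the same FOD to total
variation < 0.02 at the default settings.

### Cost

    E = E_diff + λ_micro E_micro + λ_complex E_complex

* `E_diff`: mean squared error between measured and predicted attenuations.
* `E_micro`: symmetric Kullback–Leibler divergence between the microscopy
  histogram `P` and the projected model FOD `Q`, `D(P‖Q) + D(Q‖P)`, in
  natural-log units (the log base only rescales the meaning of λ_micro). Both
  histograms are floored at 2·10⁻¹⁶ and renormalised, so the divergence is
  always finite.
* `E_complex = E_neg + Σ_{n=1}^{28} |x_n|`: negativity plus L1 penalty. The
  FOD is evaluated on a dense sphere, negative amplitudes are clipped to zero
  (they contribute to neither the predicted signal nor the projection) and
  their quadrature-weighted magnitude summed into `E_neg`, making the value
  independent of the sphere resolution. The L1 term deliberately includes the
  l = 0 coefficient, i.e. it also penalises total FOD mass.

### Negativity clipping

Clipping happens pointwise on the sphere grid; the clipped amplitudes are
re-expanded in SH by least squares (the pseudoinverse of the basis matrix,
precomputed) before convolution and projection. For well-behaved FODs the
clip is a no-op; for oscillatory intermediate iterates it acts as a soft
positivity projection.

## Sphere and basis conventions

* Real orthonormal SH, ordered l ascending (even only), m = −l..l within each
  degree. Serialisation: one `l m value` line per coefficient.
* Dense sphere: level-4 subdivided icosahedron, 2562 vertices, equal weights
  4π/N. This keeps negativity detection reliable at order 6 while one
  evaluation stays a 2562×28 matrix product. (No subdivision level has
  exactly 724 vertices; 642 at level 3 was judged too coarse.)
* The microscopy plane is the x–y plane of the voxel grid by default; fibre
  inclination φ is measured out of it. All projection code takes an arbitrary
  plane normal.

## Simplified 3-parameter model and MCMC

For validation the FOD is restricted to a Watson distribution
`W(v) ∝ exp(κ (μ·v)²)` with fixed peak axis `μ`, so the free parameters are
`(ODI, d_axial, d_radial)` with `ODI = (2/π) arctan(1/κ)` ∈ (0, 1). The
Watson density (computed peak-referenced to avoid overflow at large κ) is
band-limited by least-squares projection onto the order-6 basis, then passes
through exactly the same clip–convolve–project pipeline as the full model.
This Watson FOD integrates to 1 by construction.

The log-target maps the cost through the exact Gaussian likelihood of the
dMRI noise: `log π = −N E / (2σ̂²)` with `E = E_diff + λ_micro E_micro`
(no complexity penalty in the simplified model), N the number of
diffusion-weighted measurements and σ̂ the attenuation-scale noise SD (known
in simulation, `1/SNR`; estimable from b≈0 replicates on real data). Writing
the target through `E` keeps λ_micro's meaning as the relative weight of the
two fidelity terms; the N factor makes the dMRI part the exact log-likelihood
rather than an N-times-tempered version of it. The cost *minimiser* is
unaffected by this scaling — only posterior widths are.

Sampling is random-walk Metropolis with per-parameter proposal SDs
(0.05, 0.02, 0.02) for (ODI, d_axial, d_radial). During the first 20% of
iterations the global scale adapts every 100 steps towards 25% acceptance
and, from halfway through that window, the proposal covariance is replaced by
the empirical chain covariance scaled by 2.38²/3 (frozen afterwards, so the
remaining chain targets the exact posterior). The first 30% of iterations are
discarded as burn-in. Out-of-constraint proposals (`ODI ∉ (0,1)`,
`d_radial > d_axial`, negative diffusivities, diffusivities above 4 μm²/ms)
score −∞. Chains are reproducible from a single seed; an acceptance rate
outside [0.05, 0.8] raises a warning. Default chain length 12 000–20 000;
one likelihood evaluation costs ~0.1 ms, so a chain runs in seconds.

## Full 30-parameter fit

Two diffusivities plus 28 SH coefficients, parametrised internally as
`(d_radial, d_axial − d_radial, x₁..x₂₈)` so the ordering constraint becomes
box bounds. Two structural facts shape the optimiser:

* **Scale degeneracy.** With only single-shell attenuations the data
  determine `d_axial − d_radial` and the product
  `(FOD mass) · exp(−b d_radial)`; the renormalised 2D projection is
  mass-invariant. `d_radial` is then not identifiable, and the L1 penalty
  (which includes the mass-carrying l = 0 coefficient) pulls it to zero.
  The acquisition this package targets includes eight b ≈ 8 s/mm² images,
  whose attenuation is essentially the FOD mass; the forward model therefore
  predicts any low-b rows present in the scheme with the same tensor kernel
  at their own b-value, which anchors the scale. With the anchor, noiseless
  recovery of the generating diffusivities is exact to optimiser tolerance;
  without low-b rows the model intentionally reproduces the degenerate
  behaviour. Cross-validation of λ_complex operates on the 120
  diffusion-weighted directions only, as the selection depends on the
  out-of-sample error curve, not on absolute diffusivities.
* **Flat valley.** Around the minimum, a small change in diffusivities can be
  compensated by a per-degree rescaling of the FOD at a tiny cost change, so
  plain quasi-Newton descent from a CSD initialisation stalls. The fit
  therefore starts with a nested search: for candidate diffusivities the FOD
  is profiled out by linear least squares on the signal, and Nelder–Mead
  minimises the full cost of the profiled FOD over the two diffusivities
  alone (≤ 120 evaluations). The best profiled point seeds L-BFGS-B over all
  30 parameters (numerical gradients, ftol 10⁻¹², up to 500 iterations).

Multistart: `n_starts − 1` additional starting points are generated by a
short annealing-style perturbation search (100 temperature-decayed Gaussian
jumps, Metropolis acceptance) around the warm start; each start is polished
with L-BFGS-B and the lowest-cost solution wins, ties broken by the lower
complexity term. Defaults: initial FRF (0.25, 0.05) μm²/ms, FOD initialised
from CSD (or a unit-mass isotropic FOD), λ_micro = 1, λ_complex = 10⁻³.

## CSD baseline

The response function is estimated from the 300 highest-FA voxels of a
log-linear tensor fit, axially symmetrised as `d_axial = λ₁`,
`d_radial = (λ₂+λ₃)/2`. (The alternative recursive single-fibre-voxel
selection scheme is out of scope; on dispersed tissue the FA-ranked estimator
visibly inflates d_radial, which is itself a finding the joint model is built
to avoid.) Deconvolution is least squares in the SH domain followed by
iterative soft constraints: sphere directions whose FOD amplitude falls below
τ = 0.1 times the initial mean amplitude contribute penalty rows (weighted to
the scale of the signal matrix) and the system is re-solved until the
constrained set stabilises or 50 iterations pass. Ill-conditioned systems
fall back to a 10⁻⁸ ridge with a warning.

## Structure-tensor histology analysis

Images are smoothed with a Gaussian of σ_grad = 1 px (so central-difference
gradients approximate Gaussian derivatives), the gradient outer product is
window-averaged with σ_window = 8 px, and the per-pixel orientation is the
minor eigenvector's angle (direction of least intensity change), with
coherence `(λ₁−λ₂)/(λ₁+λ₂)` (0/0 → 0; constant images are flagged
degenerate). Superpixel 2D FODs are plain frequency histograms of the masked
orientations (1° bins by default); coherence weighting and a
staining-intensity mask (pixels at or below the 50th intensity percentile,
dark-stain convention) are optional because stain thresholds and artefact
handling are dataset-specific.

## Synthetic data

The generator emulates the validation conditions end to end and fixes them as
defaults: a single Watson fibre population with ODI 0.25, d_axial 0.2 μm²/ms,
d_radial 0.1 μm²/ms; 120 quasi-uniform (Fibonacci-hemisphere) gradient
directions at b = 5000 s/mm²; zero-mean Gaussian noise on the attenuation
scale with SD 1/SNR at SNR = 15 (S0 = 100); and a histology FOD built from
1400² fibre axes drawn from the same Watson distribution by rejection
sampling (uniform proposals accepted when U(0,1) ≤ density/max-density;
below 10⁻⁴ acceptance an exact inverse-CDF sampler takes over with a
warning), projected into the plane and histogrammed with no further noise.
Misregistration is emulated as a circular shift of the histology histogram.

What the generator does **not** emulate — and what passing tests therefore do
not certify about real data: Rician/magnitude noise (a flag-level extension;
Gaussian is the documented noise model), spatially varying or non-rigid
dMRI–histology misregistration beyond in-plane rotation, staining artefacts
and unmyelinated structures invisible to the stain, partial-volume mixtures
of fibre populations, and multi-compartment response functions.

## Validation experiments and problem sizes

All experiment drivers record their configuration and seeds in a manifest and
write partial results append-safely. The package's own operating sizes: MCMC
chains of 12 000 iterations in sweeps and 20 000 in headline runs; inclination
sweep over φ ∈ {0…90}° and λ_micro ∈ {0, 0.1, 1, 10, 100}; rotation sweep over
Δθ up to 20°; λ_complex over a log grid 10⁻⁵…10⁻¹ with the two even halves of
the direction set used as train/validation folds in both directions and their
validation MSEs averaged. The λ_complex selection rule is operationalised as
"largest grid value whose validation MSE stays within 5% of the grid
minimum". The reproduction script additionally averages a handful of
independent replicate simulations for its reported posterior means — the
recovered values then reflect the method rather than one noise draw.

## Known limitations

* The 2D microscopy constraint carries no information about out-of-plane
  dispersion: perpendicular fibres (φ = 90°) remain degenerate at every
  λ_micro, and accuracy degrades beyond φ ≈ 60°. This is a property of the
  data, not of the implementation.
* Band-limiting at order 6 cannot represent very tight FODs (ODI ≲ 0.05);
  near-delta Watson densities alias on the 2562-point sphere.
* Large histology rotations with a strong microscopy weight produce precise
  but biased posteriors; λ_micro = 1 is the recommended operating point
  precisely because it degrades gracefully under ≤ 12° misalignment.
* The full 30-parameter fit relies on low-b rows for absolute diffusivity
  scale (see above); single-shell-only data identify the diffusivity
  difference, not the pair.
* Single-shell, single-tissue modelling only; no multi-shell or
  multi-compartment support.
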