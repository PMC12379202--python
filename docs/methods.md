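# Methods

This note records the model, the simulator, the numerical choices and the
limitations of `pslife`, in enough detail to reproduce or audit any number
the package computes.

## Spectrum model

The per-voxel time-difference distribution (TDD) — annihilation time minus
prompt-photon emission time — is modelled as a three-component exponential
decay convolved with a Gaussian resolution function on a fixed flat
background. With bin centres tᵢ and width w = 0.133 ns:

    mu_i = b + N * w * sum_k BR_k * f(t_i; tau_k, sigma, Delta)
    f(t; tau, sigma, Delta) = 1/(2 tau) exp(sigma^2/(2 tau^2) - u/tau)
                              erfc((sigma/tau - u/sigma)/sqrt(2)),  u = t - Delta

The three components are para-positronium (τ₁ = 125 ps, fixed), direct
annihilation (τ₂ = 388 ps, fixed) and ortho-positronium (τ₃, free, the
imaging quantity). The background b is not fitted: it is fixed to the mean
of the histogram bins whose centres lie below −2.5 ns, a region that only
random coincidences populate.

Numerics: the erfc form overflows once σ/τ or |u|/σ is large. For erfc
argument z ≥ 0 we evaluate `erfcx(z)·exp(−u²/2σ²)` (the exponents combine
exactly); for z < 0 the direct form is safe because its exponent is then
negative. The unit tests compare against adaptive quadrature of the
convolution integral at ≤ 1e−8 relative error and check finiteness for
t ∈ [−50, 50] ns and σ/τ ∈ [1e−3, 10].

Bin contents are approximated by midpoint density × width. With w = 0.133 ns
the induced bias on τ₃ is far below the statistical uncertainty at any
count level used here (the tail-slope test recovers τ₃ to < 1%).

## Priors and likelihood

    tau3  ~ Normal(1.78 ns, 0.8 ns)    truncated at 0
    BR    ~ Dirichlet(0.75, 3.1, 1.15)
    sigma ~ Normal(0.1 ns, 0.05 ns)    truncated at 0
    Delta ~ Normal(0 ns, 0.5 ns)
    N     ~ Normal(A, 0.1 A),  A = sum over fit-range bins of (y_i - b)

The truncations at zero make the lifetime and resolution priors proper on
their physical support. The likelihood is independent Gaussian per bin with
scale sᵢ = √max(μᵢ, 1): the Gaussian approximation to Poisson counting
noise, floored at one count to avoid degenerate zero-variance bins where
the model predicts (near-)zero. The fit range is [−2, 8] ns; bins are
assigned to the fit or background region by their centre. Voxels with
A ≤ 0 carry no net signal (the N prior would be ill-defined) and are
masked as unfittable.

The full histogram spans [−5, 8] ns so that ~19 bins sit below the −2.5 ns
background cutoff. Histogram edges start at −5 and advance in whole bins;
the last partial bin before +8 is dropped (values there count as
out-of-range), so every bin has full width. A voxel passes QC iff the
standard error of the background-bin mean divided by the mean is strictly
below 0.20.

## Posterior sampling

Sampling is by affine-invariant ensemble MCMC (emcee) with a mixture of
differential-evolution and snooker moves, in the unconstrained space

    theta = (log tau3, z1, z2, log sigma, Delta, log N)

where (z1, z2) is a stick-breaking parameterization of the BR simplex; the
log-Jacobian of the transform is added to the target so the constrained-
space priors are exact. Walkers within an ensemble interact, so the usual
split-Rhat over walkers saturates near 1.02 even when fully mixed. We
therefore run independent ensembles from different seeds (default 4
ensembles × 16 walkers, 600 warmup + 400 kept steps each) and compute Rhat
*across ensembles* (each ensemble's pooled draws = one chain) and ESS from
the per-walker autocorrelation. A fit is flagged converged when
Rhat < 1.01 and ESS > 400; non-convergence is reported, never raised, and
non-converged voxels are excluded from images unless requested. Ensemble
moves have no divergence concept, so `n_divergent` is always 0.

Point estimates are posterior means; τ₃ uncertainty is the posterior SD
(its marginal is bell-shaped); BR uncertainty is reported as 68%
highest-density intervals computed by brute force over sorted draws
(shortest window containing ⌈0.68 n⌉ order statistics), cross-checked
against closed-form quantiles in tests. Per-voxel seeds derive
deterministically from (global seed, flattened voxel index), so images are
bit-reproducible.

Prior-only sampling (likelihood switched off) runs through the identical
transform and is tested against the exact truncated-normal and Dirichlet
moments — an audit of the Jacobian bookkeeping.

## Synthetic data

Two generators exist, and both are first-class tested code:

* `sample_tdd_direct` draws time differences straight from the generative
  model (channel ~ BR, delay ~ Exp(τₖ), plus Normal(Δ, σ) noise, plus a
  uniform background on the histogram window). It is the fast path for
  fit-level studies and for the acceptance statistics.
* The full simulator models a four-tube phantom in an idealized cylindrical
  scanner (barrel radius 410 mm, axial half-length 530 mm). Positron decays
  are Poisson in time (activity × duration × 0.228, the ¹²⁴I positron
  branch), uniform inside each tube; 12.0% of positrons carry a prompt
  602.73 keV photon emitted at decay time. Annihilation emits two 511 keV
  photons back-to-back isotropically from the decay position at
  decay + delay. Detection applies the geometric barrel intersection, a
  per-photon Gaussian timing smear (default 95 ps, giving a pair
  time-difference resolution ≈ 134 ps, consistent with the 133 ps TDD bin)
  and a Gaussian energy smear with 11% FWHM at 511 keV scaling as √E.
  Tube materials carry the measured lifetimes and branching fractions
  (dry XAD4 2.52 ns, wet 2.37 ns, gelatine 2.27 ns, water 1.82 ns);
  activities follow the prepared samples (1.12/1.44/1.14/1.26 MBq).

Random coincidences are injected as triple coincidences whose prompt is
time-shifted uniformly against a consistent annihilation pair, which makes
the reconstructed Δt exactly uniform; their vertices are drawn from the
phantom activity distribution (randoms pile up where the activity is), and
their count is Poisson-matched so the requested fraction of *accepted* 3γE
is random. Offsets span [−6, 12.5] ns, comfortably covering the histogram
while fitting inside the 15 ns coincidence window.

What the simulator does **not** model: positron range and photon
acollinearity (the vertex equals the decay position and photons are exactly
collinear — these only blur localization), Compton scatter in the object,
attenuation, detector dead time, crystal granularity, and the
electron-capture branch of ¹²⁴I (which contributes no annihilation pair in
this idealization). Passing recovery tests therefore demonstrates the
correctness and calibration of the analysis chain under its own stated
noise model, not robustness to these additional real-data effects. One
real effect the simulator *does* reproduce: energy smearing occasionally
swaps photon roles (a prompt read as annihilation-window), producing a
small physical mis-assignment background; exactness tests disable the
energy smear for that reason.

## Event selection and localization

Clusters are formed greedily on the time-sorted singles stream: a cluster
contains every record within the 15 ns coincidence window of its first
record (the window generously covers the [−5, 8] ns TDD range plus flight
times; the hardware window of a real scanner is not modelled). A cluster is
accepted iff it contains exactly two annihilation-window and exactly one
prompt-window photon; clusters with extra in-window photons are discarded
as ambiguous rather than resolved, a conservative rule that makes counts
exactly reproducible. Out-of-window records in a cluster do not veto it.
Because of the discard rule, shrinking an energy window can in contrived
cases *increase* the accepted count (a 3-annihilation cluster becomes
unambiguous); the monotonicity property is therefore only guaranteed — and
only tested — on clusters of at most three photons.

Energy windows are closed intervals; boundary energies are accepted. The
TOF vertex is `midpoint − (c/2)(t_B − t_A)·û_AB` (displacement toward the
*earlier* crystal), clamped to the chord; c = 299.792458 mm/ns. The time
difference corrects all three photons for flight from the TOF vertex, which
also serves as the prompt emission point (positron range neglected,
matching the simulator). All per-cluster time arithmetic is done relative
to the cluster start so the flight-time cancellation is exact to machine
precision regardless of acquisition length; the noiseless end-to-end test
demands agreement with the generative delay to 1e−9 ns.

Voxel grids are axis-aligned half-open boxes (boundary points belong to the
higher-index voxel), centred on the phantom bounding box. Each voxel size
(10.0, 7.1, 4.0 mm) is an independent binning of the vertices, not a
resampling.

## Problem sizes and test design

Counting targets are set by the posterior-uncertainty regimes of interest,
since absolute detected counts depend on scanner efficiency details outside
the model:

* whole-tube regime: 4×10⁵ signal events with a 10% flat background gives a
  τ₃ posterior SD of ≈ 0.015–0.03 ns;
* single-voxel regime: 5×10³ events gives ≈ 0.12–0.25 ns.

The voxel-wise ordering study simulates a thin axial slab (±2 mm) of the
four-tube phantom for a 40 s acquisition at the sample activities, selects
≈2.4×10⁶ three-photon events, and fits the 4 mm voxels of the central
axial layer. TOF blur (σ ≈ 13 mm per axis) spreads each tube's events over
many voxels, so individual 4 mm voxels hold 10³–10⁴ events and their
posteriors are visibly prior-shrunk at the extremes of the lifetime range.
The ordering statistic is therefore the count-weighted mean of posterior
means over each tube's *core* voxels (QC-passing voxels within 20 mm of
the tube axis holding at least half the counts of the tube's densest
voxel) — the same logic as picking a well-populated central-region voxel,
but with the per-voxel noise averaged down. The strict ordering
dry > wet > gelatine > water is asserted on a fixed seed.

Calibration is checked at fixed water-tube truth over 50 replicates of
2×10⁴-event TDDs: the 68% HDI of BR₃ must cover the generative value in
68% ± 12% of replicates (the binomial band at n = 50 plus margin for the
Gaussian-likelihood approximation).

## Known limitations

* The Gaussian likelihood understates the skewness of low-count Poisson
  bins; at single-voxel statistics this contributes a small positive bias
  to τ₃ (≈ +0.02 ns at 10⁴ events) on top of prior shrinkage.
* Rhat across 2 ensembles (the light configuration used for bulk voxel
  fits) is a weak diagnostic; the default 4-ensemble configuration should
  be used for any headline number.
* The background estimator assumes the sub-(−2.5 ns) region is pure
  background; a resolution function wider than ~0.8 ns would leak signal
  into it.
* NIfTI output stores maps in scanner coordinates with a diagonal affine;
  no anatomical registration is attempted.
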