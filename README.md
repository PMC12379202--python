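# pslife — voxel-wise ortho-positronium lifetime imaging

Positronium forms when a positron from a β⁺ emitter captures an electron in
tissue. The long-lived spin triplet, ortho-positronium (oPs), is quenched by
collisions with environmental electrons ("pick-off"), so its observed
lifetime τ₃ is sensitive to the local molecular environment — notably to
oxygenation, which makes it a candidate hypoxia marker for PET. With
¹²⁴I, each positron decay is accompanied (12.0% of the time) by a prompt
602.73 keV de-excitation photon that starts a clock; the two 511 keV
annihilation photons stop it. `pslife` implements the full analysis chain
that turns such data into parametric lifetime images, plus a synthetic
phantom/scanner simulator so that every stage can be validated by parameter
recovery without access to scanner data.

The chain is:

1. **Event selection** — three-photon events (3γE): exactly two singles in
   the annihilation energy window [460, 545] keV and one in the prompt
   window [568, 639] keV, in time coincidence.
2. **TOF localization** — the annihilation vertex is placed on the line
   between the two annihilation crystals at
   `midpoint − (c/2)(t_B − t_A)·û`, with no tomographic reconstruction.
3. **Histoimaging** — vertices are binned into voxels (10.0, 7.1 or 4.0 mm);
   each voxel accumulates a time-difference distribution (TDD) with 133 ps
   bins; the flat random background *b* is fixed as the mean of bins below
   −2.5 ns, and voxels whose background relative error is ≥ 20% are masked.
4. **Bayesian lifetime fit** — per TDD, the model

   μᵢ = b + N·w·Σₖ BRₖ·f(tᵢ; τₖ, σ, Δ),

   where f is the exponentially modified Gaussian (Gaussian resolution ⊗
   exponential decay), τ₁ = 125 ps (para-positronium) and τ₂ = 388 ps
   (direct annihilation) are fixed, and the priors are
   τ₃ ~ N(1.78, 0.8) ns, BR ~ Dirichlet(0.75, 3.1, 1.15),
   σ ~ N(0.1, 0.05) ns, Δ ~ N(0, 0.5) ns, N ~ N(A, 0.1·A) with
   A = Σ(yᵢ − b) over the fit range [−2, 8] ns, under a Gaussian
   likelihood. Sampling uses an affine-invariant ensemble MCMC; summaries
   are posterior means, SDs and 68% highest-density intervals.
5. **Imaging** — τ₃ maps, relative-uncertainty maps and BR₃ maps with QC
   masks, written as NIfTI-1 with a JSON provenance sidecar; maximum
   intensity projections and slice views. No smoothing or post-processing.

The simulator generates a four-tube phantom (XAD4 at different humidity
levels plus water, 1.1–1.4 MBq per ~5 ml tube) inside an idealized
cylindrical long-axial-FOV scanner with per-photon Gaussian timing smear,
√E-scaled energy smear, and injected random coincidences producing a flat
TDD background.

## Worked example

Fit a synthetic whole-tube TDD generated with the water-tube ground truth
(τ₃ = 1.82 ns, BR = (0.088, 0.644, 0.268), σ = 0.12 ns, 4×10⁵ signal events
with a 10% flat background):

```python
from pslife import LifetimeParams, build_tdd, with_background, fit_tdd
from pslife.phantom import sample_tdd_direct

truth = LifetimeParams(tau3=1.82, br=(0.088, 0.644, 0.268), sigma=0.12)
deltas = sample_tdd_direct(truth, 400_000, 44_444, seed=1)
hist = with_background(build_tdd(deltas))
summary, samples = fit_tdd(hist, seed=1)
print(f"tau3 = {summary.tau3_mean:.4f} +- {summary.tau3_sd:.4f} ns")
print(f"BR3  = {summary.br_mean[2]:.4f}, 68% HDI {summary.br_hdi68[2]}")
```

prints (seed 1)

```
tau3 = 1.8355 +- 0.0157 ns
BR3  = 0.2692, 68% HDI [0.26729 0.27134]
```

i.e. the oPs lifetime is recovered within one posterior SD of the 1.82 ns
truth, at the ~1% relative precision characteristic of whole-tube counting
statistics, and the oPs branching fraction is recovered at the third decimal.

The full pipeline is also exposed as a CLI:

```bash
pslife simulate --config run.yaml --out singles.h5
pslife select   --singles singles.h5 --out events.csv
pslife fit      --events events.csv --out fit.json
pslife run-all  --config run.yaml --out lifetime_image --seed 1
```

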