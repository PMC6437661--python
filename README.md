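# iemtools

Simulation and analysis toolkit for **inverted encoding models (IEMs)** of
orientation-selective population responses, and for the **Bayesian stimulus
decoder** that fixes their central interpretational problem.

It is aimed at researchers who use channel encoding models on fMRI/EEG-style
population measurements and want to understand — or demonstrate — what the
reconstructed "channel response function" does and does not measure.

## The problem and the model

A channel encoding model writes the trial-by-voxel response matrix as

    B = R W + η,     R = S C,

where `S` (n×s) is the one-hot stimulus matrix, `C` (s×k) evaluates k channel
basis functions at the s stimulus orientations, `W` (k×v) are voxel weights
and `η` is zero-mean Gaussian noise.  Weights are estimated by least squares
on training data, and the model is inverted on held-out data:

    Ŵ = (RᵀR)⁻¹ Rᵀ B_T,      R̂ = B_V Ŵᵀ (Ŵ Ŵᵀ)⁻¹.

The catch: for any invertible k×k matrix `P`, the re-based channel set
`C₂ = C₁P` gives an encoding model with identical fit quality, identical
predictions (even at untrained orientations), and reconstructions related by
`R̂₂ = R̂₁P`.  The reconstructed channel response function is therefore one
member of an infinite family — it reproduces the assumed basis, not the
population tuning.  `iemtools` makes this executable:

* `basis` — rectified-cosine channel bases `max(0, cos 2(θ−φ_j))^p` and
  invertible transforms (a circulant bimodal transform `P = I + 0.9·Π³`, and
  well-conditioned random transforms);
* `simulate` — voxel populations of von Mises-tuned units
  (`a(Δ) = exp(κ(cos 2Δ − 1))`, κ set by the half-width at half-height) with
  random proportion weights and independent Gaussian voxel noise;
* `iem` — weight fitting, prediction, model inversion and the
  shift-and-average channel response function (CRF);
* `equivalence` — the four identities above as seeded, tolerance-checked
  reports;
* `bayes` — generative noise model `Ω = σ_c²ŴᵀŴ + diag(τ²)` and per-trial
  posterior `p(θ | b) ∝ N(b; c(θ)Ŵ, Ω)` over an orientation grid: the decoder
  reconstructs the *stimulus*, and its output is basis-independent;
* `metrics` — circular distance, strict local maxima, peak separation, FWHM.

## Worked example

```bash
python examples/bimodal_crf_reconstruction.py
```

```
zero noise (sigma = 0.0):
  offsets (deg): [-90.  -67.5 -45.  -22.5   0.   22.5  45.   67.5]
  aligned CRF:   [0.0795 0.     0.     0.0884 1.     0.0884 0.0795 0.9   ]
  validation r2 = 1.0000
  2 local maxima at offsets [0.0, 67.5]
  peak separation = 67.5 deg (the bimodal basis geometry, recovered from unimodally tuned units)
```

Every simulated unit is unimodally tuned, yet the reconstructed CRF is
bimodal with peaks 67.5° apart — exactly the geometry of the bimodal basis
that was assumed in the analysis.  The companion scripts show the other side:

* `examples/transform_equivalence.py` — the weight/prediction/reconstruction
  identities hold to ~1e-12, and multiplying the random- or bimodal-basis
  reconstruction by `P⁻¹` reproduces the unimodal CRF to ~1e-14;
* `examples/bayesian_decoding.py` — the posterior map is identical under
  unimodal and bimodal bases (max difference ~1e-11), peaks at the true
  orientation, and only widens (FWHM 3.9° → 8.8°) as noise grows.

A thin CLI wraps the same pipelines: `iemtools simulate|fit|invert|decode|
fig2|fig3|suite` (see `iemtools --help`).

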