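"""Bayesian stimulus decoding: reconstruct the stimulus, not the model.

Fits the generative noise model on training residuals and computes, per
validation trial, the posterior probability of every orientation under a
uniform prior.  Unlike the inverted encoding model, the posterior is
basis-independent: unimodal and bimodal channel bases give the same map,
always peaked at the true orientation, with its width tracking the noise.
"""

import numpy as np

from iemtools import (
    NOISE_PRESETS,
    evenly_spaced_design,
    fit_noise_model,
    fit_weights,
    forward_channel_responses,
    make_bimodal_transform,
    make_unimodal_basis,
    posterior_grid,
    simulate_dataset,
    simulate_population,
    summarize_posteriors,
    transform_basis,
)

design = evenly_spaced_design(8, 27)
population = simulate_population(v=100, m=180, h=40.0, seed=1)
unimodal = make_unimodal_basis(8)
bimodal = transform_basis(unimodal, make_bimodal_transform())

for preset in ("low_noise", "high_noise"):
    sigma = NOISE_PRESETS[preset]
    train = simulate_dataset(population, design, sigma, seed=11, role="train")
    valid = simulate_dataset(population, design, sigma, seed=22, role="validation")
    maps = {}
    for basis in (unimodal, bimodal):
        fit = fit_weights(forward_channel_responses(design, basis), train)
        noise = fit_noise_model(fit)
        maps[basis.kind] = posterior_grid(valid, fit, noise, grid_step=0.5)
    diff = np.abs(
        maps["unimodal"].probabilities - maps["transformed"].probabilities
    ).max()
    summary = summarize_posteriors(maps["unimodal"])
    med_err = summary.per_trial["circular_error_deg"].median()
    print(f"\n{preset} (sigma = {sigma}):")
    print(f"  max |posterior(unimodal basis) - posterior(bimodal basis)| = {diff:.2e}")
    print(f"  aligned average posterior: peak at {summary.peak_offset_deg:+.1f} deg "
          f"from truth, FWHM = {summary.fwhm_deg:.1f} deg, "
          f"local maxima = {summary.n_local_maxima} (faint tail ripples included)")
    print(f"  median MAP error = {med_err:.2f} deg")
print("\n-> the posterior peaks at the true orientation whatever basis was assumed;"
      "\n   more noise only widens it (larger FWHM = more stimulus uncertainty).")
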