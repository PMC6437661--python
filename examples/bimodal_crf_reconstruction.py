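"""Reconstruct a channel response function with a bimodal channel basis.

Simulates a population of 100 voxels built from purely *unimodal*
orientation-tuned units, then fits and inverts an encoding model whose
channel basis functions are bimodal (each channel has a secondary lobe 67.5
degrees from its primary peak).  The shift-and-averaged reconstruction
faithfully reproduces the bimodal basis — even though nothing in the
simulated brain is bimodally tuned.  The reconstruction reflects the model,
not the population.
"""

import numpy as np

from iemtools import (
    evenly_spaced_design,
    fit_weights,
    forward_channel_responses,
    invert_model,
    make_bimodal_transform,
    make_unimodal_basis,
    shift_average,
    simulate_dataset,
    simulate_population,
    transform_basis,
    variance_explained,
)
from iemtools.metrics import CircularCurve, local_maxima, peak_separation

design = evenly_spaced_design(8, 27)  # 8 orientations x 27 repeats
population = simulate_population(v=100, m=180, h=40.0, seed=1)
basis = transform_basis(make_unimodal_basis(8), make_bimodal_transform(8, 3, 0.9))

for sigma, label in ((0.0, "zero noise"), (0.008, "low noise")):
    train = simulate_dataset(population, design, sigma, seed=11, role="train")
    valid = simulate_dataset(population, design, sigma, seed=22, role="validation")
    fit = fit_weights(forward_channel_responses(design, basis), train)
    crf = shift_average(invert_model(fit, valid))
    curve = CircularCurve(offsets=crf.offsets, values=crf.mean)
    peaks = local_maxima(curve)
    print(f"\n{label} (sigma = {sigma}):")
    print("  offsets (deg):", crf.offsets)
    print("  aligned CRF:  ", np.round(crf.mean, 4))
    print(f"  validation r2 = {variance_explained(fit, valid):.4f}")
    print(f"  {len(peaks)} local maxima at offsets {[curve.offsets[p] for p in peaks]}")
    if len(peaks) == 2:
        print(f"  peak separation = {peak_separation(curve):.1f} deg "
              "(the bimodal basis geometry, recovered from unimodally tuned units)")
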