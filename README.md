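# pcctherm

Photon-counting CT (PCCT) thermometry: recover the temperature of a liquid
volume from spectral X-ray attenuation measurements, without calibrating
to the specific material.

Thermal ablation procedures need volumetric temperature maps; CT-based
thermometry exploits the drop in linear attenuation coefficient (LAC, μ)
caused by thermal expansion. The classical route — a per-tissue linear
calibration of CT number against temperature — fails when material
properties vary. This package implements an alternative: a photon-counting
detector measures μ in four energy bins (8–33, 33–45, 45–60, 60–100 keV)
simultaneously, a basis material decomposition relates an unknown liquid to
a set of characterized base materials (water, 50 mmol/L and 600 mmol/L
CaCl₂), and a small fully connected network maps the spectral measurement
to temperature.

The pipeline, end to end:

1. **Projection simulation** (`geometry`): diverging-beam (fan within each
   detector row) projections of a square liquid phantom, empty and filled,
   acquired as paired threshold frames and subtracted into energy bins.
2. **LAC extraction** (`extraction`): along a line of interest (LOI, one
   detector row), μ is recovered from the profile difference
   Δp(x) = ln(I_e/I_f) via the weak-perspective area integral

       μ = (pitch / L²) ∫ Δp(x)/m dx,

   with m = 1.23 the geometric magnification, after unstable-pixel removal
   (>3 SD), a 5-pixel sliding average and a 7-pixel median filter.
   Averaging 10 adjacent LOIs yields a measurement variance.
3. **Material model** (`materials`): volume-fraction decomposition
   μ(Eₖ) = Σᵢ Vᵢ μᵢ(Eₖ) with Σ Vᵢ = 1, solved as sum-constrained least
   squares over all four bins; Hounsfield conversion; the linear mixture
   thermal model α′ = Σ Vᵢ αᵢ kept as the (deliberately inadequate)
   non-learned baseline.
4. **Temperature regressor** (`network`): an 8-4-4-1 ReLU network on the
   feature vector [μ(T, E₁..E₄), (μ(T, E₁..E₄) − μ(T₀, E₁..E₄))·100],
   trained by per-sample SGD (MSE loss, learning rate 1e-5, 80/20 split)
   on 333 noise-perturbed inputs per base material, with baseline-scan
   augmentation, input-jitter regularization and restart selection by a
   volumetric-mixture probe; predictions are anchored to the measured
   baseline-scan temperature, and Monte-Carlo 95% confidence intervals
   propagate the 10-LOI measurement variance.
5. **Synthetic data** (`synthetic`): generates base/test thermal series
   with the measured data's structure — positive thermal slope in the
   33–45 keV bin, negative elsewhere, and a quadratic dependence of
   sensitivity on CaCl₂ concentration that the linear mixture model
   cannot represent.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from pcctherm import (PhantomGeometry, default_base_set, make_test_materials,
                      make_phantom_scene, measure_scene, mix_spectral_lac,
                      decompose, fit_thermometry, RegressorSpec,
                      evaluate_on_series)

geometry = PhantomGeometry.self_consistent()   # reference distances, 25.4 mm phantom
bases = default_base_set()                     # water, 50, 600 mmol/L CaCl2

# 1. measure a phantom filled with 600 mmol/L CaCl2 at 43 degC
scene = make_phantom_scene(geometry, bases.bases[2], 43.0, noise=False)
m = measure_scene(scene, geometry)
print(np.round(m.mu_per_bin, 5))        # [0.04985 0.03476 0.02636 0.02112]
print(np.round(bases.bases[2].lac_at(43.0).mu_per_bin, 5))
                                        # [0.04979 0.03472 0.02634 0.0211 ]

# 2. decompose an equal-volume water / 600 mmol/L mixture
target = mix_spectral_lac(np.array([0.5, 0.0, 0.5]), bases, 33.0)
print(decompose(target, bases).fractions.round(6))   # [0.5 0.  0.5]

# 3. train the regressor and evaluate the held-out series
model, history = fit_thermometry(bases, RegressorSpec(), seed=1)
print(round(history["val_mae"].iloc[0], 2),
      "->", round(history["val_mae"].min(), 2))      # 61.09 -> 3.66
similar, dissimilar = make_test_materials(seed=1)
print(round(evaluate_on_series(model, similar)["abs_error"].mean(), 2))    # 1.7
print(round(evaluate_on_series(model, dissimilar)["abs_error"].mean(), 2)) # 2.81
```

The extracted LACs (step 1) match the generating series to ~0.1% — the
residual error of the weak-perspective correction in this geometry (its
theoretical bound is 3%). The decomposition (step 2) identifies the
mixture's volume fractions to ~1e-10. In step 3 the validation error
falls from the uninformed ~61 degC to 3.66 degC, and the mean absolute
errors on the held-out series — a 300 mmol/L-like mixture the network
never saw and an organic-like surrogate off the basis family — are
1.7 degC and 2.81 degC.

A command-line interface wraps the same pipeline:

```
pcctherm simulate --config run.yaml --out data/
pcctherm extract  --frames data/ --out lac.csv
pcctherm decompose --lac lac.csv --bases data/bases.csv --out fractions.csv
pcctherm train    --series data/bases.csv --model model.json
pcctherm predict  --model model.json --series data/test.csv --out pred.csv
pcctherm evaluate --pred pred.csv
```

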