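"""Generate synthetic NIR spectra with known analyte concentrations.

The generator mixes per-component pure spectra (sums of Gaussian
absorption bands) with Beer-Lambert weights, then applies multiplicative
scatter, a polynomial baseline and white noise — the standard nuisance
structure of diffuse-reflectance NIR measurements.
"""

import numpy as np

from nirquant import SyntheticConfig, generate

cfg = SyntheticConfig(n_samples=100, n_points=400, seed=42)
spectra, refs, pure = generate(cfg)

print(f"spectra matrix : {spectra.absorbance.shape}")
print(f"wavenumbers    : {spectra.wavenumbers[0]:.0f}-{spectra.wavenumbers[-1]:.0f} cm^-1")
print(f"analyte        : mean {refs.values.mean():.2f}, sd {refs.values.std():.2f} "
      "(concentration units)")
print(f"pure spectra   : {pure.shape[0]} components x {pure.shape[1]} points")

# the analyte (component 0) drives part of the measured signal; its
# strongest band is where concentration information is most visible
peak = int(np.argmax(pure[0]))
r = np.corrcoef(refs.values, spectra.absorbance[:, peak])[0, 1]
print(f"correlation between concentration and absorbance at the analyte's "
      f"strongest band ({spectra.wavenumbers[peak]:.0f} cm^-1): r = {r:.2f}")
print("(high but imperfect: scatter, baseline and interferents mask the "
      "signal, which is what calibration models must overcome)")
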