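"""Decompose a biofluid-like spectrum into metabolite standard spectra.

Builds a target = 2.0 x valine + 0.5 x tryptophan + smooth fluorescence
background + noise, then fits it against the ten-metabolite synthetic
standard library by alternating non-negative least squares with a
penalized-least-squares baseline. The recovered coefficients measure each
metabolite's contribution.
"""

import numpy as np

from ramanfuse import fit_references, make_reference_library
from ramanfuse.spectra import Spectrum

lib = make_reference_library()
rng = np.random.default_rng(1)
x = lib.axis
R = lib.matrix()
u = (x - x[0]) / (x[-1] - x[0])
background = 3.0 * (1 + 0.4 * u - 0.5 * u**2)
y = background + 2.0 * R[:, lib.names.index("valine")] \
    + 0.5 * R[:, lib.names.index("tryptophan")] \
    + rng.normal(0, 0.002, x.size)

fit = fit_references(Spectrum(axis=x, intensities=y), lib)
print(f"converged in {fit.n_iter} sweeps; R^2 on baseline-subtracted signal "
      f"= {fit.r_squared:.4f}")
print("recovered coefficients (planted: valine 2.0, tryptophan 0.5):")
for name, c in fit.coefficients.sort_values(ascending=False).items():
    if c > 1e-3:
        print(f"  {name:<14} {c:.3f}")
print(f"largest spurious coefficient: "
      f"{fit.coefficients.drop(['valine', 'tryptophan']).max():.4f}")
# Coefficients within a few percent of the planted values, near-zero
# weight on the eight absent metabolites.
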