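"""Compute the ten vegetation indices on a toy reflectance image.

A single pixel with blue/green/red/NIR reflectances (0.1, 0.2, 0.2, 0.4)
— a moderately vegetated surface — is pushed through all ten index
formulas (soil adjustment L=0.5, SARVI gamma=1, WDRVI alpha=0.2).
Positive NDVI/SAVI values indicate vegetation; CI=1 means NIR is twice
the green reflectance.
"""

import numpy as np

import gmmfusion as gf
from gmmfusion.features import INDEX_NAMES

img = gf.MultiBandImage(
    np.array([[[0.1, 0.2, 0.2, 0.4]]]),
    {"blue": 0, "green": 1, "red": 2, "nir": 3},
)
values = gf.vegetation_indices(img, gf.IndexParams(soil_L=0.5, gamma=1.0, alpha=0.2))
for name, val in zip(INDEX_NAMES, values[0, 0]):
    print(f"{name:>6s} = {val: .5f}")
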