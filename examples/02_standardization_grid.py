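"""The 36-setting image standardization grid and the three quantizers.

Texture matrices need a common voxel size and a discrete gray-level alphabet;
the grid crosses voxel sizes (1/2/3 mm) with three quantizers at four level
counts.  The demo quantizes one skewed intensity sample three ways.
"""

import numpy as np

import mpradiomics as mp
from mpradiomics.standardization import quantization_mse, quantize

grid = mp.enumerate_grid()
print(f"{len(grid)} settings; first = {grid[0]}, last = {grid[-1]}")

rng = np.random.default_rng(0)
sample = rng.gamma(2.0, 20.0, size=5000).reshape(-1, 1, 1)
mask = np.ones(sample.shape, dtype=bool)

print("\nquantizing 5000 gamma-distributed intensities to L = 8 levels:")
for method in ("uniform", "equal_probability", "lloyd_max"):
    region = quantize(sample, mask, method, 8)
    counts = np.bincount(region.masked_levels(), minlength=9)[1:]
    mse = quantization_mse(sample, mask, region)
    print(f"  {method:18s} level counts {counts.tolist()}  MSE {mse:7.2f}")
print("\nuniform bins are equal-width (skewed counts); equal-probability bins "
      "are flat; Lloyd-Max minimizes the quantization MSE.")
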