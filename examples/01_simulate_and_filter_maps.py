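"""Simulate a density map from a bead model, then resample and filter it.

Builds a toy subunit, renders it as a Gaussian density at 20 A resolution,
joins neighbouring voxels (doubling the voxel size, conserving the density
sum exactly) and low-pass filters the result to 44.8 A — the preprocessing
applied to experimental maps whose resolution-to-voxel ratio is too high.
"""
import numpy as np

from emassemble.densmap import downsample_join, lowpass_filter, simulate_map
from emassemble.synthetic import ToySpec, make_toy_assembly

assembly, subunit = make_toy_assembly(ToySpec())
fine = simulate_map(assembly, 20.0, voxel_size=5.0)
print(f"20 A map: dims {fine.dims}, voxel {fine.voxel_size} A, "
      f"sum*voxvol = {fine.density_sum * fine.voxel_size**3:.0f} "
      f"(total bead weight {assembly.total_weight:.0f})")

joined = downsample_join(fine, 2)
print(f"joined:   dims {joined.dims}, voxel {joined.voxel_size} A, "
      f"density sum conserved: {np.isclose(joined.density_sum, fine.density_sum)}")

joined.resolution_label = 20.0
coarse = lowpass_filter(joined, 44.8)
print(f"44.8 A:   dims {coarse.dims}; peak dropped from "
      f"{joined.values.max():.2f} to {coarse.values.max():.2f} "
      "(the blur spreads density, the integral stays put)")
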