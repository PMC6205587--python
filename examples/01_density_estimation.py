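"""Heat-diffusion KDE versus the brute-force Gaussian-sum oracle.

Draws a 3D Gaussian benchmark cloud (mean 0.5, variance 0.3 per axis),
estimates its density with the spectral (DCT) solver and with the direct
product-kernel sum at the same Silverman bandwidth, and compares both to
the closed-form density.
"""

import numpy as np

from tides import default_ranges, diffusion_kde, direct_kernel_kde, silverman_bandwidth
from tides.simulate import gaussian3d_density, simulate_gaussian3d

points = simulate_gaussian3d(2000, seed=0)
bw = silverman_bandwidth(points)
ranges = default_ranges(points)
print(f"Silverman bandwidths per axis: {np.round(bw.h, 4)}")

spectral = diffusion_kde(points, m=64, bandwidth=bw, ranges=ranges)
direct = direct_kernel_kde(points, "gaussian", bw, m=64, ranges=ranges)

rel_l1 = np.abs(spectral.values - direct.values).sum() * spectral.bin_volume
mesh = np.stack(np.meshgrid(*(spectral.axis_centers(i) for i in range(3)),
                            indexing="ij"), axis=-1)
mae = np.abs(spectral.values - gaussian3d_density(mesh)).mean()

print(f"grid mass (should be 1):       {spectral.total_mass():.6f}")
print(f"spectral vs direct rel. L1:    {rel_l1:.4f}   (fraction of total mass)")
print(f"per-node MAE vs closed form:   {mae:.5f}  (density units)")
# The spectral estimate reproduces the O(n m^3) direct sum to a few percent
# of total mass while running in a fraction of the time.
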