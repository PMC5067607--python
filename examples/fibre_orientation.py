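"""Fibre-orientation distributions of isotropic and aligned textures.

Renders a synthetic isotropic fibre texture and one aligned along 90
degrees, and prints their FFT-based orientation histograms (8-degree bins).
"""

import numpy as np

from activegel import (FibreTextureSpec, orientation_distribution,
                       render_fibre_image)

iso = FibreTextureSpec(size=(1024, 1024), n_fibres=20_000, seed=1)
dist = orientation_distribution(render_fibre_image(iso), bin_width=8.0,
                                tile=128)
print("isotropic texture (orientations uniform on [0, 180)):")
print(f"  {len(dist.values)} bins, per-bin mean {dist.values.mean():.4f}, "
      f"min {dist.values.min():.4f}, max {dist.values.max():.4f}")
print("  flat at ~1/23 ~ 0.044: no preferred orientation\n")

aligned = FibreTextureSpec(size=(1024, 1024), n_fibres=20_000,
                           orientation_law="von_mises", mu_deg=90.0,
                           kappa=8.0, seed=2)
dist = orientation_distribution(render_fibre_image(aligned), bin_width=8.0,
                                tile=128)
print("aligned texture (von Mises, mu = 90 deg, kappa = 8):")
print(f"  mode bin at {dist.mode_angle:.1f} deg with value "
      f"{dist.values[dist.mode_bin]:.4f}")
print("  the peak marks the preferred fibre direction, as develops when an")
print("  anisotropically attached gel contracts along a free channel axis.")
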