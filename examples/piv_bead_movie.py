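"""PIV on a synthetic tracer-bead movie of a contracting disk.

Renders fluorescent-bead frames advected by the model's penetrating
contraction field, measures the displacement field by iterative NCC PIV and
compares the local strain rate near the boundary with the centre.
"""

import numpy as np

from activegel import (ContractionCurve, SyntheticScene, compute_piv,
                       penetrating_contraction_field, repair_vectors,
                       render_bead_movie, strain_rate)

scene = SyntheticScene(size=(256, 256), seed=1)
curve = ContractionCurve(L_init=100.0, K=0.23, tau=12.0)
field = penetrating_contraction_field((128.0, 128.0), 100.0, curve)

stack, truth = render_bead_movie(scene, field, [3.0, 4.5])
print(f"rendered {stack.shape[0]} frames of {truth['n_beads']} beads "
      f"({scene.size[0]}x{scene.size[1]} px, 1 um/px)")

vf = repair_vectors(compute_piv(stack[0], stack[1]))
print(f"PIV: {int(vf.valid.sum())}/{vf.valid.size} valid vectors on a "
      f"{len(vf.x)}x{len(vf.y)} grid (10 px pitch)")

near = strain_rate(vf, (30, 60, 108, 148), "x", dt=1.5)
centre = strain_rate(vf, (108, 148, 108, 148), "x", dt=1.5)
print(f"strain rate d(v_x)/dx near the left interface: {near:+.4f} 1/min")
print(f"strain rate d(v_x)/dx at the centre:           {centre:+.4f} 1/min")
print("early in the contraction only material near the active/passive")
print("boundary contracts; the centre has not yet 'felt' the boundary.")
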