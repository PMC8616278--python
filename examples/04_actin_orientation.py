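"""Actin orientation order parameter on synthetic filament images.

Renders one aligned and one isotropic filament network, extracts the
per-pixel orientation field (Gabor enhancement + structure tensor) and
computes the nematic order parameter S = <cos 2 theta> relative to the
cell axis. Aligned networks approach S = 1; isotropic ones S = 0 --
the same ordering observed between primed and naive cells.
"""

import numpy as np

from escmech.orientation import (CellAxis, gabor_enhance, order_parameter,
                                 order_parameter_from_angles, polar_histogram,
                                 structure_tensor_orientation)
from escmech.synthetic import render_filament_image

axis = CellAxis(major_axis_angle=0.0, aspect_ratio=1.0, centroid=(0, 0))
rng = np.random.default_rng(4)

for name, angles in [
        ("aligned (primed-like)", rng.normal(0.0, 8.0, 80)),
        ("isotropic (naive-like)", rng.uniform(-90, 90, 200))]:
    angles = (angles + 90) % 180 - 90
    truth = order_parameter_from_angles(angles, 0.0)
    img, _ = render_filament_image(angles, image_size=224, seed=1)
    field = structure_tensor_orientation(gabor_enhance(img, n_orientations=12))
    res = order_parameter(field, axis)
    counts, edges = polar_histogram(field, n_bins=6)
    print(f"{name}: S = {res.S:+.3f} (truth <cos 2 theta> = {truth:+.3f}, "
          f"{res.n_pixels} px)")
    frac = counts / counts.sum()
    bins = ", ".join(f"{e:+.0f}:{f:.2f}" for e, f in zip(edges[:-1], frac))
    print(f"  30-degree histogram mass: {bins}")

print("\nS near 1 means filaments run along the reference axis; near 0, no "
      "preferred direction.")
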